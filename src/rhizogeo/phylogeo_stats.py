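"""Spatial and environmental association statistics.

Great-circle distances, Mantel and partial Mantel permutation tests,
principal coordinates analysis (Gower double-centering), sliding-window
diversity curves against a random-distance null, and sequential
distance-based permutational ANOVA for environmental covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CollinearityError, ParameterError, RhizogeoError
from .msa_core import DistanceMatrix

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Geographic distance
# ---------------------------------------------------------------------------

def geo_distance(meta: pd.DataFrame) -> DistanceMatrix:
    """Haversine great-circle distance matrix in km.

    Strains with missing coordinates are excluded; the excluded ids are
    recorded in ``result.excluded``.
    """
    if "latitude" not in meta or "longitude" not in meta:
        raise ValueError("metadata needs latitude and longitude columns")
    ok = meta["latitude"].notna() & meta["longitude"].notna()
    excluded = list(meta.loc[~ok, "strain_id"]) if "strain_id" in meta else \
        list(meta.index[~ok])
    sub = meta.loc[ok]
    ids = list(sub["strain_id"]) if "strain_id" in sub else list(sub.index)
    lat = np.radians(sub["latitude"].to_numpy(float))
    lon = np.radians(sub["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] \
        * np.sin(dlon / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(ids, (d + d.T) / 2, "haversine-km")
    dm.excluded = excluded
    return dm


def value_distance(values, labels) -> DistanceMatrix:
    """|x_i - x_j| distance matrix from a per-strain scalar (pH, altitude...)."""
    v = np.asarray(values, dtype=float)
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(list(labels), d, "abs-difference")


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    partial: bool = False
    covariate: str | None = None
    alternative: str = "greater"


def _aligned_values(*dms: DistanceMatrix) -> list[np.ndarray]:
    labels = dms[0].labels
    out = [dms[0].values]
    for dm in dms[1:]:
        if dm.labels == labels:
            out.append(dm.values)
        else:
            out.append(dm.submatrix(labels).values)
    return out


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pvalue(obs: float, null: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        hits = int((null >= obs - 1e-12).sum())
    elif alternative == "less":
        hits = int((null <= obs + 1e-12).sum())
    else:  # two-sided
        hits = int((np.abs(null) >= abs(obs) - 1e-12).sum())
    return (1 + hits) / (1 + len(null))


def mantel(d_gen: DistanceMatrix, d_geo: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, method: str = "pearson",
           alternative: str = "greater") -> MantelResult:
    """Mantel test: correlation of two distance matrices.

    r is the Pearson correlation of upper-triangle entries; the null is
    generated by simultaneous row/column permutation of the second matrix;
    p is one-sided (greater) by default with the +1 Monte-Carlo correction.
    """
    if len(d_gen.labels) < 4:
        raise ParameterError("mantel needs >= 4 strains")
    a_m, b_m = _aligned_values(d_gen, d_geo)
    x, y = _upper(a_m), _upper(b_m)
    if method == "spearman":
        from scipy.stats import rankdata
        x, y = rankdata(x), rankdata(y)
    if x.std() == 0 or y.std() == 0:
        raise RhizogeoError("undefined correlation: constant distance matrix")
    obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = a_m.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        yp = _upper(b_m[np.ix_(perm, perm)])
        if method == "spearman":
            from scipy.stats import rankdata
            yp = rankdata(yp)
        null[k] = np.corrcoef(x, yp)[0, 1]
    return MantelResult(r=obs, p_value=_pvalue(obs, null, alternative),
                        n_permutations=n_perm, alternative=alternative)


def partial_mantel(d_gen: DistanceMatrix, d_geo: DistanceMatrix,
                   d_cov: DistanceMatrix, n_perm: int = 999, seed: int = 0,
                   alternative: str = "greater",
                   covariate_name: str | None = None) -> MantelResult:
    """Partial Mantel: correlation of d_gen and d_geo residuals after
    regressing each on d_cov; null by permuting the d_gen residuals."""
    a_m, b_m, c_m = _aligned_values(d_gen, d_geo, d_cov)
    x, y, z = _upper(a_m), _upper(b_m), _upper(c_m)
    if z.std() == 0:
        raise CollinearityError("covariate distance matrix is constant")

    def residuals(v, w):
        wc = w - w.mean()
        beta = float(wc @ (v - v.mean())) / float(wc @ wc)
        return v - v.mean() - beta * wc

    ry = residuals(y, z)
    if ry.std() == 0:
        raise CollinearityError("d_geo perfectly collinear with covariate")
    rx = residuals(x, z)
    if rx.std() == 0:
        raise CollinearityError("d_gen perfectly collinear with covariate")
    obs = float(np.corrcoef(rx, ry)[0, 1])
    # Freedman-Lane style: permute strains in the d_gen matrix, recompute
    # its residuals against the (fixed) covariate
    rng = np.random.default_rng(seed)
    n = a_m.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        xp = _upper(a_m[np.ix_(perm, perm)])
        rxp = residuals(xp, z)
        sd = rxp.std()
        null[k] = np.corrcoef(rxp, ry)[0, 1] if sd > 0 else 0.0
    return MantelResult(r=obs, p_value=_pvalue(obs, null, alternative),
                        n_permutations=n_perm, partial=True,
                        covariate=covariate_name, alternative=alternative)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray  # strains x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray
    n_negative: int = 0


def gower_center(d: np.ndarray) -> np.ndarray:
    """-1/2 J D^2 J with J the centering matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinates analysis via Gower double-centering.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) on positive
    axes; negative eigenvalues are reported but their axes omitted.
    """
    g = gower_center(dm.values)
    lam, vec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    pos = lam > max(lam.max(), 0) * 1e-10
    coords = vec[:, pos] * np.sqrt(lam[pos])
    n_neg = int((lam < -abs(lam).max() * 1e-10).sum())
    if n_axes is not None:
        coords = coords[:, :n_axes]
    denom = lam[lam > 0].sum()
    prop = np.where(lam > 0, lam / denom, 0.0)
    return PCoAResult(labels=list(dm.labels), coordinates=coords,
                      eigenvalues=lam, proportion_explained=prop,
                      n_negative=n_neg)


# ---------------------------------------------------------------------------
# Sliding-window diversity curves
# ---------------------------------------------------------------------------

@dataclass
class SlidingWindowCurve:
    window_centers: np.ndarray
    observed: np.ndarray  # NaN where a window had no eligible pair
    null: np.ndarray
    pair_counts: np.ndarray
    window_width_km: float
    step_km: float
    level: str
    n_resamples: int


def sliding_window(d_geo: DistanceMatrix, d_gen: DistanceMatrix,
                   level: str = "nucleotide", width_km: float = 80.0,
                   step_km: float = 10.0, n_resamples: int = 1,
                   seed: int = 0) -> SlidingWindowCurve:
    """Genetic diversity of strain pairs as a function of their separation.

    For each window center, eligible pairs are those whose geographic
    separation falls inside the window; the observed value is the mean
    genetic distance of ``n_resamples`` randomly drawn eligible pairs (one
    pair by default). The null draws the same number of pairs irrespective
    of distance. Windows with no eligible pair are reported as NaN (absent),
    never zero.
    """
    if width_km <= 0 or step_km <= 0:
        raise ParameterError("window width and step must be positive")
    geo_m, gen_m = _aligned_values(d_geo, d_gen)
    n = geo_m.shape[0]
    iu = np.triu_indices(n, k=1)
    gd, xd = geo_m[iu], gen_m[iu]
    rng = np.random.default_rng(seed)
    centers = np.arange(0.0, gd.max() + step_km, step_km)
    obs = np.full(len(centers), np.nan)
    nul = np.full(len(centers), np.nan)
    cnt = np.zeros(len(centers), dtype=int)
    half = width_km / 2.0
    for k, c in enumerate(centers):
        mask = (gd >= c - half) & (gd <= c + half)
        cnt[k] = int(mask.sum())
        if cnt[k] == 0:
            continue
        pool = np.flatnonzero(mask)
        pick = rng.choice(pool, size=n_resamples, replace=True)
        obs[k] = float(xd[pick].mean())
        rand = rng.integers(0, len(xd), size=n_resamples)
        nul[k] = float(xd[rand].mean())
    return SlidingWindowCurve(window_centers=centers, observed=obs, null=nul,
                              pair_counts=cnt, window_width_km=width_km,
                              step_km=step_km, level=level,
                              n_resamples=n_resamples)


def species_distance(assignment_labels: dict[str, str],
                     ids: list[str]) -> DistanceMatrix:
    """0/1 same-genospecies indicator distance between strains."""
    lab = np.array([assignment_labels[i] for i in ids], dtype=object)
    d = (lab[:, None] != lab[None, :]).astype(float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ids), d, "species-indicator")


# ---------------------------------------------------------------------------
# PERMANOVA (sequential, distance-based)
# ---------------------------------------------------------------------------

@dataclass
class PermanovaTable:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __str__(self) -> str:  # pragma: no cover
        return str(self.table)


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def permanova(d_gen: DistanceMatrix, covariates: pd.DataFrame,
              n_perm: int = 999, seed: int = 0) -> PermanovaTable:
    """Sequential (Type-I) distance-based permutational ANOVA.

    The Gower-centered matrix G is partitioned by adding covariates in
    order (McArdle-Anderson trace form): SS_j = tr(H_{1..j} G) -
    tr(H_{1..j-1} G); pseudo-F_j = (SS_j/df_j) / (SS_res/df_res). p-values
    use Freedman-Lane permutation of residuals under the reduced model.
    The SS column is labelled pseudo-chi2 in exported tables.
    """
    cov = covariates.dropna()
    ids = [i for i in d_gen.labels if i in cov.index]
    if len(ids) < len(cov.columns) + 2:
        raise ParameterError("too few complete cases for the covariates")
    g = gower_center(d_gen.submatrix(ids).values)
    n = len(ids)
    x = cov.loc[ids].to_numpy(float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1)
    ones = np.ones((n, 1))
    total_ss = float(np.trace(g))
    names = list(cov.columns)
    k = len(names)
    h_full = _hat(np.hstack([ones, x]))
    ss_res = total_ss - float(np.trace(h_full @ g))
    df_res = n - 1 - k
    rng = np.random.default_rng(seed)

    rows = []
    prev_h = _hat(ones)
    prev_trace = float(np.trace(prev_h @ g))
    for j, name in enumerate(names):
        h_j = _hat(np.hstack([ones, x[:, : j + 1]]))
        ss_j = float(np.trace(h_j @ g)) - prev_trace
        f_j = (ss_j / 1.0) / (ss_res / df_res)
        # Freedman-Lane: permute residuals of G under the reduced model
        i_minus = np.eye(n) - prev_h
        resid = i_minus @ g @ i_minus
        fitted = g - resid
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            g_star = fitted + resid[np.ix_(perm, perm)]
            ss_star = float(np.trace(h_j @ g_star)) - float(np.trace(prev_h @ g_star))
            ss_res_star = float(np.trace(g_star)) - float(np.trace(h_full @ g_star))
            f_star = ss_star / max(ss_res_star / df_res, 1e-300)
            if f_star >= f_j - 1e-12:
                hits += 1
        rows.append({"source": name, "df": 1, "pseudo_chi2": ss_j,
                     "F": f_j, "p_value": (1 + hits) / (1 + n_perm)})
        prev_h, prev_trace = h_j, float(np.trace(h_j @ g))
    rows.append({"source": "Residuals", "df": df_res, "pseudo_chi2": ss_res,
                 "F": np.nan, "p_value": np.nan})
    rows.append({"source": "Total", "df": n - 1, "pseudo_chi2": total_ss,
                 "F": np.nan, "p_value": np.nan})
    return PermanovaTable(pd.DataFrame(rows).set_index("source"))
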