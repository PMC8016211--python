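"""Spatial statistics: haversine, Mantel, PCoA, windows, PERMANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rhizogeo import (
    DistanceMatrix,
    geo_distance,
    mantel,
    partial_mantel,
    pcoa,
    permanova,
    sliding_window,
    species_distance,
    value_distance,
)
from rhizogeo.errors import CollinearityError, ParameterError


def _meta(coords):
    return pd.DataFrame([{"strain_id": f"s{i}", "latitude": la,
                          "longitude": lo} for i, (la, lo) in
                         enumerate(coords)])


def _random_dm(rng, n, labels=None):
    pts = rng.random((n, 2)) * 10
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(labels or [f"s{i}" for i in range(n)], d)


class TestGeoDistance:
    def test_same_point_zero(self):
        dm = geo_distance(_meta([(7.0, 38.0), (7.0, 38.0)]))
        assert dm.get("s0", "s1") == 0.0

    def test_one_degree_on_equator(self):
        dm = geo_distance(_meta([(0.0, 0.0), (0.0, 1.0)]))
        assert dm.get("s0", "s1") == pytest.approx(111.195, abs=0.001)

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(20):
            coords = [(float(rng.uniform(-60, 60)),
                       float(rng.uniform(-180, 180))) for _ in range(3)]
            dm = geo_distance(_meta(coords))
            d01, d02, d12 = (dm.get("s0", "s1"), dm.get("s0", "s2"),
                             dm.get("s1", "s2"))
            assert d01 <= d02 + d12 + 1e-9
            assert np.allclose(dm.values, dm.values.T)

    def test_missing_coordinates_excluded(self):
        meta = pd.DataFrame([
            {"strain_id": "s0", "latitude": 7.0, "longitude": 38.0},
            {"strain_id": "s1", "latitude": 7.5, "longitude": 38.5},
            {"strain_id": "s2", "latitude": None, "longitude": None}])
        dm = geo_distance(meta)
        assert dm.labels == ["s0", "s1"] and dm.excluded == ["s2"]


class TestMantel:
    def test_identical_matrices_r_one(self, rng):
        dm = _random_dm(rng, 6)
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        """MC p with many draws agrees with full 5! enumeration."""
        a = _random_dm(rng, 5)
        b = _random_dm(rng, 5)
        iu = np.triu_indices(5, 1)
        x = a.values[iu]
        obs = np.corrcoef(x, b.values[iu])[0, 1]
        rs = []
        for perm in itertools.permutations(range(5)):
            pm = b.values[np.ix_(perm, perm)]
            rs.append(np.corrcoef(x, pm[iu])[0, 1])
        p_exact = np.mean([r >= obs - 1e-12 for r in rs])
        res = mantel(a, b, n_perm=4999, seed=3)
        se = math.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p_value - p_exact) < 3 * se + 1e-3

    def test_type_i_error_near_nominal(self, rng):
        rejections = 0
        n_runs = 100
        for k in range(n_runs):
            a = _random_dm(rng, 10)
            b = _random_dm(rng, 10)
            rejections += mantel(a, b, n_perm=99, seed=k).p_value <= 0.05
        assert 1 <= rejections <= 12  # binomial(100, 0.05) central range

    def test_constant_matrix_rejected(self, rng):
        a = _random_dm(rng, 5)
        c = DistanceMatrix(a.labels, np.ones((5, 5)) - np.eye(5))
        c.values[:] = 1 - np.eye(5)
        with pytest.raises(Exception):
            mantel(DistanceMatrix(a.labels, np.zeros((5, 5))), a)

    def test_needs_four_strains(self, rng):
        small = _random_dm(rng, 3)
        with pytest.raises(ParameterError):
            mantel(small, small)


class TestPartialMantel:
    def test_reduces_to_simple_mantel_when_cov_uncorrelated(self, rng):
        a = _random_dm(rng, 25)
        b = DistanceMatrix(a.labels, a.values + rng.random((25, 25)) * 0
                           + _sym(rng, 25) * 0.3)
        c = _random_dm(rng, 25)  # independent covariate
        simple = mantel(a, b, n_perm=99, seed=0).r
        partial = partial_mantel(a, b, c, n_perm=99, seed=0).r
        assert abs(simple - partial) < 0.1

    def test_near_zero_when_gen_built_from_cov(self, rng):
        c = _random_dm(rng, 20)
        # covariate-driven signal plus a trace of noise to stay non-singular
        a = DistanceMatrix(c.labels, 2.0 * c.values + _sym(rng, 20) * 0.01)
        b = DistanceMatrix(c.labels, c.values + _sym(rng, 20) * 0.2)
        simple = mantel(a, b, n_perm=99, seed=0)
        res = partial_mantel(a, b, c, n_perm=99, seed=0)
        assert abs(res.r) < 0.2 < simple.r  # association vanishes given cov
        assert -1 <= res.r <= 1

    def test_collinear_geo_rejected(self, rng):
        c = _random_dm(rng, 8)
        a = _random_dm(rng, 8)
        with pytest.raises(CollinearityError):
            partial_mantel(a, c, c)


def _sym(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestPCoA:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.random((5, 2)) * 4
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(5)], d))
        got = res.coordinates[:, :2]
        d2 = np.sqrt(((got[:, None] - got[None, :]) ** 2).sum(-1))
        assert np.allclose(d2, d, atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_two_points_single_axis(self):
        d = np.array([[0, 3.0], [3.0, 0]])
        res = pcoa(DistanceMatrix(["a", "b"], d))
        assert res.coordinates.shape[1] == 1
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.5, 1.5])

    def test_equilateral_three_points_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(list("abc"), d))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa
        dm = _random_dm(rng, 7)
        ours = pcoa(dm)
        theirs = skbio_pcoa(skbio.DistanceMatrix(dm.values, dm.labels))
        lam_theirs = np.sort(theirs.eigvals.values)[::-1]
        k = min(len(ours.eigenvalues), 7)
        assert np.allclose(np.sort(ours.eigenvalues)[::-1][:k],
                           lam_theirs[:k], atol=1e-8)


class TestSlidingWindow:
    def test_empty_windows_absent_not_zero(self, rng):
        # two tight clusters far apart: middle windows have no pairs
        coords = [(7.0, 38.0)] * 4 + [(7.0, 41.0)] * 4
        meta = _meta(coords)
        d_geo = geo_distance(meta)
        d_gen = _random_dm(rng, 8, labels=d_geo.labels)
        curve = sliding_window(d_geo, d_gen, width_km=20, step_km=10, seed=0)
        assert np.isnan(curve.observed[curve.pair_counts == 0]).all()
        assert (~np.isnan(curve.observed[curve.pair_counts > 0])).all()

    def test_structured_data_diverges_from_null(self, rng):
        """Distance-decay on -> observed curve rises with distance."""
        from rhizogeo.synthetic_study import StudyConfig, simulate_study
        from rhizogeo import msa_core
        st = simulate_study(StudyConfig(
            n_strains=60, spatial_decay=2.0, ph_associated_clade=None,
            sym_absent_clade=None, seed=5))
        local = list(st.truth["strain_id"])
        hk = msa_core.concatenate(msa_core.harmonize(
            [a.subset(local) for a in st.hk_loci()]))
        d_gen = msa_core.p_distance(hk.as_locus_alignment())
        meta = st.metadata.set_index("strain_id", drop=False).loc[local]
        d_geo = geo_distance(meta)
        curve = sliding_window(d_geo, d_gen.submatrix(d_geo.labels),
                               n_resamples=30, seed=1)
        ok = ~np.isnan(curve.observed)
        centers, obs = curve.window_centers[ok], curve.observed[ok]
        slope = np.polyfit(centers, obs, 1)[0]
        assert slope > 0  # diversity increases with distance
        null_slope = np.polyfit(centers, curve.null[ok], 1)[0]
        assert slope > 5 * abs(null_slope)

    def test_unstructured_data_overlaps_null(self, rng):
        d_geo_m = _sym(rng, 30) * 300
        d_gen_m = _sym(rng, 30)
        labels = [f"s{i}" for i in range(30)]
        curve = sliding_window(DistanceMatrix(labels, d_geo_m),
                               DistanceMatrix(labels, d_gen_m),
                               n_resamples=20, seed=2)
        ok = ~np.isnan(curve.observed)
        diffs = curve.observed[ok] - curve.null[ok]
        assert abs(np.mean(diffs)) < 0.1

    def test_parameters_validated(self, rng):
        dm = _random_dm(rng, 5)
        with pytest.raises(ParameterError):
            sliding_window(dm, dm, width_km=0)


class TestSpeciesDistance:
    def test_indicator_values(self):
        d = species_distance({"a": "X", "b": "X", "c": "Y"}, ["a", "b", "c"])
        assert d.get("a", "b") == 0.0 and d.get("a", "c") == 1.0


class TestPermanova:
    def test_ss_additivity(self, rng):
        dm = _random_dm(rng, 20)
        cov = pd.DataFrame({"u": rng.random(20), "v": rng.random(20)},
                           index=dm.labels)
        tab = permanova(dm, cov, n_perm=49, seed=0).table
        terms = tab.loc[["u", "v"], "pseudo_chi2"].sum()
        assert terms + tab.loc["Residuals", "pseudo_chi2"] == \
            pytest.approx(tab.loc["Total", "pseudo_chi2"])
        assert tab.loc[["u", "v", "Residuals"], "df"].sum() == 19

    def test_informative_covariate_dominates(self, rng):
        dm = _random_dm(rng, 24)
        axis1 = pcoa(dm).coordinates[:, 0]
        cov = pd.DataFrame({"axis1": axis1, "noise": rng.random(24)},
                           index=dm.labels)
        tab = permanova(dm, cov, n_perm=199, seed=1).table
        assert tab.loc["axis1", "pseudo_chi2"] > tab.loc["noise", "pseudo_chi2"]
        assert tab.loc["axis1", "p_value"] <= 0.05
        assert tab.loc["noise", "p_value"] > 0.05

    def test_pure_noise_type_i_error(self, rng):
        rejections = 0
        n_runs = 40
        for k in range(n_runs):
            dm = _random_dm(rng, 15)
            cov = pd.DataFrame({"w": rng.random(15)}, index=dm.labels)
            tab = permanova(dm, cov, n_perm=99, seed=k).table
            rejections += tab.loc["w", "p_value"] <= 0.05
        assert rejections <= 7

    def test_too_few_cases_rejected(self, rng):
        dm = _random_dm(rng, 3)
        cov = pd.DataFrame({"u": [1.0, 2.0, 3.0], "v": [2.0, 1.0, 3.0]},
                           index=dm.labels)
        with pytest.raises(ParameterError):
            permanova(dm, cov)
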