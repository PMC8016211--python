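"""Reference-anchored genospecies/symbiovar assignment and composition tests.

A query strain is assigned by walking rootward from its leaf and anchoring
at the smallest well-supported monophyletic clade (bootstrap support above a
threshold, default 60) that contains at least one reference strain; the
label is the consensus reference species of that clade, ties broken by the
reference closest in patristic distance. Queries whose only such clade is
the whole tree are "unclustered"; maximal supported query-only clades among
them are reported as novel genospecies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateTableError,
    ParameterError,
    RootingError,
    SupportMissingError,
)
from .tree_infer import clade_leafsets

# ---------------------------------------------------------------------------
# Strain metadata
# ---------------------------------------------------------------------------

_COLLECTIONS = {"current", "previous", "reference"}


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the strain metadata table.

    Required columns: strain_id, collection; reference_species required
    exactly for collection == "reference". latitude/longitude/elevation/
    soil_pH are optional for references, range-checked when present.
    """
    meta = meta.copy()
    if "strain_id" not in meta or "collection" not in meta:
        raise ValueError("metadata needs strain_id and collection columns")
    if meta["strain_id"].duplicated().any():
        dups = meta.loc[meta["strain_id"].duplicated(), "strain_id"].tolist()
        raise ValueError(f"duplicate strain ids in metadata: {dups}")
    bad = set(meta["collection"]) - _COLLECTIONS
    if bad:
        raise ValueError(f"unknown collections {sorted(bad)}")
    is_ref = meta["collection"] == "reference"
    has_sp = meta.get("reference_species")
    has_sp = has_sp.notna() if has_sp is not None else pd.Series(False, index=meta.index)
    if (is_ref != has_sp).any():
        raise ValueError("reference_species must be present iff collection=reference")
    for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180),
                        ("soil_pH", 0, 14)):
        if col in meta:
            v = meta[col].dropna()
            if ((v < lo) | (v > hi)).any():
                raise ValueError(f"{col} outside [{lo}, {hi}]")
    return meta.set_index("strain_id", drop=False)


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

@dataclass
class CladeAssignment:
    """Per-strain labels plus anchoring details."""

    labels: dict[str, str]
    support: dict[str, float] = field(default_factory=dict)
    anchor_references: dict[str, list] = field(default_factory=dict)
    ambiguous: dict[str, list] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strain_id": list(self.labels),
            "label": [self.labels[s] for s in self.labels],
            "support": [self.support.get(s, np.nan) for s in self.labels],
            "anchor_references": [";".join(self.anchor_references.get(s, []))
                                  for s in self.labels],
        })


def _edge_support(node: dendropy.Node) -> float | None:
    sup = getattr(node.edge, "support", None)
    if sup is None and node.label is not None:
        try:
            sup = float(node.label)
        except ValueError:
            sup = None
    return sup


def assign_clades(tree: dendropy.Tree, meta: pd.DataFrame,
                  support_threshold: float = 60.0) -> CladeAssignment:
    """Assign every non-reference leaf to a genospecies.

    The tree must be rooted and its internal edges must carry bootstrap
    supports (percentages). Terminal edges count as trivially supported, so
    a query forming a cherry with a reference anchors at the cherry's parent
    if that parent's edge is supported.
    """
    if not tree.is_rooted:
        raise RootingError("assign_clades requires a rooted tree")
    meta = meta if meta.index.name == "strain_id" else validate_metadata(meta)
    ref_species = {
        sid: meta.loc[sid, "reference_species"]
        for sid in meta.index[meta["collection"] == "reference"]
    }
    leafsets = clade_leafsets(tree)
    root_set = leafsets[tree.seed_node]
    internal = [nd for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and nd.parent_node is not None]
    if internal and all(_edge_support(nd) is None for nd in internal):
        raise SupportMissingError("internal edges carry no supports")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}

    def patristic(a: str, b: str) -> float:
        return pdm.patristic_distance(taxa[a], taxa[b])

    def supported(node: dendropy.Node) -> bool:
        if node.is_leaf():
            return True
        if node.parent_node is None:
            return True  # the root clade is the whole tree
        sup = _edge_support(node)
        return sup is not None and sup > support_threshold

    labels: dict[str, str] = {}
    support_out: dict[str, float] = {}
    anchors: dict[str, frozenset] = {}
    anchor_refs: dict[str, list] = {}
    ambiguous: dict[str, list] = {}

    queries = [lf for lf in tree.leaf_node_iter()
               if lf.taxon.label not in ref_species]
    for lf in queries:
        sid = lf.taxon.label
        node = lf
        anchor = None
        while node is not None:
            if supported(node):
                members = leafsets[node]
                refs = [m for m in members if m in ref_species]
                if refs:
                    anchor = node
                    break
            node = node.parent_node
        if anchor is None or leafsets[anchor] == root_set:
            labels[sid] = f"unclustered:{sid}"
            support_out[sid] = np.nan
            continue
        refs = sorted(m for m in leafsets[anchor] if m in ref_species)
        species = sorted({str(ref_species[r]) for r in refs})
        if len(species) == 1:
            labels[sid] = species[0]
        else:
            nearest = min(refs, key=lambda r: (patristic(sid, r), r))
            labels[sid] = str(ref_species[nearest])
            ambiguous[sid] = species
        sup = _edge_support(anchor)
        support_out[sid] = 100.0 if sup is None and anchor.is_leaf() else sup
        anchors[sid] = leafsets[anchor]
        anchor_refs[sid] = refs

    # novel genospecies: maximal supported clades made only of unclustered queries
    unclustered = {s for s, l in labels.items() if l.startswith("unclustered:")}
    novel_clades: list[frozenset] = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        members = leafsets[nd]
        if members <= unclustered and len(members) >= 2 and supported(nd):
            if not any(members < c for c in novel_clades):
                novel_clades = [c for c in novel_clades if not (c < members)]
                novel_clades.append(members)
    novel_clades.sort(key=lambda c: (-len(c), sorted(c)))
    for i, clade in enumerate(novel_clades, start=1):
        for sid in clade:
            labels[sid] = f"novel:{i}"
    return CladeAssignment(labels=labels, support=support_out,
                           anchor_references=anchor_refs, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Cross-tabulation
# ---------------------------------------------------------------------------

def cross_tabulate(assign_hk: CladeAssignment,
                   assign_sym: CladeAssignment) -> pd.DataFrame:
    """Genospecies x symbiovar contingency table with recomputed margins.

    Strains lacking a symbiovar call (e.g. the symbiotic locus was absent)
    are dropped; the count of dropped strains is stored in
    ``table.attrs["n_dropped"]``. Margins are always recomputed from the
    cells.
    """
    shared = [s for s in assign_hk.labels if s in assign_sym.labels]
    dropped = len(assign_hk.labels) - len(shared)
    rows = sorted({assign_hk.labels[s] for s in shared})
    cols = sorted({assign_sym.labels[s] for s in shared})
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for s in shared:
        table.loc[assign_hk.labels[s], assign_sym.labels[s]] += 1
    table = add_margins(table)
    table.attrs["n_dropped"] = dropped
    return table


def add_margins(cells: pd.DataFrame) -> pd.DataFrame:
    """Append a Total row and column computed from the cells."""
    out = cells.copy()
    out["Total"] = out.sum(axis=1)
    out.loc["Total"] = out.sum(axis=0)
    return out


# ---------------------------------------------------------------------------
# Composition test (Fisher-style exact / Monte-Carlo)
# ---------------------------------------------------------------------------

def _log_binom(n, k):
    from scipy.special import gammaln
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _table_logprob(row1: np.ndarray, coltot: np.ndarray, n1: int, N: int):
    return float(_log_binom(coltot, row1).sum() - _log_binom(N, n1))


def _count_tables(coltot: np.ndarray, n1: int, limit: int) -> int:
    """Number of 2xK tables with the given margins (capped at ``limit``)."""
    total = int(coltot.sum())
    counts = {n1: 1}
    n_tables = 0
    remaining = total
    for c in coltot:
        remaining -= int(c)
        new: dict[int, int] = {}
        for rem, ways in counts.items():
            lo = max(0, rem - remaining)
            hi = min(int(c), rem)
            for x in range(lo, hi + 1):
                new[rem - x] = new.get(rem - x, 0) + ways
                n_tables += ways
                if n_tables > limit:
                    return limit + 1
        counts = new
    return counts.get(0, 0)


def composition_test(counts_by_group, method: str = "auto",
                     n_mc: int = 9999, seed: int = 0,
                     exact_limit: int = 10 ** 6) -> float:
    """Fisher-style exact test of homogeneity for a 2xK count table.

    Enumerates all tables with the observed margins when their number is
    within ``exact_limit`` (p = total conditional probability of tables no
    more probable than the observed one); otherwise a fixed-margin
    Monte-Carlo estimate with the +1 correction.
    """
    t = np.asarray(counts_by_group, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ParameterError("composition_test expects a 2xK table")
    if (t < 0).any():
        raise ParameterError("counts must be non-negative")
    if t.sum() == 0:
        raise DegenerateTableError("all-zero table")
    keep = t.sum(axis=0) > 0
    t = t[:, keep]
    if t.shape[1] < 2:
        return 1.0
    coltot = t.sum(axis=0)
    n1, N = int(t[0].sum()), int(t.sum())
    obs_lp = _table_logprob(t[0], coltot, n1, N)
    eps = 1e-9

    use_exact = method == "exact" or (
        method == "auto" and _count_tables(coltot, n1, exact_limit) <= exact_limit)
    if use_exact:
        k = len(coltot)
        p_total = 0.0

        def rec(j: int, rem: int, lp_partial: float):
            nonlocal p_total
            if j == k:
                if rem == 0 and lp_partial <= obs_lp + eps:
                    p_total += float(np.exp(lp_partial))
                return
            remaining_cols = int(coltot[j + 1:].sum())
            lo = max(0, rem - remaining_cols)
            hi = min(int(coltot[j]), rem)
            for x in range(lo, hi + 1):
                rec(j + 1, rem - x,
                    lp_partial + float(_log_binom(coltot[j], x)))

        rec(0, n1, -float(_log_binom(N, n1)))
        return float(min(p_total, 1.0))

    # Monte-Carlo with fixed margins: permute group labels of the N units
    rng = np.random.default_rng(seed)
    units = np.repeat(np.arange(len(coltot)), coltot)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(N)
        grp1 = units[perm[:n1]]
        row1 = np.bincount(grp1, minlength=len(coltot))
        if _table_logprob(row1, coltot, n1, N) <= obs_lp + eps:
            hits += 1
    return (1 + hits) / (1 + n_mc)
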