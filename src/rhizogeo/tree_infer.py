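"""Distance-based tree building and bootstrap clade support.

Trees are dendropy.Tree objects. Bootstrap supports are attached to
internal nodes as integer percentages (node.label and node.edge.support);
the raw replicate counts are kept on ``node.edge.support_count``.

Bipartitions are canonicalized as the leaf-set side NOT containing the
lexicographically smallest leaf label, so equal splits compare equal
regardless of rooting or child order.
"""

from __future__ import annotations

from typing import Callable, Iterable

import dendropy
import numpy as np

from .errors import ParameterError
from .msa_core import DistanceMatrix, LocusAlignment

# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou & Nei neighbor joining with deterministic tie-breaking.

    The joined pair at each step is the Q-matrix minimum, ties broken by
    lowest (row, column) index. Negative branch-length estimates are clamped
    to zero with the deficit transferred to the sister branch, preserving
    the pair's summed length.
    """
    n = len(dm.labels)
    if n < 3:
        raise ParameterError("neighbor joining needs >= 3 taxa")
    d = np.array(dm.values, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin on flattened row-major array
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i], active[j]
        parent = dendropy.Node()
        nodes[gi].edge.length = li
        nodes[gj].edge.length = lj
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        # distances from the new node to remaining taxa
        new_row = np.full(d.shape[0] + 1, 0.0)
        for k_pos, gk in enumerate(active):
            if gk in (gi, gj):
                continue
            new_row[gk] = 0.5 * (d[gi, gk] + d[gj, gk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :] = new_row
        d[:, -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # join the last two nodes under an (unrooted) bifurcating seed node
    ga, gb = active
    dab = max(d[ga, gb], 0.0)
    root = dendropy.Node()
    nodes[ga].edge.length = dab / 2.0
    nodes[gb].edge.length = dab / 2.0
    root.add_child(nodes[ga])
    root.add_child(nodes[gb])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree,
                 restrict_to: Iterable[str] | None = None) -> set[frozenset]:
    """Canonical non-trivial bipartitions, one per internal edge.

    Each split is represented by the side not containing the smallest leaf
    label (after optional restriction to a shared leaf set), making the set
    invariant under re-rooting and child order.
    """
    labels = set(leaf_labels(tree))
    if restrict_to is not None:
        labels &= set(restrict_to)
    if not labels:
        return set()
    anchor = min(labels)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter()) & labels
        side = below if anchor not in below else frozenset(labels - below)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def clade_leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset]:
    """Map every node to its descendant leaf-label set (leaves included)."""
    sets: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            sets[node] = frozenset().union(*(sets[c] for c in
                                             node.child_nodes()))
    return sets


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_supports(aln: LocusAlignment,
                       builder: Callable[[LocusAlignment], dendropy.Tree],
                       n_replicates: int = 100,
                       seed: int | np.random.Generator = 0,
                       reference_tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """Nonparametric bootstrap clade supports on the builder's tree.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal edge of the reference tree is the percentage of
    replicate trees containing the same bipartition (restricted to shared
    leaves). Supports are written as integer-rounded percentages on internal
    node labels and as floats on ``edge.support``.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    tree = reference_tree if reference_tree is not None else builder(aln)
    labels = set(leaf_labels(tree))
    ids = aln.strain_ids
    seqs = [aln.rows[i] for i in ids]
    ncol = aln.n_columns
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = {sid: "".join(s[c] for c in cols) for sid, s in zip(ids, seqs)}
        rep_tree = builder(LocusAlignment(aln.locus_name, rows))
        rep_bps = bipartitions(rep_tree, restrict_to=labels)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    anchor = min(labels)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else frozenset(labels - below)
        if 2 <= len(side) <= len(labels) - 2:
            c = counts[side]
            node.edge.support_count = c
            node.edge.support = 100.0 * c / n_replicates
            node.label = str(int(round(node.edge.support)))
        else:
            # trivial split: fully determined, treat as unanimously supported
            node.edge.support_count = n_replicates
            node.edge.support = 100.0
            node.label = "100"
    return tree


def nj_builder(deletion_policy: str = "pairwise"
               ) -> Callable[[LocusAlignment], dendropy.Tree]:
    """Deterministic alignment -> tree function: p-distance + NJ."""
    from .msa_core import p_distance

    def build(aln: LocusAlignment) -> dendropy.Tree:
        return neighbor_joining(p_distance(aln, deletion_policy))

    return build


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def root_tree(tree: dendropy.Tree, outgroup: str | None = None) -> dendropy.Tree:
    """Root by outgroup when given, otherwise at the midpoint.

    Internal-node support labels are preserved; after rerooting, supports
    are re-derived from bipartitions so that each internal edge keeps the
    support of the split it induces.
    """
    supports = {}
    labels = set(leaf_labels(tree))
    anchor = min(labels)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if getattr(node.edge, "support", None) is None and node.label is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else frozenset(labels - below)
        sup = getattr(node.edge, "support", None)
        if sup is None and node.label is not None:
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        if sup is not None:
            supports[side] = sup
    t = tree.clone(depth=1)
    if outgroup is not None:
        og = t.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not found in tree")
        half = (og.edge.length or 0.0) / 2.0
        t.reroot_at_edge(og.edge, length1=half, length2=half,
                         update_bipartitions=False)
    else:
        t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    for node in t.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else frozenset(labels - below)
        sup = supports.get(side)
        node.edge.support = sup
        node.label = str(int(round(sup))) if sup is not None else None
    return t


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick tree; internal node labels are kept as supports."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.edge.support = float(node.label)
            except ValueError:
                pass
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.edge.support = float(node.label)
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
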