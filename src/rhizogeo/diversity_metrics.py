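"""Genetic diversity at three levels of genomic hierarchy.

Nucleotide level: mean pairwise proportion of differing sites (pi).
Locus level: Nei's unbiased haplotype diversity h = n/(n-1) * (1 - sum p_i^2),
averaged across loci; haplotypes are exact sequence matches after masking
ambiguity/gap sites within the group.
Species level: Shannon (natural log) and Gini-Simpson indices over
genospecies counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    ParameterError,
    UndefinedDistanceError,
)
from .msa_core import DistanceMatrix, LocusAlignment, p_distance


@dataclass
class DiversityProfile:
    group_name: str
    n_strains: int
    nucleotide_diversity: float | None = None
    locus_diversity: float | None = None
    shannon: float | None = None
    simpson: float | None = None
    reason_absent: str | None = None


# ---------------------------------------------------------------------------
# Nucleotide level
# ---------------------------------------------------------------------------

def nucleotide_diversity(aln: LocusAlignment, strain_subset=None) -> float:
    """Mean pairwise p-distance (pairwise deletion) within a strain set."""
    ids = list(strain_subset) if strain_subset is not None else aln.strain_ids
    if len(ids) < 2:
        raise InsufficientDataError("nucleotide diversity needs >= 2 strains")
    dm = p_distance(aln.subset(ids))
    iu = np.triu_indices(len(ids), k=1)
    return float(dm.values[iu].mean())


# ---------------------------------------------------------------------------
# Locus (haplotype) level
# ---------------------------------------------------------------------------

def haplotypes(aln: LocusAlignment, strain_subset=None) -> dict[str, int]:
    """Integer haplotype id per strain: exact identity after masking columns
    containing any gap/ambiguity within the group."""
    ids = list(strain_subset) if strain_subset is not None else aln.strain_ids
    sub = aln.subset(ids)
    m = sub.matrix()
    keep = (m < 4).all(axis=0)
    seen: dict[bytes, int] = {}
    out: dict[str, int] = {}
    for i, sid in enumerate(ids):
        key = m[i, keep].tobytes()
        out[sid] = seen.setdefault(key, len(seen))
    return out


def haplotype_diversity(haplotype_labels, unbiased: bool = True) -> float:
    """Nei's (unbiased) haplotype diversity from per-strain labels."""
    labels = list(haplotype_labels.values()) \
        if isinstance(haplotype_labels, dict) else list(haplotype_labels)
    n = len(labels)
    if n < 2:
        raise InsufficientDataError("haplotype diversity needs >= 2 strains")
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / n
    h = 1.0 - float((p ** 2).sum())
    return h * n / (n - 1) if unbiased else h


def locus_diversity(loci: list[LocusAlignment], strain_subset=None,
                    unbiased: bool = True) -> float:
    """Haplotype diversity per locus, averaged across loci."""
    vals = [haplotype_diversity(haplotypes(a, strain_subset), unbiased)
            for a in loci]
    return float(np.mean(vals))


def allele_sharing_distance(multilocus_haplotypes: dict[str, dict[str, int]]
                            ) -> DistanceMatrix:
    """d(i,j) = fraction of co-typed loci where i and j differ.

    ``multilocus_haplotypes`` maps locus name -> {strain_id: haplotype id};
    a strain may be untyped (absent) at a locus. A pair with no co-typed
    locus is an error.
    """
    ids = sorted({s for hl in multilocus_haplotypes.values() for s in hl})
    n = len(ids)
    diff = np.zeros((n, n))
    typed = np.zeros((n, n))
    for hl in multilocus_haplotypes.values():
        present = np.array([s in hl for s in ids])
        vals = np.array([hl.get(s, -1) for s in ids])
        both = np.outer(present, present)
        typed += both
        diff += both & (vals[:, None] != vals[None, :])
    off = ~np.eye(n, dtype=bool)
    if (typed[off] == 0).any():
        i, j = np.argwhere((typed == 0) & off)[0]
        raise UndefinedDistanceError(
            f"no co-typed locus for pair ({ids[i]!r}, {ids[j]!r})")
    d = np.where(typed > 0, diff / np.maximum(typed, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, "allele-sharing")


# ---------------------------------------------------------------------------
# Species level
# ---------------------------------------------------------------------------

def species_diversity(category_counts) -> dict[str, float]:
    """Shannon H' (nats) and Gini-Simpson 1 - sum(p^2) over positive counts."""
    c = np.asarray(list(category_counts.values())
                   if isinstance(category_counts, dict) else category_counts,
                   dtype=float)
    if (c < 0).any():
        raise ParameterError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise DegenerateTableError("all categories empty")
    p = c / c.sum()
    return {"shannon": float(-(p * np.log(p)).sum()),
            "simpson": float(1.0 - (p ** 2).sum())}


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_diversity(group_a, group_b, metric, n_perm: int = 999,
                      seed: int = 0) -> dict[str, float]:
    """Two-sided permutation test for a difference in a diversity metric.

    ``metric`` maps a list of strain ids to a scalar. Strains are shuffled
    between the groups ``n_perm`` times; p is the +1-corrected fraction of
    permuted |differences| at least as large as observed.
    """
    if n_perm < 19:
        raise ParameterError("n_perm must be >= 19")
    a, b = list(group_a), list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("both groups need >= 2 strains")
    obs = metric(a) - metric(b)
    rng = np.random.default_rng(seed)
    pool = np.array(a + b, dtype=object)
    na = len(a)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))
        pa, pb = pool[perm[:na]], pool[perm[na:]]
        if abs(metric(list(pa)) - metric(list(pb))) >= abs(obs) - 1e-12:
            hits += 1
    return {"observed_difference": float(obs),
            "p_value": (1 + hits) / (1 + n_perm)}
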