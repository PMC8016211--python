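"""Multilocus alignment handling.

Reading, harmonizing and concatenating per-locus nucleotide alignments;
site classification (conserved / variable / parsimony-informative /
singleton); observed and model-corrected pairwise distances; and
alignment-fraction average nucleotide identity (MLSA-ANI).

Sequences are stored upper-case over the alphabet {A,C,G,T,-,N} plus the
IUPAC ambiguity codes. Site classification and distances consider only
unambiguous bases (A/C/G/T); gaps and ambiguity codes are excluded per
column or per pair (pairwise deletion), with a complete-deletion option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    DuplicateIdError,
    EmptyOverlapError,
    InsufficientDataError,
    SaturationError,
    UndefinedDistanceError,
)

# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

#: IUPAC nucleotide codes mapped to the set of compatible unambiguous bases.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# codes >= 4 are gaps / ambiguity; exact code identifies the character
_CHAR_ORDER = "ACGT" + "".join(c for c in IUPAC_CODES if c not in "ACGT")
_CHAR_TO_CODE = {c: i for i, c in enumerate(_CHAR_ORDER)}
_CODE_TO_CHAR = {i: c for c, i in _CHAR_TO_CODE.items()}

_PURINES = frozenset("AG")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CHAR_TO_CODE[c] for c in seq), dtype=np.uint8,
                           count=len(seq))
    except KeyError as exc:
        raise AlphabetError(f"illegal character {exc.args[0]!r} in sequence") from exc


def normalize_sequence(seq: str) -> str:
    """Upper-case, map RNA U to T, and validate against the alphabet."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - set(IUPAC_CODES)
    if bad:
        raise AlphabetError(f"illegal characters {sorted(bad)} in sequence")
    return out


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LocusAlignment:
    """One gene's aligned sequences keyed by strain id."""

    locus_name: str
    rows: dict[str, str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        lengths = set()
        for sid, seq in self.rows.items():
            if sid in norm:
                raise DuplicateIdError(f"duplicate strain id {sid!r}")
            s = normalize_sequence(seq)
            norm[sid] = s
            lengths.add(len(s))
        if len(lengths) > 1:
            raise AlignmentError(
                f"locus {self.locus_name!r}: rows of unequal length {sorted(lengths)}")
        self.rows = norm

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def strain_ids(self) -> list[str]:
        return list(self.rows)

    def matrix(self) -> np.ndarray:
        """(n_strains, n_columns) uint8 code matrix; cached."""
        if self._matrix is None or self._matrix.shape[0] != len(self.rows):
            self._matrix = np.vstack([_encode(s) for s in self.rows.values()]) \
                if self.rows else np.zeros((0, 0), dtype=np.uint8)
        return self._matrix

    def subset(self, ids) -> "LocusAlignment":
        missing = [i for i in ids if i not in self.rows]
        if missing:
            raise KeyError(f"strain ids absent from {self.locus_name}: {missing}")
        return LocusAlignment(self.locus_name, {i: self.rows[i] for i in ids})

    def trim(self, start: int, end: int) -> "LocusAlignment":
        """Restrict to the half-open column interval [start, end)."""
        if not (0 <= start <= end <= self.n_columns):
            raise AlignmentError(f"trim interval [{start},{end}) out of range")
        return LocusAlignment(self.locus_name,
                              {i: s[start:end] for i, s in self.rows.items()})


@dataclass
class ConcatenatedAlignment:
    """Loci joined column-wise over a common strain set."""

    loci: list[str]
    boundaries: dict[str, tuple[int, int]]
    rows: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def strain_ids(self) -> list[str]:
        return list(self.rows)

    def as_locus_alignment(self, name: str = "concatenated") -> LocusAlignment:
        return LocusAlignment(name, dict(self.rows))

    def extract_locus(self, locus: str) -> LocusAlignment:
        a, b = self.boundaries[locus]
        return LocusAlignment(locus, {i: s[a:b] for i, s in self.rows.items()})


@dataclass(frozen=True)
class SiteClassification:
    n_sites: int
    n_conserved: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise distances with ordered labels."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.labels.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)],
                              self.metric_name)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path, locus_name: str | None = None) -> LocusAlignment:
    """Read a FASTA alignment (wrapped or single-line records).

    Records must all have the same length; ids must be unique. Lower-case
    and RNA input are normalized.
    """
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise DuplicateIdError(f"duplicate strain id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq)
    if not rows:
        raise AlignmentError(f"no FASTA records in {path}")
    name = locus_name
    if name is None:
        import os
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return LocusAlignment(name, rows)


def write_fasta(aln: LocusAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.rows.items():
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Harmonization and concatenation
# ---------------------------------------------------------------------------

def harmonize(loci: list[LocusAlignment], strain_policy="intersection",
              trim: dict[str, tuple[int, int]] | None = None) -> list[LocusAlignment]:
    """Restrict every locus to a common strain set.

    strain_policy is either the string "intersection" or an explicit list of
    strain ids. Column trimming is never inferred: if wanted it must be given
    explicitly as ``trim[locus_name] = (start, end)`` half-open intervals.
    """
    if not loci:
        raise ValueError("harmonize requires at least one locus")
    if strain_policy == "intersection":
        keep = [i for i in loci[0].strain_ids
                if all(i in a.rows for a in loci[1:])]
    else:
        keep = list(strain_policy)
        missing = [i for i in keep if any(i not in a.rows for a in loci)]
        if missing:
            raise EmptyOverlapError(f"strains absent from some loci: {missing}")
    if not keep:
        raise EmptyOverlapError("no strain ids shared by all loci")
    out = []
    for a in loci:
        b = a.subset(keep)
        if trim and a.locus_name in trim:
            b = b.trim(*trim[a.locus_name])
        out.append(b)
    return out


def concatenate(loci: list[LocusAlignment]) -> ConcatenatedAlignment:
    """Join harmonized loci column-wise, recording per-locus boundaries."""
    if not loci:
        raise ValueError("concatenate requires at least one locus")
    ids = loci[0].strain_ids
    idset = set(ids)
    for a in loci[1:]:
        if set(a.strain_ids) != idset:
            raise AlignmentError(
                f"locus {a.locus_name!r} strain set differs; harmonize first")
    boundaries: dict[str, tuple[int, int]] = {}
    pos = 0
    for a in loci:
        boundaries[a.locus_name] = (pos, pos + a.n_columns)
        pos += a.n_columns
    rows = {i: "".join(a.rows[i] for a in loci) for i in ids}
    return ConcatenatedAlignment([a.locus_name for a in loci], boundaries, rows)


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def classify_sites(aln: LocusAlignment) -> SiteClassification:
    """Classify columns from unambiguous bases only.

    conserved: exactly one distinct base present; variable: >= 2 distinct
    bases; parsimony-informative: >= 2 distinct bases each in >= 2 sequences;
    singleton: variable but not parsimony-informative. Columns containing
    only gaps/ambiguity fall in neither class.
    """
    if len(aln.rows) < 2:
        raise InsufficientDataError("site classification needs >= 2 rows")
    m = aln.matrix()
    counts = np.zeros((4, m.shape[1]), dtype=np.int64)
    for b in range(4):
        counts[b] = (m == b).sum(axis=0)
    present = counts > 0
    n_distinct = present.sum(axis=0)
    conserved = int((n_distinct == 1).sum())
    variable_mask = n_distinct >= 2
    variable = int(variable_mask.sum())
    ge2 = (counts >= 2).sum(axis=0)
    pi = int((variable_mask & (ge2 >= 2)).sum())
    return SiteClassification(
        n_sites=m.shape[1],
        n_conserved=conserved,
        n_variable=variable,
        n_parsimony_informative=pi,
        n_singleton=variable - pi,
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _pair_counts(m: np.ndarray, complete_deletion: bool):
    """Pairwise (comparable, different, transition) counts via one-hot matmuls."""
    valid = m < 4
    if complete_deletion:
        keep = valid.all(axis=0)
        m = m[:, keep]
        valid = valid[:, keep]
    onehot = np.stack([(m == b) for b in range(4)]).astype(np.float64)
    match = np.einsum("bik,bjk->ij", onehot, onehot)
    vf = valid.astype(np.float64)
    comparable = vf @ vf.T
    diff = comparable - match
    # transitions: A<->G or C<->T
    ts = (onehot[0] @ onehot[2].T) + (onehot[2] @ onehot[0].T) \
        + (onehot[1] @ onehot[3].T) + (onehot[3] @ onehot[1].T)
    return comparable, diff, ts


def p_distance(aln: LocusAlignment, deletion_policy: str = "pairwise") -> DistanceMatrix:
    """Observed proportion of differing sites between every pair of rows.

    Only columns where both sequences carry unambiguous bases are compared
    ("pairwise" deletion); "complete" restricts to columns unambiguous in
    every row first.
    """
    if len(aln.rows) < 2:
        raise InsufficientDataError("p_distance needs >= 2 rows")
    comparable, diff, _ = _pair_counts(aln.matrix(),
                                       deletion_policy == "complete")
    labels = aln.strain_ids
    bad = np.argwhere((comparable == 0) & ~np.eye(len(labels), dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise UndefinedDistanceError(
            f"no comparable columns between {labels[i]!r} and {labels[j]!r}")
    with np.errstate(invalid="ignore"):
        d = np.where(comparable > 0, diff / np.maximum(comparable, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, (d + d.T) / 2.0, "p-distance")


def corrected_distance(aln: LocusAlignment, model: str = "K2P",
                       deletion_policy: str = "pairwise") -> DistanceMatrix:
    """Model-corrected distances (JC69, K2P, or T92).

    JC69: d = -(3/4) ln(1 - 4p/3)
    K2P:  d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)
    T92:  d = -h ln(1 - P/h - Q) - ((1-h)/2) ln(1 - 2Q), h = 2*theta*(1-theta)
    with P, Q the transition/transversion proportions and theta the GC content.
    A pair whose log argument is non-positive raises a saturation error.
    """
    model = model.upper()
    if model not in {"JC69", "K2P", "T92"}:
        raise ValueError(f"unknown model {model!r}")
    if len(aln.rows) < 2:
        raise InsufficientDataError("corrected_distance needs >= 2 rows")
    m = aln.matrix()
    comparable, diff, ts = _pair_counts(m, deletion_policy == "complete")
    labels = aln.strain_ids
    n = len(labels)
    d = np.zeros((n, n))
    if model == "T92":
        gc = float(((m == 1) | (m == 2)).sum()) / max(int((m < 4).sum()), 1)
        h = 2.0 * gc * (1.0 - gc)
    for i in range(n):
        for j in range(i + 1, n):
            c = comparable[i, j]
            if c == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}")
            p = diff[i, j] / c
            P = ts[i, j] / c
            Q = p - P
            if model == "JC69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    raise SaturationError(
                        f"saturated pair ({labels[i]!r}, {labels[j]!r})")
                d[i, j] = -0.75 * math.log(arg)
            elif model == "K2P":
                a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if a1 <= 0 or a2 <= 0:
                    raise SaturationError(
                        f"saturated pair ({labels[i]!r}, {labels[j]!r})")
                d[i, j] = -0.5 * math.log(a1) - 0.25 * math.log(a2)
            else:  # T92
                a1, a2 = 1.0 - P / h - Q, 1.0 - 2.0 * Q
                if h <= 0 or a1 <= 0 or a2 <= 0:
                    raise SaturationError(
                        f"saturated pair ({labels[i]!r}, {labels[j]!r})")
                d[i, j] = -h * math.log(a1) - 0.5 * (1.0 - h) * math.log(a2)
            d[j, i] = d[i, j]
    return DistanceMatrix(labels, d, model)


# ---------------------------------------------------------------------------
# MLSA-ANI
# ---------------------------------------------------------------------------

def ani(aln: LocusAlignment, ids_a, ids_b=None) -> dict[str, float]:
    """Alignment-fraction average nucleotide identity (MLSA-ANI), percent.

    %identity of a pair = 100 * (1 - p_distance) over the shared alignment.
    With a single strain set, summarizes within-set pairs (self-pairs
    excluded); with two sets, all between-set pairs. Returns mean/min/max.
    """
    ids_a = list(ids_a)
    within = ids_b is None
    ids_b = ids_a if within else list(ids_b)
    if not ids_a or not ids_b:
        raise InsufficientDataError("ANI strain sets must be non-empty")
    if within and len(ids_a) < 2:
        raise InsufficientDataError("within-set ANI needs >= 2 strains")
    all_ids = list(dict.fromkeys(ids_a + ids_b))
    dm = p_distance(aln.subset(all_ids))
    vals = []
    for a in ids_a:
        for b in ids_b:
            if within and all_ids.index(a) >= all_ids.index(b):
                continue
            if a == b:
                continue
            vals.append(100.0 * (1.0 - dm.get(a, b)))
    return {"mean": float(np.mean(vals)), "min": float(np.min(vals)),
            "max": float(np.max(vals)), "n_pairs": len(vals)}
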