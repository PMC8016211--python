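"""Felsenstein-pruning likelihood under GTR-family models with +G/+I.

Implements phylogenetic likelihood with pattern compression, discrete-gamma
rate heterogeneity (equal-probability category means) and an
invariant-sites class; coordinate-ascent optimization of branch lengths and
model parameters; best-improving NNI topology search; BIC/AICc model
selection; alignment simulation along a tree; and the parametric-bootstrap
(SOWH-style) test of gene-tree congruence against a reference topology.

Rate matrices are reversible (Q_ij = s_ij * pi_j) and normalized to one
expected substitution per site; with an invariant class the variable-site
categories are rescaled so the overall mean rate stays 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import ParameterError
from .msa_core import IUPAC_CODES, LocusAlignment, _BASE_INDEX, _CODE_TO_CHAR
from .tree_infer import neighbor_joining, to_newick

# exchangeability order
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
_AG, _CT = 1, 4  # transition slots in _PAIRS

_MIN_BLEN, _MAX_BLEN = 1e-8, 10.0


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible nucleotide model (JC69 / K2P / T92 / GTR), optionally +G+I."""

    name: str = "JC69"
    exchangeabilities: tuple = (1.0,) * 6  # AC, AG, AT, CG, CT, GT
    base_frequencies: tuple = (0.25,) * 4  # A, C, G, T
    gamma_shape: float | None = None
    p_invariant: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self):
        f = np.asarray(self.base_frequencies, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9 or (f <= 0).any():
            raise ParameterError("base frequencies must be positive and sum to 1")
        if any(s < 0 for s in self.exchangeabilities):
            raise ParameterError("exchangeabilities must be non-negative")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ParameterError("gamma shape must be positive")
        if self.p_invariant is not None and not (0 <= self.p_invariant < 1):
            raise ParameterError("p_invariant must lie in [0, 1)")

    # -- factories ---------------------------------------------------------
    @staticmethod
    def jc69(**kw) -> "SubstitutionModel":
        return SubstitutionModel(name="JC69", **kw)

    @staticmethod
    def k2p(kappa: float = 2.0, **kw) -> "SubstitutionModel":
        ex = [1.0] * 6
        ex[_AG] = ex[_CT] = float(kappa)
        return SubstitutionModel(name="K2P", exchangeabilities=tuple(ex), **kw)

    @staticmethod
    def t92(gc: float = 0.5, kappa: float = 2.0, **kw) -> "SubstitutionModel":
        ex = [1.0] * 6
        ex[_AG] = ex[_CT] = float(kappa)
        freqs = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
        return SubstitutionModel(name="T92", exchangeabilities=tuple(ex),
                                 base_frequencies=freqs, **kw)

    @staticmethod
    def gtr(exchangeabilities=(1.0,) * 6,
            base_frequencies=(0.25,) * 4, **kw) -> "SubstitutionModel":
        return SubstitutionModel(name="GTR",
                                 exchangeabilities=tuple(exchangeabilities),
                                 base_frequencies=tuple(base_frequencies), **kw)

    # -- derived quantities --------------------------------------------------
    def q_matrix(self) -> np.ndarray:
        """Rate matrix with mean substitution rate normalized to 1."""
        pi = np.asarray(self.base_frequencies)
        q = np.zeros((4, 4))
        for s, (i, j) in zip(self.exchangeabilities, _PAIRS):
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(pi @ np.diag(q))
        return q / mu

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the mixture including any invariant class.

        Gamma categories are the means of equal-probability quantile bins of
        Gamma(alpha, mean 1); with p_invariant the variable categories are
        scaled by 1/(1-p_inv) so the mixture mean stays 1.
        """
        if self.gamma_shape is None:
            rates = np.array([1.0])
            probs = np.array([1.0])
        else:
            k = self.n_rate_categories
            a = self.gamma_shape
            edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
            edges[0], edges[-1] = 0.0, np.inf
            upper = gammainc(a + 1, np.where(np.isinf(edges), np.inf, edges * a))
            upper[-1] = 1.0
            rates = k * np.diff(upper)
            probs = np.full(k, 1.0 / k)
        pinv = self.p_invariant or 0.0
        if pinv > 0:
            rates = np.concatenate([[0.0], rates / (1.0 - pinv)])
            probs = np.concatenate([[pinv], probs * (1.0 - pinv)])
        return rates, probs

    def n_free_parameters(self, include_tree_branches: int = 0) -> int:
        base = {"JC69": 0, "K2P": 1, "T92": 2, "GTR": 8}[self.name]
        extra = (self.gamma_shape is not None) + (self.p_invariant is not None)
        return base + extra + include_tree_branches

    def _eigensystem(self):
        return _cached_eigensystem(self.exchangeabilities,
                                   self.base_frequencies)

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths, via symmetric eigendecomposition."""
        left, lam, right = self._eigensystem()
        t = np.asarray(lengths, dtype=float)
        e = np.exp(np.multiply.outer(t, lam))  # (..., 4)
        p = np.einsum("il,...l,lj->...ij", left, e, right)
        return np.clip(p, 0.0, None)


from functools import lru_cache


@lru_cache(maxsize=256)
def _cached_eigensystem(exchangeabilities: tuple, base_frequencies: tuple):
    """Eigendecomposition of the normalized rate matrix (reversible trick)."""
    model = SubstitutionModel(name="GTR", exchangeabilities=exchangeabilities,
                              base_frequencies=base_frequencies)
    pi = np.asarray(base_frequencies)
    q = model.q_matrix()
    sq = np.sqrt(pi)
    sym = (q * sq[:, None]) / sq[None, :]
    lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
    left = u / sq[:, None]
    right = (u * sq[:, None]).T
    return left, lam, right


# ---------------------------------------------------------------------------
# Internal tree representation
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "parent", "length", "name", "index")

    def __init__(self, name=None, length=0.0):
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.length = length
        self.name = name
        self.index = -1

    def add(self, child: "_Node"):
        child.parent = self
        self.children.append(child)


class LikTree:
    """Mutable rooted view of an (un)rooted tree for likelihood work."""

    def __init__(self, root: _Node):
        self.root = root
        self.reindex()

    def reindex(self):
        self.postorder: list[_Node] = []

        def rec(nd):
            for c in nd.children:
                rec(c)
            self.postorder.append(nd)

        rec(self.root)
        for i, nd in enumerate(self.postorder):
            nd.index = i

    @property
    def leaves(self) -> list[_Node]:
        return [nd for nd in self.postorder if not nd.children]

    @property
    def branches(self) -> list[_Node]:
        return [nd for nd in self.postorder if nd.parent is not None]

    # -- conversion ---------------------------------------------------------
    @staticmethod
    def from_dendropy(tree: dendropy.Tree) -> "LikTree":
        def rec(dnode) -> _Node:
            nd = _Node(name=dnode.taxon.label if dnode.taxon else None,
                       length=dnode.edge.length or 0.0)
            for c in dnode.child_nodes():
                nd.add(rec(c))
            return nd

        return LikTree(rec(tree.seed_node))

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace(
            sorted(nd.name for nd in self.leaves))
        def rec(nd) -> dendropy.Node:
            dn = dendropy.Node()
            if not nd.children:
                dn.taxon = tns.require_taxon(label=nd.name)
            dn.edge.length = nd.length
            for c in nd.children:
                dn.add_child(rec(c))
            return dn

        t = dendropy.Tree(taxon_namespace=tns)
        t.seed_node = rec(self.root)
        t.is_rooted = False
        return t

    def copy(self) -> "LikTree":
        def rec(nd):
            c = _Node(nd.name, nd.length)
            for ch in nd.children:
                c.add(rec(ch))
            return c

        return LikTree(rec(self.root))

    def newick(self) -> str:
        def rec(nd):
            if not nd.children:
                return f"{nd.name}:{nd.length:.10g}"
            inner = ",".join(rec(c) for c in nd.children)
            return f"({inner}):{nd.length:.10g}"

        return f"({','.join(rec(c) for c in self.root.children)});"


def _as_liktree(tree) -> LikTree:
    if isinstance(tree, LikTree):
        return tree
    return LikTree.from_dendropy(tree)


# ---------------------------------------------------------------------------
# Pattern compression and leaf partials
# ---------------------------------------------------------------------------

_AMBIG_PARTIAL = np.zeros((len(_CODE_TO_CHAR), 4))
for _code, _ch in _CODE_TO_CHAR.items():
    comp = IUPAC_CODES[_ch]
    if comp:
        for _b in comp:
            _AMBIG_PARTIAL[_code, _BASE_INDEX[_b]] = 1.0
    else:  # gap: uninformative
        _AMBIG_PARTIAL[_code] = 1.0


def compress_patterns(aln: LocusAlignment, leaf_order: list[str]):
    """Unique site patterns and their counts, in a fixed leaf order."""
    m = np.vstack([aln.matrix()[aln.strain_ids.index(l)] for l in leaf_order])
    patterns, counts = np.unique(m, axis=1, return_counts=True)
    return patterns, counts.astype(float)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class LikelihoodKernel:
    """Caches pattern data for repeated likelihood evaluations on one locus."""

    def __init__(self, tree: LikTree, aln: LocusAlignment,
                 model: SubstitutionModel):
        self.tree = tree
        self.aln = aln
        self.model = model
        leaf_names = [nd.name for nd in tree.leaves]
        missing = [n for n in leaf_names if n not in aln.rows]
        if missing:
            raise ParameterError(f"leaves without sequences: {missing}")
        self.leaf_names = leaf_names
        self.patterns, self.weights = compress_patterns(aln, leaf_names)
        self.leaf_partials = {
            name: _AMBIG_PARTIAL[self.patterns[i]]  # (n_patterns, 4)
            for i, name in enumerate(leaf_names)
        }
        self._const_prod: np.ndarray | None = None

    def set_model(self, model: SubstitutionModel):
        self.model = model

    def invariant_site_lik(self) -> np.ndarray:
        """Per-pattern probability under the zero-rate (invariant) class."""
        if self._const_prod is None:
            prod = np.ones((self.patterns.shape[1], 4))
            for nd in self.tree.leaves:
                prod = prod * self.leaf_partials[nd.name]
            self._const_prod = prod
        return self._const_prod @ np.asarray(self.model.base_frequencies)

    def log_likelihood(self) -> float:
        model = self.model
        rates, probs = model.rate_categories()
        pi = np.asarray(model.base_frequencies)
        npat = self.patterns.shape[1]
        site_lik = np.zeros(npat)
        nz = rates > 0
        if (~nz).any():
            # invariant class: pattern compatible with a constant column
            site_lik += float(probs[~nz].sum()) * self.invariant_site_lik()
        ncat = int(nz.sum())
        lengths = np.array([nd.length for nd in self.tree.postorder])
        # (n_nodes, ncat, 4, 4) transition matrices in one shot
        pmats = model.transition_matrices(np.multiply.outer(lengths, rates[nz]))
        partial: dict[int, np.ndarray] = {}
        for nd in self.tree.postorder:
            if not nd.children:
                partial[nd.index] = np.broadcast_to(
                    self.leaf_partials[nd.name][:, None, :], (npat, ncat, 4))
            else:
                acc = np.ones((npat, ncat, 4))
                for c in nd.children:
                    acc *= np.einsum("pcj,cij->pci", partial.pop(c.index),
                                     pmats[c.index])
                partial[nd.index] = acc
        root = partial[self.tree.root.index]
        site_lik += (root @ pi) @ probs[nz]
        return float(self.weights @ np.log(np.clip(site_lik, 1e-300, None)))


def log_likelihood(tree, aln: LocusAlignment, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of an alignment on a tree (any rooting)."""
    return LikelihoodKernel(_as_liktree(tree), aln, model).log_likelihood()


# ---------------------------------------------------------------------------
# Fit result and information criteria
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    log_likelihood: float
    n_free_parameters: int
    model: SubstitutionModel
    tree: LikTree
    n_columns: int
    aicc: float = field(init=False)
    bic: float = field(init=False)
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self):
        k, n, lnl = self.n_free_parameters, self.n_columns, self.log_likelihood
        self.bic = -2.0 * lnl + k * math.log(n)
        if n <= k + 1:
            self.aicc = math.inf
        else:
            self.aicc = -2.0 * lnl + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def _optimize_branches(kernel: LikelihoodKernel, xatol=1e-4) -> float:
    """One sweep of per-branch optimization against cached partials.

    Up (tipward) and down (rootward) partial-likelihood arrays are computed
    once per sweep; each branch is then a cheap one-dimensional problem
    L(t) = sum_i D_i [P(t) U]_i per site. Partials go stale as branches
    update within the sweep, so the sweep ends with an exact recomputation
    and reverts wholesale if it failed to improve (rare).
    """
    tree, model = kernel.tree, kernel.model
    start_lengths = [nd.length for nd in tree.postorder]
    start_lnl = kernel.log_likelihood()

    rates, probs = model.rate_categories()
    nz = rates > 0
    rnz, pnz = rates[nz], probs[nz]
    pi = np.asarray(model.base_frequencies)
    npat = kernel.patterns.shape[1]
    ncat = int(nz.sum())
    inv = float(probs[~nz].sum()) * kernel.invariant_site_lik() \
        if (~nz).any() else np.zeros(npat)

    lengths = np.array([nd.length for nd in tree.postorder])
    pmats = model.transition_matrices(np.multiply.outer(lengths, rnz))
    up: dict[int, np.ndarray] = {}
    m: dict[int, np.ndarray] = {}
    for nd in tree.postorder:
        if not nd.children:
            up[nd.index] = np.broadcast_to(
                kernel.leaf_partials[nd.name][:, None, :], (npat, ncat, 4))
        else:
            acc = np.ones((npat, ncat, 4))
            for c in nd.children:
                acc = acc * m[c.index]
            up[nd.index] = acc
        if nd.parent is not None:
            m[nd.index] = np.einsum("pcj,cij->pci", up[nd.index],
                                    pmats[nd.index])
    down: dict[int, np.ndarray] = {}
    for nd in reversed(tree.postorder):  # preorder
        if nd.parent is None:
            base = np.broadcast_to(pi[None, None, :], (npat, ncat, 4))
        else:
            base = np.einsum("pci,cij->pcj", down[nd.index], pmats[nd.index])
        for c in nd.children:
            acc = base
            for s in nd.children:
                if s is not c:
                    acc = acc * m[s.index]
            down[c.index] = acc

    left, lam, right = model._eigensystem()
    for nd in tree.branches:
        d_arr, u_arr = down[nd.index], up[nd.index]
        # contract pattern dim late: per-eval cost npat*ncat*16
        du = np.einsum("pci,pcj->pcij", d_arr, u_arr)

        def f(t):
            e = np.exp(np.multiply.outer(t * rnz, lam))  # (ncat, 4)
            p = np.einsum("il,cl,lj->cij", left, e, right)
            site = inv + np.einsum("pcij,cij->pc", du, p) @ pnz
            return -float(kernel.weights @
                          np.log(np.clip(site, 1e-300, None)))

        res = minimize_scalar(f, bounds=(_MIN_BLEN, _MAX_BLEN),
                              method="bounded",
                              options={"xatol": xatol, "maxiter": 40})
        nd.length = float(res.x)

    lnl = kernel.log_likelihood()
    if lnl < start_lnl:
        for nd, t in zip(tree.postorder, start_lengths):
            nd.length = t
        return start_lnl
    return lnl


def _model_param_space(model: SubstitutionModel):
    """Yield (getter, setter, bounds) triplets for the model's free knobs."""
    space = []
    if model.name in ("K2P", "T92"):
        def set_kappa(m, v):
            ex = list(m.exchangeabilities)
            ex[_AG] = ex[_CT] = v
            return replace(m, exchangeabilities=tuple(ex))
        space.append((lambda m: m.exchangeabilities[_AG], set_kappa,
                      (0.05, 100.0)))
    if model.name == "T92":
        def set_gc(m, v):
            return replace(m, base_frequencies=((1 - v) / 2, v / 2, v / 2,
                                                (1 - v) / 2))
        space.append((lambda m: m.base_frequencies[1] * 2, set_gc,
                      (0.02, 0.98)))
    if model.name == "GTR":
        for slot in range(5):  # GT exchangeability fixed at 1 for identifiability
            def set_ex(m, v, slot=slot):
                ex = list(m.exchangeabilities)
                ex[slot] = v
                return replace(m, exchangeabilities=tuple(ex))
            space.append((lambda m, slot=slot: m.exchangeabilities[slot],
                          set_ex, (0.01, 100.0)))
    if model.gamma_shape is not None:
        space.append((lambda m: m.gamma_shape,
                      lambda m, v: replace(m, gamma_shape=v), (0.02, 100.0)))
    if model.p_invariant is not None:
        space.append((lambda m: m.p_invariant,
                      lambda m, v: replace(m, p_invariant=v), (0.0, 0.99)))
    return space


def _empirical_frequencies(aln: LocusAlignment) -> tuple:
    m = aln.matrix()
    counts = np.array([(m == b).sum() for b in range(4)], dtype=float)
    counts = np.maximum(counts, 1.0)
    return tuple(counts / counts.sum())


def optimize(tree, aln: LocusAlignment, model: SubstitutionModel,
             free=("branch_lengths", "model_params"),
             tol: float = 1e-6, max_rounds: int = 20) -> FitResult:
    """Coordinate-ascent fit of branch lengths and/or model parameters.

    Each round optimizes every branch with bounded scalar search, then each
    free model parameter; stops when the round's lnL improvement is below
    ``tol`` or after ``max_rounds`` (non-convergence is flagged on the
    result, not an error). The lnL trace never decreases.
    """
    lt = _as_liktree(tree).copy() if not isinstance(tree, LikTree) else tree.copy()
    if model.name == "GTR" and model.base_frequencies == (0.25,) * 4:
        model = replace(model, base_frequencies=_empirical_frequencies(aln))
    kernel = LikelihoodKernel(lt, aln, model)
    lnl = kernel.log_likelihood()
    do_bl = "branch_lengths" in free
    do_mp = "model_params" in free
    space = _model_param_space(model) if do_mp else []
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        prev = lnl
        if do_bl:
            lnl = _optimize_branches(kernel)
        for getter, setter, bounds in space:
            prev_model = kernel.model

            def f(v):
                kernel.set_model(setter(prev_model, v))
                return -kernel.log_likelihood()

            res = minimize_scalar(f, bounds=bounds, method="bounded",
                                  options={"xatol": 1e-4})
            cand_lnl = -res.fun
            if cand_lnl >= lnl:
                kernel.set_model(setter(prev_model, float(res.x)))
                lnl = cand_lnl
            else:  # guard against scalar-search wobble
                kernel.set_model(prev_model)
        if not do_bl and not space:
            converged = True
            break
        if lnl - prev < tol:
            converged = True
            break
    n_branches = len(lt.branches) if do_bl else 0
    k = kernel.model.n_free_parameters(n_branches) if do_mp else n_branches
    return FitResult(log_likelihood=kernel.log_likelihood(),
                     n_free_parameters=k, model=kernel.model, tree=lt,
                     n_columns=aln.n_columns, converged=converged,
                     n_iterations=rounds)


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def _nni_moves(tree: LikTree):
    """All (parent, child, a, b) swaps: a is a child of child, b another
    child of parent; swapping a and b realizes one NNI around the edge."""
    moves = []
    for nd in tree.postorder:
        if not nd.children or nd.parent is None:
            continue
        parent = nd.parent
        sibs = [c for c in parent.children if c is not nd]
        for a in nd.children:
            for b in sibs:
                moves.append((parent, nd, a, b))
    return moves


def _apply_swap(parent, child, a, b):
    child.children[child.children.index(a)] = b
    parent.children[parent.children.index(b)] = a
    a.parent, b.parent = parent, child


def nni_search(start_tree, aln: LocusAlignment, model: SubstitutionModel,
               max_rounds: int = 20, optimize_model: bool = True,
               opt_tol: float = 1e-6, opt_rounds: int = 20) -> FitResult:
    """Hill climbing by best-improving nearest-neighbour interchanges.

    Branch lengths are re-optimized after every accepted move; candidate
    moves are scored at current branch lengths. Terminates at a local
    optimum. The returned lnL is never below the start tree's.
    """
    free = ("branch_lengths", "model_params") if optimize_model else \
        ("branch_lengths",)
    fit = optimize(start_tree, aln, model, free=free, tol=opt_tol,
                   max_rounds=opt_rounds)
    lt, model = fit.tree, fit.model
    kernel = LikelihoodKernel(lt, aln, model)
    best = kernel.log_likelihood()
    for _ in range(max_rounds):
        best_move, best_gain = None, 1e-6
        for move in _nni_moves(lt):
            parent, child, a, b = move
            _apply_swap(parent, child, a, b)
            lt.reindex()
            cand = kernel.log_likelihood()
            _apply_swap(parent, child, b, a)
            lt.reindex()
            if cand - best > best_gain:
                best_gain, best_move = cand - best, move
        if best_move is None:
            break
        _apply_swap(*best_move)
        lt.reindex()
        best = _optimize_branches(kernel)
    final = optimize(lt, aln, model, free=free, tol=opt_tol,
                     max_rounds=opt_rounds)
    if final.log_likelihood < fit.log_likelihood:  # never worse than start
        return fit
    return final


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def model_select(aln: LocusAlignment, tree, candidates,
                 criterion: str = "BIC") -> list[FitResult]:
    """Optimize each candidate model on the same tree; rank ascending by
    the chosen information criterion (BIC default, AICc optional)."""
    if len(candidates) < 2:
        raise ParameterError("model selection needs >= 2 candidates")
    fits = [optimize(tree, aln, m) for m in candidates]
    if criterion.upper() == "AICC":
        if any(math.isinf(f.aicc) for f in fits):
            raise ParameterError("AICc undefined: n_columns <= k + 1")
        return sorted(fits, key=lambda f: f.aicc)
    return sorted(fits, key=lambda f: f.bic)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree, model: SubstitutionModel, n_columns: int,
                       seed: int | np.random.Generator = 0,
                       locus_name: str = "simulated") -> LocusAlignment:
    """Evolve i.i.d. sites along the tree under the model.

    Root states are drawn from the base frequencies; each site carries a
    rate category (possibly the invariant class); children are sampled from
    the branch transition matrices. Deterministic under a fixed seed.
    """
    if n_columns < 1:
        raise ParameterError("n_columns must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    lt = _as_liktree(tree)
    rates, probs = model.rate_categories()
    cat = rng.choice(len(rates), size=n_columns, p=probs)
    site_rates = rates[cat]
    pi = np.asarray(model.base_frequencies)
    states = {lt.root.index: rng.choice(4, size=n_columns, p=pi)}
    order = [nd for nd in reversed(lt.postorder)]  # preorder
    for nd in order:
        if nd.parent is None:
            continue
        parent_states = states[nd.parent.index]
        child = parent_states.copy()
        for r in np.unique(site_rates):
            mask = site_rates == r
            if r == 0.0 or nd.length == 0.0:
                continue
            p = model.transition_matrices(np.array([nd.length * r]))[0]
            cum = np.cumsum(p, axis=1)
            u = rng.random(int(mask.sum()))
            child[mask] = (u[:, None] >
                           cum[parent_states[mask]]).sum(axis=1)
        states[nd.index] = child
    bases = np.array(list("ACGT"))
    rows = {nd.name: "".join(bases[states[nd.index]]) for nd in lt.leaves}
    return LocusAlignment(locus_name, rows)


# ---------------------------------------------------------------------------
# Congruence test (parametric bootstrap)
# ---------------------------------------------------------------------------

@dataclass
class CongruenceResult:
    locus_name: str
    lnl_free: float
    lnl_constrained: float
    delta: float
    p_value: float
    n_bootstrap: int
    null_deltas: list[float] = field(default_factory=list)


def _free_fit(aln: LocusAlignment, model: SubstitutionModel,
              start: LikTree | None = None, opt_tol: float = 1e-4,
              opt_rounds: int = 8) -> FitResult:
    from .msa_core import p_distance
    if start is None:
        start = LikTree.from_dendropy(neighbor_joining(p_distance(aln)))
    return nni_search(start, aln, model, optimize_model=False,
                      opt_tol=opt_tol, opt_rounds=opt_rounds)


def congruence_test(locus_aln: LocusAlignment, reference_topology,
                    model: SubstitutionModel, n_bootstrap: int = 100,
                    seed: int | np.random.Generator = 0) -> CongruenceResult:
    """SOWH-style parametric bootstrap for gene-tree congruence.

    The constrained fit optimizes branch lengths and model parameters on
    the reference topology (pruned to the locus' taxa); the free fit is an
    NNI hill climb from the locus' own NJ tree. ``n_bootstrap`` alignments
    are simulated under the constrained fit and the lnL gain recomputed for
    each; p = (1 + #{delta* >= delta}) / (1 + B).
    """
    if n_bootstrap < 19:
        raise ParameterError("n_bootstrap must be >= 19 for p-value resolution")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    ref = reference_topology
    if not isinstance(ref, LikTree):
        ref = ref.clone(depth=1)
        shared = [l.taxon.label for l in ref.leaf_node_iter()
                  if l.taxon.label in locus_aln.rows]
        ref.retain_taxa_with_labels(shared)
        ref = LikTree.from_dendropy(ref)
    sub = locus_aln.subset([nd.name for nd in ref.leaves])

    constrained = optimize(ref, sub, model, tol=1e-4, max_rounds=10)
    # free search starts from the locus' own NJ tree; model parameters are
    # carried over from the constrained fit (shared nuisance parameters)
    free = _free_fit(sub, constrained.model)
    delta = max(free.log_likelihood - constrained.log_likelihood, 0.0)

    null_deltas = []
    for _ in range(n_bootstrap):
        sim = simulate_alignment(constrained.tree, constrained.model,
                                 sub.n_columns, seed=rng)
        c_fit = optimize(constrained.tree, sim, constrained.model,
                         free=("branch_lengths",), tol=1e-3, max_rounds=4)
        f_fit = _free_fit(sim, constrained.model, opt_tol=1e-3, opt_rounds=4)
        null_deltas.append(max(f_fit.log_likelihood - c_fit.log_likelihood,
                               0.0))
    p = (1 + sum(d >= delta for d in null_deltas)) / (1 + n_bootstrap)
    return CongruenceResult(locus_name=locus_aln.locus_name,
                            lnl_free=free.log_likelihood,
                            lnl_constrained=constrained.log_likelihood,
                            delta=delta, p_value=p, n_bootstrap=n_bootstrap,
                            null_deltas=null_deltas)
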