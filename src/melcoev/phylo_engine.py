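"""Nucleotide-level likelihood machinery: JC69 and HKY85+Gamma.

Implements the standard toolkit behind branch-length estimation and null
simulation: reversible rate matrices scaled to one expected substitution per
unit time, spectral transition probabilities, Felsenstein pruning with
per-node scaling, Yang's equal-probability discrete-Gamma rates, coordinate
ascent (Brent per branch, then kappa and alpha) on a fixed topology, and a
seeded sequence simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize
from scipy.stats import gamma as gamma_dist

from .seq_io import IUPAC, GeneAlignment
from .trees import Tree

NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# 4-vector of compatible states for every alignment symbol
SYMBOL_PARTIALS = {
    sym: np.array([1.0 if n in compat else 0.0 for n in "ACGT"])
    for sym, compat in IUPAC.items()
}

MIN_BLEN = 1e-8
MAX_BLEN = 20.0


class ModelParameterError(ValueError):
    pass


@dataclass
class PhyloModel:
    """Topology + branch lengths + HKY85(+Gamma) parameters."""

    tree: Tree
    kappa: float = 2.0
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    loglik: float | None = None

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, float)
        if self.kappa <= 0:
            raise ModelParameterError("kappa must be positive")
        if abs(self.base_freqs.sum() - 1.0) > 1e-8 or np.any(self.base_freqs <= 0):
            raise ModelParameterError("base_freqs must be a positive simplex point")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelParameterError("gamma shape must be positive")

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    def rate_matrix(self) -> np.ndarray:
        return hky_rate_matrix(self.kappa, self.base_freqs)


def hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """HKY85 generator scaled to one expected substitution per unit time.

    kappa = 1 with uniform frequencies reduces to JC69.
    """
    freqs = np.asarray(freqs, float)
    if kappa <= 0:
        raise ModelParameterError("kappa must be positive")
    if freqs.shape != (4,) or np.any(freqs <= 0) or abs(freqs.sum() - 1) > 1e-8:
        raise ModelParameterError("freqs must be a positive 4-simplex point")
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(freqs @ np.diag(Q))
    return Q / rate


def jc_rate_matrix() -> np.ndarray:
    return hky_rate_matrix(1.0, np.full(4, 0.25))


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, t = 0 gives the identity."""
    if t < 0:
        raise ModelParameterError("branch length must be non-negative")
    return linalg.expm(np.asarray(Q, float) * t)


def jc_transition(t: float, mu: float = 1.0 / 3.0) -> np.ndarray:
    """Closed-form JC69 transition matrix; ``mu`` is the per-target rate
    (mu = 1/3 gives one expected substitution per unit time)."""
    if t < 0:
        raise ModelParameterError("branch length must be non-negative")
    e = np.exp(-4.0 * mu * t)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    P = np.full((4, 4), p_diff)
    np.fill_diagonal(P, p_same)
    return P


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Category-mean rates of the equal-probability discrete Gamma(alpha, alpha).

    Mean of the returned rates is exactly 1 (renormalised mean-of-category
    conditional expectations).
    """
    if alpha <= 0:
        raise ModelParameterError("gamma shape must be positive")
    if ncat < 1:
        raise ModelParameterError("need at least one rate category")
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1 / alpha)
    # E[X; X in (a,b)] for Gamma(alpha, 1/alpha) via the shape+1 CDF trick
    upper = gamma_dist.cdf(edges[1:], a=alpha + 1, scale=1 / alpha)
    lower = gamma_dist.cdf(edges[:-1], a=alpha + 1, scale=1 / alpha)
    rates = (upper - lower) * ncat
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _spectral(Q: np.ndarray, freqs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetrised eigendecomposition of a reversible generator."""
    freqs = np.asarray(freqs, float)
    sq = np.sqrt(freqs)
    A = (Q * sq[:, None]) / sq[None, :]
    w, U = np.linalg.eigh((A + A.T) / 2.0)
    left = U / sq[:, None]
    right = U.T * sq[None, :]
    return w, left, right


def branch_transition_stack(Q: np.ndarray, freqs, lengths: np.ndarray) -> np.ndarray:
    """P(t_b) for every branch length in ``lengths`` -> (n, 4, 4)."""
    w, left, right = _spectral(Q, freqs)
    E = np.exp(np.outer(lengths, w))  # (n, 4)
    P = np.einsum("ik,nk,kj->nij", left, E, right)
    return np.clip(P, 0.0, None)


def leaf_partial_matrix(aln: GeneAlignment, leaf_names: list[str]) -> np.ndarray:
    """(n_leaves, n_sites, 4) partial-likelihood indicators.

    Gaps and ambiguity codes contribute 1 for every compatible state
    (missing-data convention).
    """
    index = {s: i for i, s in enumerate(aln.species)}
    missing = [nm for nm in leaf_names if nm not in index]
    if missing:
        raise ModelParameterError(
            f"species absent from alignment {aln.gene_name}: {missing[:5]}")
    out = np.empty((len(leaf_names), aln.width, 4))
    for k, nm in enumerate(leaf_names):
        row = aln.sequences[index[nm]]
        for j, ch in enumerate(row):
            out[k, j] = SYMBOL_PARTIALS.get(ch, SYMBOL_PARTIALS["N"])
    return out


def _prune_site_logliks(tree: Tree, P: np.ndarray, partials: np.ndarray,
                        root_dist: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood via postorder pruning with scaling.

    ``P``: (n_nodes, k, k) transition matrix above each node (root row unused);
    ``partials``: (n_leaves, n_sites, k).
    """
    n_sites = partials.shape[1]
    buf: dict[int, np.ndarray] = {}
    scale = np.zeros(n_sites)
    for v in tree.postorder():
        if not tree.children[v]:
            buf[v] = partials[v]
            continue
        L = np.ones((n_sites, root_dist.size))
        for c in tree.children[v]:
            L = L * (buf.pop(c) @ P[c].T)
        m = L.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        scale += np.log(m)
        buf[v] = L / m[:, None]
    root = buf[tree.root]
    site = root @ root_dist
    return np.log(np.clip(site, 1e-300, None)) + scale


def loglik_alignment(aln: GeneAlignment, model: PhyloModel,
                     pattern_compress: bool = True) -> float:
    """HKY85(+Gamma) log-likelihood of an alignment on the model's tree.

    Sites are averaged over equal-weight Gamma categories; gaps and
    ambiguity codes are missing data.
    """
    tree = model.tree
    partials = leaf_partial_matrix(aln, tree.leaf_names)
    counts = np.ones(aln.width)
    if pattern_compress:
        cols = np.array(["".join(aln.sequences[:, j]) for j in range(aln.width)])
        _, first, counts = np.unique(cols, return_index=True, return_counts=True)
        partials = partials[:, first, :]
    return float(_gamma_mixture_loglik(tree, model, partials) @ counts)


def _gamma_mixture_loglik(tree: Tree, model: PhyloModel,
                          partials: np.ndarray) -> np.ndarray:
    Q = model.rate_matrix()
    rates = model.category_rates
    per_cat = np.empty((rates.size, partials.shape[1]))
    for k, r in enumerate(rates):
        P = branch_transition_stack(Q, model.base_freqs, tree.blen * r)
        per_cat[k] = _prune_site_logliks(tree, P, partials, model.base_freqs)
    m = per_cat.max(axis=0)
    return m + np.log(np.mean(np.exp(per_cat - m), axis=0))


def empirical_base_freqs(aln: GeneAlignment) -> np.ndarray:
    counts = np.array([(aln.sequences == n).sum() for n in "ACGT"], float)
    counts = np.maximum(counts, 1.0)  # guard degenerate compositions
    return counts / counts.sum()


def optimize_branch_lengths(aln: GeneAlignment, topology: Tree,
                            kappa: float = 2.0, gamma_shape: float = 1.0,
                            n_rate_categories: int = 4,
                            estimate_kappa: bool = True,
                            estimate_alpha: bool = True,
                            base_freqs: np.ndarray | None = None,
                            tol: float = 1e-6, max_cycles: int = 20,
                            ) -> PhyloModel:
    """ML branch lengths (and optionally kappa, alpha) on a fixed topology.

    Coordinate ascent: Brent on each branch in turn, then on kappa and the
    Gamma shape, cycling until the log-likelihood improves by less than
    ``tol``.  The returned model carries the fitted tree and final
    log-likelihood; the trace is non-decreasing by construction.
    """
    if aln.n_species < 3:
        raise ModelParameterError("need at least 3 species")
    freqs = empirical_base_freqs(aln) if base_freqs is None else np.asarray(base_freqs)
    tree = topology.with_blen(np.clip(topology.blen, MIN_BLEN, MAX_BLEN))
    if np.all(topology.blen == 0):
        tree = topology.with_blen(np.full(topology.n_nodes, 0.1))
    tree.blen[tree.root] = 0.0

    partials = leaf_partial_matrix(aln, tree.leaf_names)
    cols = np.array(["".join(aln.sequences[:, j]) for j in range(aln.width)])
    _, first, counts = np.unique(cols, return_index=True, return_counts=True)
    partials = partials[:, first, :]

    state = {"kappa": kappa, "alpha": gamma_shape}

    def current_model() -> PhyloModel:
        return PhyloModel(tree, state["kappa"], freqs, state["alpha"],
                          n_rate_categories)

    def total_ll() -> float:
        return float(_gamma_mixture_loglik(tree, current_model(), partials) @ counts)

    if len({"".join(row) for row in aln.sequences}) == 1:
        warnings.warn("all sequences identical; branch lengths at lower bound")
        tree.blen[:] = MIN_BLEN
        tree.blen[tree.root] = 0.0
        model = current_model()
        model.loglik = total_ll()
        return model

    ll = total_ll()
    for _ in range(max_cycles):
        ll_start = ll
        for b in tree.branches:
            def f(x, b=b):
                tree.blen[b] = x
                return -total_ll()
            res = optimize.minimize_scalar(
                f, bounds=(MIN_BLEN, MAX_BLEN), method="bounded",
                options={"xatol": 1e-7})
            tree.blen[b] = res.x
            ll = -res.fun
        if estimate_kappa:
            def fk(x):
                state["kappa"] = x
                return -total_ll()
            res = optimize.minimize_scalar(fk, bounds=(0.05, 60.0),
                                           method="bounded",
                                           options={"xatol": 1e-5})
            state["kappa"] = res.x
            ll = -res.fun
        if estimate_alpha:
            def fa(x):
                state["alpha"] = x
                return -total_ll()
            res = optimize.minimize_scalar(fa, bounds=(0.05, 100.0),
                                           method="bounded",
                                           options={"xatol": 1e-5})
            state["alpha"] = res.x
            ll = -res.fun
        if ll - ll_start < tol:
            break
    model = current_model()
    model.loglik = ll
    return model


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _draw_states(P_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one categorical draw per row of ``P_rows`` (n, k)."""
    cdf = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0])
    return np.minimum((u[:, None] > cdf).sum(axis=1), P_rows.shape[1] - 1)


def simulate_alignment(model: PhyloModel, nsites: int, seed: int,
                       gene_name: str = "sim") -> GeneAlignment:
    """Simulate nucleotide sites on the model's rooted tree.

    Root states are drawn from the stationary distribution; per-site Gamma
    categories (if any) are drawn once and shared along the tree.
    """
    if nsites < 1:
        raise ModelParameterError("nsites must be >= 1")
    rng = np.random.default_rng(seed)
    tree = model.tree
    Q = model.rate_matrix()
    rates = model.category_rates
    cat = rng.integers(0, rates.size, size=nsites)
    states = np.empty((tree.n_nodes, nsites), dtype=np.int64)
    states[tree.root] = _draw_states(
        np.tile(model.base_freqs, (nsites, 1)), rng)
    for v in tree.preorder():
        if tree.parent[v] < 0:
            continue
        for k, r in enumerate(rates):
            mask = cat == k
            if not mask.any():
                continue
            P = transition_probabilities(Q, tree.blen[v] * r)
            states[v, mask] = _draw_states(P[states[tree.parent[v], mask]], rng)
    letters = np.array(list("ACGT"))
    matrix = letters[states[: tree.n_leaves]]
    return GeneAlignment(gene_name=gene_name, species=list(tree.leaf_names),
                         sequences=matrix)
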