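"""Pairwise inter-gene coevolution scoring.

The coevolution (Coev-style) model treats a pair of nucleotide positions
as a single 16-state Markov chain over dinucleotides.
A *profile* — two dinucleotide states differing at both positions — defines
the favoured combinations; single-position substitutions into a profile
state occur at rate ``s``, all other single-position substitutions at rate
``d``, and double substitutions are forbidden.  The null model evolves the
two positions independently under unit-rate JC69 with branch lengths fixed
from the concatenated alignment, and has no free parameters; the coevolution
model has two (s, d).  Support for coevolution is measured by
``delta_aic = AIC_indep - AIC_coev = 2 (lnL_coev - lnL_indep) - 4``,
with significance thresholds taken from the empirical percentiles of the
same statistic on data simulated under the independent model.

Maximum likelihood over (s, d) is evaluated on a fixed logarithmic grid of
(s/d, d).  Because the generator can be written ``Q = d (rho A + B)`` with
``rho = s/d``, and every profile is a per-position nucleotide relabelling of
the canonical profile {AA, CC}, one family of 16x16 eigensystems indexed by
rho serves every pair; the scan then reduces to batched matrix products
shared by all pairs on a tree.  The same grid estimator is used for the
null calibration and for the data, so thresholds are internally consistent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg

from .phylo_engine import SYMBOL_PARTIALS, _prune_site_logliks, jc_transition
from .seq_io import PairedAlignment
from .trees import Tree

NUCS = "ACGT"
NUC_IDX = {n: i for i, n in enumerate(NUCS)}
K_COEV = 2
K_INDEP = 0
INFEASIBLE = -np.inf  # delta_aic sentinel for profile-infeasible pairs

DEFAULT_RHO_GRID = 2.0 ** np.linspace(-6, 9, 31)
DEFAULT_D_GRID = 2.0 ** np.linspace(-9, 4, 27)


class CoevError(ValueError):
    pass


@dataclass(frozen=True)
class CoevProfile:
    """Two dinucleotide states (as 2-letter strings) differing at both
    positions; ``state1 < state2`` lexicographically."""

    state1: str
    state2: str

    def __post_init__(self) -> None:
        a, b = self.state1, self.state2
        if len(a) != 2 or len(b) != 2 or a[0] == b[0] or a[1] == b[1]:
            raise CoevError(f"invalid profile ({a}, {b}): "
                            "states must differ at both positions")
        if not a < b:
            raise CoevError("profile states must be in lexicographic order")

    @property
    def state_indices(self) -> tuple[int, int]:
        a, b = self.state1, self.state2
        return (4 * NUC_IDX[a[0]] + NUC_IDX[a[1]],
                4 * NUC_IDX[b[0]] + NUC_IDX[b[1]])


@dataclass
class CoevFit:
    profile: CoevProfile
    s: float
    d: float
    loglik: float
    k: int = K_COEV

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


@dataclass
class CoevPairResult:
    site_a: tuple[str, int]
    site_b: tuple[str, int]
    coev: CoevFit | None
    loglik_indep: float
    k_indep: int = K_INDEP

    @property
    def aic_indep(self) -> float:
        return 2.0 * self.k_indep - 2.0 * self.loglik_indep

    @property
    def delta_aic(self) -> float:
        if self.coev is None:
            return INFEASIBLE
        return self.aic_indep - self.coev.aic

    def is_coevolving(self, threshold: float) -> bool:
        return self.delta_aic > threshold


# ---------------------------------------------------------------------------
# profile selection and canonicalisation
# ---------------------------------------------------------------------------

def encode_column(column) -> np.ndarray:
    """Integer codes (0..3) with -1 for gaps/ambiguity symbols."""
    return np.array([NUC_IDX.get(c, -1) for c in column], dtype=np.int64)


def select_profile(col_a, col_b) -> CoevProfile | None:
    """Most frequent pair of observed dinucleotide states differing at both
    positions; ties broken lexicographically.  None when infeasible."""
    ca, cb = encode_column(col_a), encode_column(col_b)
    ok = (ca >= 0) & (cb >= 0)
    if not ok.any():
        return None
    dinuc = 4 * ca[ok] + cb[ok]
    counts = np.bincount(dinuc, minlength=16)
    observed = np.where(counts > 0)[0]
    best: tuple[int, str, str] | None = None
    for x, y in combinations(sorted(observed), 2):
        if x // 4 == y // 4 or x % 4 == y % 4:
            continue
        sx = NUCS[x // 4] + NUCS[x % 4]
        sy = NUCS[y // 4] + NUCS[y % 4]
        if sy < sx:
            sx, sy = sy, sx
        cand = (-int(counts[x] + counts[y]), sx, sy)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return CoevProfile(best[1], best[2])


def profile_permutations(profile: CoevProfile) -> tuple[np.ndarray, np.ndarray]:
    """Per-position nucleotide permutations sigma with
    ``sigma1[x1] = 0, sigma1[x2] = 1`` (likewise position 2), mapping the
    profile onto the canonical {AA, CC}."""
    perms = []
    for pos in range(2):
        a = NUC_IDX[profile.state1[pos]]
        b = NUC_IDX[profile.state2[pos]]
        rest = [i for i in range(4) if i not in (a, b)]
        sigma = np.empty(4, dtype=np.int64)
        sigma[a], sigma[b] = 0, 1
        sigma[rest[0]], sigma[rest[1]] = 2, 3
        perms.append(sigma)
    return perms[0], perms[1]


def _structure_matrices(profile_states: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """A (targets in profile) and B (targets outside) adjacency matrices of
    single-position dinucleotide changes, without diagonals."""
    A = np.zeros((16, 16))
    B = np.zeros((16, 16))
    for x in range(16):
        x1, x2 = divmod(x, 4)
        for y in range(16):
            if x == y:
                continue
            y1, y2 = divmod(y, 4)
            if (x1 == y1) == (x2 == y2):  # double change or identical
                continue
            if y in profile_states:
                A[x, y] = 1.0
            else:
                B[x, y] = 1.0
    return A, B


def coev_rate_matrix(profile: CoevProfile, s: float, d: float) -> np.ndarray:
    """16x16 generator in original dinucleotide coordinates."""
    if s < 0 or d < 0:
        raise CoevError("rates must be non-negative")
    A, B = _structure_matrices(profile.state_indices)
    Q = s * A + d * B
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def pair_leaf_partials(col_a, col_b, profile: CoevProfile) -> np.ndarray:
    """(n_leaves, 16) partials in canonical coordinates; gaps/ambiguities at
    either position marginalise over the compatible dinucleotides."""
    s1, s2 = profile_permutations(profile)
    n = len(col_a)
    out = np.empty((n, 16))
    for i in range(n):
        u = SYMBOL_PARTIALS.get(col_a[i], SYMBOL_PARTIALS["N"])
        v = SYMBOL_PARTIALS.get(col_b[i], SYMBOL_PARTIALS["N"])
        p1 = np.empty(4)
        p2 = np.empty(4)
        p1[s1] = u
        p2[s2] = v
        out[i] = np.outer(p1, p2).ravel()
    return out


# ---------------------------------------------------------------------------
# independent (null) model
# ---------------------------------------------------------------------------

def jc_site_logliks(tree: Tree, partials: np.ndarray,
                    mu: float = 1.0 / 3.0) -> np.ndarray:
    """Unit-rate JC69 per-site log-likelihoods (``mu``: per-target rate)."""
    P = np.stack([jc_transition(t, mu) for t in tree.blen])
    return _prune_site_logliks(tree, P, partials, np.full(4, 0.25))


def column_partials(columns: np.ndarray) -> np.ndarray:
    """(n_leaves, n_cols, 4) partials for a character matrix (n_leaves, n_cols)."""
    n, m = columns.shape
    out = np.empty((n, m, 4))
    for i in range(n):
        for j in range(m):
            out[i, j] = SYMBOL_PARTIALS.get(columns[i, j], SYMBOL_PARTIALS["N"])
    return out


def fit_independent_pair(col_a, col_b, tree: Tree) -> tuple[float, int, float]:
    """(loglik, k, AIC) of the two-site independent JC69 null."""
    cols = np.stack([np.asarray(col_a), np.asarray(col_b)], axis=1)
    ll = float(jc_site_logliks(tree, column_partials(cols)).sum())
    return ll, K_INDEP, 2.0 * K_INDEP - 2.0 * ll


# ---------------------------------------------------------------------------
# grid engine
# ---------------------------------------------------------------------------

class CoevEngine:
    """Shared precomputation for scoring many site pairs on one tree.

    Precomputes, for every (rho = s/d, d) grid point and every branch, the
    16-state transition matrix of the canonical-profile chain.  All pairs on
    the tree are then scored by batched pruning over the grid.
    """

    def __init__(self, tree: Tree, rho_grid: np.ndarray | None = None,
                 d_grid: np.ndarray | None = None):
        self.tree = tree
        self.rho_grid = np.asarray(
            DEFAULT_RHO_GRID if rho_grid is None else rho_grid, float)
        self.d_grid = np.asarray(
            DEFAULT_D_GRID if d_grid is None else d_grid, float)
        self._canonical_states = CoevProfile("AA", "CC").state_indices
        A, B = _structure_matrices(self._canonical_states)
        R, D = len(self.rho_grid), len(self.d_grid)
        n_nodes = tree.n_nodes
        self.grid_s = np.repeat(self.rho_grid, D) * np.tile(self.d_grid, R)
        self.grid_d = np.tile(self.d_grid, R)
        # transition matrices on the grid; the batched grid path runs in
        # single precision (per-node rescaling keeps it accurate), the exact
        # per-pair evaluator stays in double precision
        self.G = R * D
        P = np.empty((n_nodes, R * D, 16, 16), dtype=np.float32)
        t_all = np.outer(self.d_grid, tree.blen).ravel()  # (D * n_nodes,)
        for r, rho in enumerate(self.rho_grid):
            M = rho * A + B
            np.fill_diagonal(M, -M.sum(axis=1))
            w, V = linalg.eig(M)
            Vinv = linalg.inv(V)
            E = np.exp(np.outer(t_all, w))  # (D*n_nodes, 16) complex
            Pr = np.matmul(V[None, :, :] * E[:, None, :], Vinv).real
            Pr = Pr.reshape(len(self.d_grid), n_nodes, 16, 16)
            P[:, r * D:(r + 1) * D] = np.clip(Pr, 0.0, None).transpose(1, 0, 2, 3)
        # PT[v, g] = P[v, g].T for internal-node children (batched matmul);
        # PT_wide[v] = (16, G*16) layout for leaf children (one large GEMM)
        self.PT = np.ascontiguousarray(P.transpose(0, 1, 3, 2))
        self.PT_wide = np.ascontiguousarray(
            self.PT.transpose(0, 2, 1, 3).reshape(n_nodes, 16, R * D * 16))

    # -- likelihood over the grid ---------------------------------------
    def _grid_logliks(self, partials: np.ndarray) -> np.ndarray:
        """(n_pairs, G) log-likelihoods; ``partials``: (n_pairs, n_leaves, 16)."""
        tree = self.tree
        C = partials.shape[0]
        G = self.G
        partials = partials.astype(np.float32)
        buf: dict[int, np.ndarray] = {}
        scale = np.zeros((G, C), dtype=np.float32)
        for v in tree.postorder():
            if not tree.children[v]:
                continue
            L: np.ndarray | None = None
            for c in tree.children[v]:
                if not tree.children[c]:
                    # leaf partials are shared across the grid: one large GEMM
                    X = (partials[:, c] @ self.PT_wide[c])
                    X = X.reshape(C, G, 16).transpose(1, 0, 2)
                else:
                    X = np.matmul(buf.pop(c), self.PT[c])
                L = X if L is None else L * X
            m = L.max(axis=2)
            m = np.where(m > 0, m, np.float32(1.0))
            scale += np.log(m)
            buf[v] = L / m[:, :, None]
        root = buf[self.tree.root]
        ll = np.log(np.clip(root.sum(axis=2), 1e-30, None)) - np.log(16.0) + scale
        return ll.T.astype(np.float64)  # (C, G)

    def fit_pairs(self, partials: np.ndarray,
                  chunk: int = 64) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Grid-ML fit of many pairs -> (loglik, s_hat, d_hat)."""
        n = partials.shape[0]
        ll = np.empty(n)
        s_hat = np.empty(n)
        d_hat = np.empty(n)
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            grid_ll = self._grid_logliks(partials[lo:hi])
            best = np.argmax(grid_ll, axis=1)
            ll[lo:hi] = grid_ll[np.arange(hi - lo), best]
            s_hat[lo:hi] = self.grid_s[best]
            d_hat[lo:hi] = self.grid_d[best]
        return ll, s_hat, d_hat


def coev_pair_loglik(col_a, col_b, tree: Tree, profile: CoevProfile,
                     s: float, d: float) -> float:
    """Exact 16-state log-likelihood at given rates (expm per branch);
    root distribution uniform over the 16 dinucleotides."""
    Q = coev_rate_matrix(profile, s, d)
    # original-coordinate partials: identity permutations via canonical map
    s1, s2 = profile_permutations(profile)
    n = len(col_a)
    partials = np.empty((n, 1, 16))
    for i in range(n):
        u = SYMBOL_PARTIALS.get(col_a[i], SYMBOL_PARTIALS["N"])
        v = SYMBOL_PARTIALS.get(col_b[i], SYMBOL_PARTIALS["N"])
        partials[i, 0] = np.outer(u, v).ravel()
    P = np.stack([linalg.expm(Q * t) for t in tree.blen])
    ll = _prune_site_logliks(tree, P, partials, np.full(16, 1.0 / 16.0))
    return float(ll[0])


def fit_coev_pair(col_a, col_b, tree: Tree,
                  engine: CoevEngine | None = None) -> CoevFit | None:
    """Grid-ML fit of one pair; None when profile-infeasible."""
    profile = select_profile(col_a, col_b)
    if profile is None:
        return None
    if engine is None:
        engine = CoevEngine(tree)
    partials = pair_leaf_partials(col_a, col_b, profile)[None]
    ll, s_hat, d_hat = engine.fit_pairs(partials)
    return CoevFit(profile, float(s_hat[0]), float(d_hat[0]), float(ll[0]))


# ---------------------------------------------------------------------------
# scanning and calibration
# ---------------------------------------------------------------------------

def score_site_pairs(cols_a: np.ndarray, cols_b: np.ndarray,
                     pair_index: np.ndarray, tree: Tree,
                     engine: CoevEngine) -> pd.DataFrame:
    """Score pairs (i, j) of columns from two matrices.

    ``cols_a``/``cols_b``: (n_leaves, n_cols) character matrices in the
    tree's leaf order; ``pair_index``: (n_pairs, 2) column indices.
    """
    ll_a = jc_site_logliks(tree, column_partials(cols_a))
    if cols_b is cols_a:
        ll_b = ll_a
    else:
        ll_b = jc_site_logliks(tree, column_partials(cols_b))
    n = len(pair_index)
    profiles: list[CoevProfile | None] = []
    partials = []
    for i, j in pair_index:
        prof = select_profile(cols_a[:, i], cols_b[:, j])
        profiles.append(prof)
        if prof is not None:
            partials.append(pair_leaf_partials(cols_a[:, i], cols_b[:, j], prof))
    feasible = np.array([p is not None for p in profiles])
    ll_coev = np.full(n, np.nan)
    s_hat = np.full(n, np.nan)
    d_hat = np.full(n, np.nan)
    if partials:
        ll_f, s_f, d_f = engine.fit_pairs(np.stack(partials))
        ll_coev[feasible] = ll_f
        s_hat[feasible] = s_f
        d_hat[feasible] = d_f
    ll_indep = ll_a[pair_index[:, 0]] + ll_b[pair_index[:, 1]]
    delta = np.where(feasible, 2.0 * (ll_coev - ll_indep) - 2.0 * K_COEV,
                     INFEASIBLE)
    return pd.DataFrame({
        "col_a": pair_index[:, 0], "col_b": pair_index[:, 1],
        "profile": [f"{p.state1}/{p.state2}" if p else "" for p in profiles],
        "s": s_hat, "d": d_hat,
        "loglik_coev": ll_coev, "loglik_indep": ll_indep,
        "delta_aic": delta,
    })


def scan_gene_pair(paired: PairedAlignment, tree: Tree,
                   engine: CoevEngine | None = None) -> pd.DataFrame:
    """Score every inter-molecular site pair of a paired alignment.

    The tree must carry branch lengths estimated from the concatenated
    two-gene alignment; its leaves must match the shared species.
    """
    rows = [paired.shared_species.index(nm) for nm in tree.leaf_names]
    mat_a = paired.gene_a.sequences[rows]
    mat_b = paired.gene_b.sequences[rows]
    if engine is None:
        engine = CoevEngine(tree)
    wa, wb = paired.gene_a.width, paired.gene_b.width
    pair_index = np.array(np.meshgrid(np.arange(wa), np.arange(wb),
                                      indexing="ij")).reshape(2, -1).T
    out = score_site_pairs(mat_a, mat_b, pair_index, tree, engine)
    out.insert(0, "site_b_gene", paired.gene_b.gene_name)
    out.insert(0, "site_a_gene", paired.gene_a.gene_name)
    out["orig_col_a"] = paired.gene_a.orig_columns[out["col_a"].to_numpy()]
    out["orig_col_b"] = paired.gene_b.orig_columns[out["col_b"].to_numpy()]
    return out


@dataclass
class NullCalibration:
    """Empirical dAIC null distribution and its percentile thresholds."""

    sample: np.ndarray
    thresholds: dict[str, float]
    seed: int
    nsites: int
    tree_newick: str = ""

    def threshold(self, percentile) -> float:
        return self.thresholds[f"{float(percentile):g}"]

    def to_json(self, path=None) -> str:
        finite = self.sample[np.isfinite(self.sample)]
        payload = json.dumps({
            "thresholds": self.thresholds,
            "seed": self.seed,
            "nsites": self.nsites,
            "n_pairs": int(len(self.sample)),
            "n_feasible": int(len(finite)),
            "sample_mean": float(finite.mean()) if len(finite) else None,
            "sample_max": float(finite.max()) if len(finite) else None,
            "k_coev": K_COEV, "k_indep": K_INDEP,
            "tree": self.tree_newick,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def null_pair_index(nsites: int, n_pairs: int | None,
                    rng: np.random.Generator) -> np.ndarray:
    """All unordered site pairs, or a random subsample of them."""
    idx = np.array(list(combinations(range(nsites), 2)))
    if n_pairs is not None and n_pairs < len(idx):
        keep = rng.choice(len(idx), size=n_pairs, replace=False)
        idx = idx[np.sort(keep)]
    return idx


def simulate_null_columns(tree: Tree, nsites: int, seed: int) -> np.ndarray:
    """JC69 alignment matrix (n_leaves, nsites) in tree leaf order."""
    from .phylo_engine import PhyloModel, simulate_alignment
    model = PhyloModel(tree, kappa=1.0, base_freqs=np.full(4, 0.25),
                       gamma_shape=None)
    sim = simulate_alignment(model, nsites, seed)
    return sim.sequences


def calibrate_null(tree: Tree, nsites: int = 200, seed: int = 0,
                   n_pairs: int | None = None,
                   percentiles=(90, 95, 97.5),
                   engine: CoevEngine | None = None) -> NullCalibration:
    """Simulate one JC69 alignment on the tree and build the dAIC null.

    Thresholds are the empirical percentiles of the dAIC sample over site
    pairs of the simulated alignment (all unordered pairs by default).
    """
    if engine is None:
        engine = CoevEngine(tree)
    rng = np.random.default_rng(seed)
    cols = simulate_null_columns(tree, nsites, seed)
    idx = null_pair_index(nsites, n_pairs, rng)
    res = score_site_pairs(cols, cols, idx, tree, engine)
    sample = res["delta_aic"].to_numpy()
    finite = sample[np.isfinite(sample)]
    if len(finite) < 10:
        warnings.warn("very few feasible null pairs; thresholds unreliable")
    # percentiles over the full sample (infeasible pairs keep their -inf
    # sentinel and can never exceed a threshold), so that by construction a
    # nominal fraction of *all* null pairs scores above each threshold
    thresholds = {f"{float(p):g}": float(np.percentile(sample, p))
                  for p in sorted(percentiles)}
    return NullCalibration(sample, thresholds, seed, nsites,
                           tree.to_newick())


# ---------------------------------------------------------------------------
# marginal ancestral reconstruction for the fitted pair chain
# ---------------------------------------------------------------------------

def pair_substitution_branches(col_a, col_b, tree: Tree,
                               profile: CoevProfile, s: float, d: float
                               ) -> np.ndarray:
    """Marginal-reconstruction substitution calls per branch.

    Returns a boolean (n_nodes, 2) array: entry [v, p] is True when the
    marginally most probable state at position p changes along the branch
    above node v (root row False).
    """
    Q = coev_rate_matrix(profile, s, d)
    P = np.stack([linalg.expm(Q * t) for t in tree.blen])
    n = tree.n_nodes
    down = np.empty((n, 16))
    for i in range(tree.n_leaves):
        u = SYMBOL_PARTIALS.get(col_a[i], SYMBOL_PARTIALS["N"])
        v = SYMBOL_PARTIALS.get(col_b[i], SYMBOL_PARTIALS["N"])
        down[i] = np.outer(u, v).ravel()
    for v in tree.postorder():
        if not tree.children[v]:
            continue
        L = np.ones(16)
        for c in tree.children[v]:
            L = L * (P[c] @ down[c])
        down[v] = L / max(L.max(), 1e-300)
    up = np.empty((n, 16))
    up[tree.root] = 1.0 / 16.0
    for v in tree.preorder():
        for c in tree.children[v]:
            above = up[v].copy()
            for sib in tree.children[v]:
                if sib != c:
                    above = above * (P[sib] @ down[sib])
            u = above @ P[c]
            up[c] = u / max(u.max(), 1e-300)
    post = up * down
    post /= np.maximum(post.sum(axis=1, keepdims=True), 1e-300)
    pos1 = post.reshape(n, 4, 4).sum(axis=2).argmax(axis=1)
    pos2 = post.reshape(n, 4, 4).sum(axis=1).argmax(axis=1)
    calls = np.stack([pos1, pos2], axis=1)
    changed = np.zeros((n, 2), dtype=bool)
    for v in range(n):
        p = tree.parent[v]
        if p >= 0:
            changed[v] = calls[v] != calls[p]
    return changed
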