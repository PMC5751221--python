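"""Per-codon test for episodic positive selection (MEME-style).

Each codon site is fitted with an MG94-style codon model built on HKY85
nucleotide exchangeabilities (one-step codon changes only, uniform codon
frequencies).  The alternative model mixes two dN/dS classes *per branch*:
every branch independently draws omega_minus (<= 1, weight p_minus) or
omega_plus (weight 1 - p_minus); marginalising the branch assignments makes
the per-branch transition matrix a mixture of the two class matrices.  The
null constrains omega_plus <= 1.  Sites are tested with a boundary-corrected
LRT (50:50 chi2_0 : chi2_2 mixture), corrected across sites by
Benjamini-Hochberg, and classified positive / purifying / neutral /
ambiguous.  Branches carrying an episode are attributed by empirical-Bayes
factors (posterior versus prior odds of the omega_plus class; BF > 1 counts
the branch).

Likelihoods are profiled on a fixed parameter grid (omega values x mixture
weights) shared by all sites of a gene, evaluated with batched pruning; the
null and alternative maxima are taken over nested subsets of the same grid,
so the LRT is non-negative by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .trees import Tree

# --- genetic code ----------------------------------------------------------
_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS = sorted(c for c in _TABLE.forward_table)  # 61 sense codons
CODON_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO = np.array([_TABLE.forward_table[c] for c in SENSE_CODONS])
STOPS = set(_TABLE.stop_codons)
N_CODONS = len(SENSE_CODONS)

OMEGA_LE1 = (0.0, 0.0625, 0.125, 0.25, 0.5, 0.75, 1.0)
OMEGA_GT1 = (1.5, 2.5, 4.0, 8.0, 16.0)
DEFAULT_OMEGA_GRID = OMEGA_LE1 + OMEGA_GT1
DEFAULT_P_GRID = tuple(np.linspace(0.0, 1.0, 13))


class SelectionError(ValueError):
    pass


def _codon_adjacency() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(synonymous-single, transition, single-change) boolean codon-exchange
    masks; kappa and omega weights are folded in by the rate-matrix builder."""
    ti = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    is_transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    syn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                continue
            single[i, j] = True
            is_transition[i, j] = (a[diff[0]], b[diff[0]]) in ti
            syn[i, j] = AMINO[i] == AMINO[j]
    return single & syn, is_transition, single


_SYN_MASK, _TI_MASK, _SINGLE_MASK = _codon_adjacency()


def mg94_rate_matrix(kappa: float, omega: float) -> np.ndarray:
    """MG94xHKY generator (uniform codon frequencies), scaled so that the
    neutral model (omega = 1) evolves at one expected nucleotide
    substitution per site per unit time."""
    if kappa <= 0 or omega < 0:
        raise SelectionError("kappa must be > 0 and omega >= 0")

    def raw(om: float) -> np.ndarray:
        Q = np.where(_SINGLE_MASK, np.where(_TI_MASK, kappa, 1.0), 0.0)
        Q = Q * np.where(_SYN_MASK, 1.0, om)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    neutral_rate = -np.mean(np.diag(raw(1.0)))  # per codon at omega = 1
    return raw(omega) / (neutral_rate / 3.0)


def codon_column_partials(codon_column) -> np.ndarray:
    """(n_species, 61) partials for one codon column.

    Codons with gaps, ambiguity codes or stop codons are treated as missing
    data (all-ones partial).
    """
    out = np.ones((len(codon_column), N_CODONS))
    for i, codon in enumerate(codon_column):
        idx = CODON_IDX.get(codon)
        if idx is not None:
            out[i] = 0.0
            out[i, idx] = 1.0
    return out


def extract_codon_columns(aln) -> list[np.ndarray]:
    """Codon-string columns of an in-frame (trimmed) alignment."""
    if aln.width % 3 != 0:
        raise SelectionError(
            f"alignment width {aln.width} is not a multiple of 3")
    cols = []
    for c in range(aln.width // 3):
        block = aln.sequences[:, 3 * c:3 * c + 3]
        cols.append(np.array(["".join(row) for row in block]))
    return cols


# ---------------------------------------------------------------------------
# grid engine
# ---------------------------------------------------------------------------

@dataclass
class SiteFit:
    """Grid-profiled fit of one codon site."""

    loglik_alt: float
    loglik_null: float
    loglik_pur_free: float
    loglik_neutral: float
    omega_minus: float
    omega_plus: float
    p_minus: float


class CodonEngine:
    """Precomputed per-branch transition matrices on an omega grid."""

    def __init__(self, tree: Tree, kappa: float = 2.0,
                 omega_grid=DEFAULT_OMEGA_GRID, p_grid=DEFAULT_P_GRID):
        self.tree = tree
        self.kappa = kappa
        self.omega_grid = np.asarray(omega_grid, float)
        self.p_grid = np.asarray(p_grid, float)
        self.n_le1 = int((self.omega_grid <= 1.0).sum())
        if not np.all(np.diff(self.omega_grid) > 0) or self.omega_grid[self.n_le1 - 1] != 1.0:
            raise SelectionError("omega grid must be increasing and contain 1.0")
        # P[w][v]: transition matrix above node v for omega_grid[w]
        self.P = np.empty((len(self.omega_grid), tree.n_nodes,
                           N_CODONS, N_CODONS))
        for w, om in enumerate(self.omega_grid):
            Q = mg94_rate_matrix(kappa, om)
            vals, vecs = np.linalg.eigh(Q)  # symmetric under uniform freqs
            E = np.exp(np.outer(tree.blen, vals))
            self.P[w] = np.clip(
                np.einsum("ik,nk,kj->nij", vecs, E, vecs.T), 0.0, None)
        self._combos = self._build_combos()

    def _build_combos(self) -> list[tuple[int, int, float]]:
        """(omega_minus index, omega_plus index, p_minus) grid, deduplicated
        at the p boundaries where one class has zero weight."""
        combos = []
        for p in self.p_grid:
            if p == 1.0:
                combos += [(i, i, 1.0) for i in range(self.n_le1)]
            elif p == 0.0:
                combos += [(0, j, 0.0) for j in range(len(self.omega_grid))]
            else:
                combos += [(i, j, float(p))
                           for i in range(self.n_le1)
                           for j in range(len(self.omega_grid))]
        return combos

    def _mixed_site_logliks(self, partials: np.ndarray, i: int, j: int,
                            p: float) -> np.ndarray:
        """Pruning with per-branch mixture P = p P(w_i) + (1-p) P(w_j);
        ``partials``: (n_leaves, n_sites, 61) -> per-site loglik."""
        tree = self.tree
        n_sites = partials.shape[1]
        buf: dict[int, np.ndarray] = {}
        scale = np.zeros(n_sites)
        for v in tree.postorder():
            if not tree.children[v]:
                buf[v] = partials[v]
                continue
            L = np.ones((n_sites, N_CODONS))
            for c in tree.children[v]:
                Pmix = p * self.P[i, c] + (1.0 - p) * self.P[j, c]
                L = L * (buf.pop(c) @ Pmix.T)
            m = L.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            scale += np.log(m)
            buf[v] = L / m[:, None]
        root = buf[tree.root]
        return np.log(np.clip(root.mean(axis=1), 1e-300, None)) + scale

    def fit_sites(self, partials: np.ndarray) -> list[SiteFit]:
        """Grid-profile the mixture likelihood for many sites at once."""
        n_sites = partials.shape[1]
        combo_ll = np.empty((len(self._combos), n_sites))
        for k, (i, j, p) in enumerate(self._combos):
            combo_ll[k] = self._mixed_site_logliks(partials, i, j, p)
        omega = self.omega_grid
        alt_mask = np.ones(len(self._combos), dtype=bool)
        null_mask = np.array([omega[j] <= 1.0 for (_, j, _) in self._combos])
        pur_mask = np.array([p == 1.0 for (_, _, p) in self._combos])
        neutral_mask = np.array([p == 1.0 and omega[i] == 1.0
                                 for (i, _, p) in self._combos])
        fits = []
        for site in range(n_sites):
            ll = combo_ll[:, site]
            best = int(np.argmax(np.where(alt_mask, ll, -np.inf)))
            i, j, p = self._combos[best]
            fits.append(SiteFit(
                loglik_alt=float(ll[best]),
                loglik_null=float(ll[null_mask].max()),
                loglik_pur_free=float(ll[pur_mask].max()),
                loglik_neutral=float(ll[neutral_mask].max()),
                omega_minus=float(omega[i]), omega_plus=float(omega[j]),
                p_minus=float(p)))
        return fits

    def branch_bayes_factors(self, partial: np.ndarray,
                             fit: SiteFit) -> np.ndarray:
        """Empirical-Bayes factor per branch for the omega_plus class.

        ``partial``: (n_leaves, 61) for one site.  BF is posterior odds of
        the plus-class assignment over prior odds (1-p_minus)/p_minus.
        Returns NaN for the root entry.
        """
        p = fit.p_minus
        if p in (0.0, 1.0):
            warnings.warn("degenerate mixture weight: Bayes factors undefined")
            return np.full(self.tree.n_nodes, np.nan)
        i = int(np.searchsorted(self.omega_grid, fit.omega_minus))
        j = int(np.searchsorted(self.omega_grid, fit.omega_plus))
        base = self._mixed_site_logliks(partial[:, None, :], i, j, p)[0]
        bf = np.full(self.tree.n_nodes, np.nan)
        prior_odds = (1.0 - p) / p
        for b in self.tree.branches:
            ll_forced = self._forced_branch_loglik(partial, i, j, p, b)
            post = (1.0 - p) * np.exp(min(ll_forced - base, 700.0))
            post = min(post, 1.0 - 1e-12)
            bf[b] = (post / (1.0 - post)) / prior_odds
        return bf

    def _forced_branch_loglik(self, partial: np.ndarray, i: int, j: int,
                              p: float, branch: int) -> float:
        tree = self.tree
        buf: dict[int, np.ndarray] = {}
        scale = 0.0
        for v in tree.postorder():
            if not tree.children[v]:
                buf[v] = partial[v]
                continue
            L = np.ones(N_CODONS)
            for c in tree.children[v]:
                if c == branch:
                    Pc = self.P[j, c]
                else:
                    Pc = p * self.P[i, c] + (1.0 - p) * self.P[j, c]
                L = L * (Pc @ buf.pop(c))
            m = max(L.max(), 1e-300)
            scale += np.log(m)
            buf[v] = L / m
        return float(np.log(max(buf[tree.root].mean(), 1e-300)) + scale)


# ---------------------------------------------------------------------------
# tests, FDR, classification
# ---------------------------------------------------------------------------

def site_lrt(null_ll: float, alt_ll: float, df: int = 2) -> tuple[float, float]:
    """Boundary-corrected LRT: p from a 50:50 chi2_0 : chi2_df mixture."""
    if alt_ll < null_ll - 1e-6:
        raise SelectionError("alternative log-likelihood below null")
    lrt = max(0.0, 2.0 * (alt_ll - null_ll))
    p = 1.0 if lrt == 0.0 else 0.5 * float(chi2.sf(lrt, df))
    return lrt, p


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey's q-values with a single lambda (optional alternative to BH)."""
    p = np.asarray(p_values, float)
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, pi0 * p[idx] * m / rank)
        q[idx] = prev
    return q


def parsimony_substitutions(codon_column, tree: Tree) -> int:
    """Fitch parsimony count of codon changes (missing codons = wildcard)."""
    full = frozenset(range(N_CODONS))
    sets: dict[int, frozenset[int]] = {}
    count = 0
    for i, codon in enumerate(codon_column):
        idx = CODON_IDX.get(codon)
        sets[i] = full if idx is None else frozenset([idx])
    for v in tree.postorder():
        if not tree.children[v]:
            continue
        inter = full
        union: frozenset[int] = frozenset()
        for c in tree.children[v]:
            inter = inter & sets[c]
            union = union | sets[c]
        if inter:
            sets[v] = inter
        else:
            sets[v] = union
            count += 1
    return count


CATEGORIES = ("positive", "purifying", "neutral", "ambiguous")


@dataclass
class SiteSelectionCall:
    codon_index: int
    lrt_stat: float = 0.0
    p_value: float = 1.0
    q_value: float = 1.0
    lrt_pur: float = 0.0
    p_pur: float = 1.0
    q_pur: float = 1.0
    category: str = "ambiguous"
    omega_plus: float = np.nan
    omega_minus: float = np.nan
    p_minus: float = np.nan
    n_usable: int = 0
    n_substitutions: int = 0
    branch_bayes_factors: np.ndarray | None = field(default=None, repr=False)
    branches_selected: frozenset[int] = frozenset()


def classify_site(call: SiteSelectionCall, fdr_level: float = 0.05,
                  min_substitutions: int = 1) -> str:
    """Positive / purifying / neutral / ambiguous decision rule."""
    if call.n_usable < 3:
        return "ambiguous"
    if call.q_value < fdr_level and call.omega_plus > 1.0:
        return "positive"
    if call.q_pur < fdr_level:
        return "purifying"
    if call.n_substitutions >= min_substitutions:
        return "neutral"
    return "ambiguous"


def analyze_gene(codon_columns: list[np.ndarray], tree: Tree,
                 kappa: float = 2.0, fdr_level: float = 0.05,
                 engine: CodonEngine | None = None,
                 compute_bayes_factors: bool = True,
                 codon_indices: list[int] | None = None
                 ) -> list[SiteSelectionCall]:
    """Fit and classify every codon site of a gene.

    ``codon_columns``: per-site arrays of 3-letter codon strings in the
    tree's leaf order.  FDR correction is applied across the gene's testable
    sites (separately for the positive and the purifying test family).
    """
    if engine is None:
        engine = CodonEngine(tree, kappa=kappa)
    if codon_indices is None:
        codon_indices = list(range(len(codon_columns)))
    calls = [SiteSelectionCall(codon_index=ci) for ci in codon_indices]
    usable_idx = []
    partial_list = []
    for k, col in enumerate(codon_columns):
        part = codon_column_partials(col)
        n_usable = int((part.sum(axis=1) == 1).sum())
        calls[k].n_usable = n_usable
        calls[k].n_substitutions = parsimony_substitutions(col, tree)
        if n_usable >= 3:
            usable_idx.append(k)
            partial_list.append(part)
    if usable_idx:
        partials = np.stack(partial_list, axis=1)  # (n_leaves, n_sites, 61)
        fits = engine.fit_sites(partials)
        p_pos = np.empty(len(usable_idx))
        p_pur = np.empty(len(usable_idx))
        for m, k in enumerate(usable_idx):
            fit = fits[m]
            call = calls[k]
            call.lrt_stat, call.p_value = site_lrt(
                fit.loglik_null, fit.loglik_alt, df=2)
            call.lrt_pur, call.p_pur = site_lrt(
                fit.loglik_neutral, fit.loglik_pur_free, df=1)
            call.omega_plus = fit.omega_plus
            call.omega_minus = fit.omega_minus
            call.p_minus = fit.p_minus
            p_pos[m] = call.p_value
            p_pur[m] = call.p_pur
        q_pos = fdr_adjust(p_pos)
        q_pur = fdr_adjust(p_pur)
        for m, k in enumerate(usable_idx):
            calls[k].q_value = float(q_pos[m])
            calls[k].q_pur = float(q_pur[m])
    for k, call in enumerate(calls):
        call.category = classify_site(call, fdr_level=fdr_level)
        if call.category == "positive" and compute_bayes_factors:
            part = codon_column_partials(codon_columns[k])
            m = usable_idx.index(k)
            bf = engine.branch_bayes_factors(part, fits[m])
            call.branch_bayes_factors = bf
            if fits[m].omega_plus <= 1.0:
                call.branches_selected = frozenset()
            else:
                call.branches_selected = frozenset(
                    int(b) for b in np.where(bf > 1.0)[0])
    return calls


def selection_summary(calls: list[SiteSelectionCall]) -> dict:
    """Per-gene category proportions among unambiguous sites."""
    n = len(calls)
    unamb = [c for c in calls if c.category != "ambiguous"]
    out = {"n_sites": n, "n_unambiguous": len(unamb),
           "fraction_unambiguous": len(unamb) / n if n else 0.0}
    for cat in ("positive", "purifying", "neutral"):
        k = sum(1 for c in unamb if c.category == cat)
        out[f"prop_{cat}"] = k / len(unamb) if unamb else float("nan")
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(tree: Tree, site_omegas: np.ndarray,
                             kappa: float, seed: int) -> list[np.ndarray]:
    """Simulate codon columns with per-site, per-branch dN/dS.

    ``site_omegas``: (n_sites, n_nodes) omega applying on the branch above
    each node (root column ignored).  Returns per-site codon-string columns
    in tree leaf order.
    """
    rng = np.random.default_rng(seed)
    n_sites, _ = site_omegas.shape
    cache: dict[tuple[float, int], np.ndarray] = {}

    def P_for(om: float, node: int) -> np.ndarray:
        key = (float(om), node)
        if key not in cache:
            from scipy.linalg import expm
            Q = mg94_rate_matrix(kappa, om)
            cache[key] = expm(Q * tree.blen[node])
        return cache[key]

    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.integers(0, N_CODONS, size=n_sites)
    for v in tree.preorder():
        if tree.parent[v] < 0:
            continue
        for om in np.unique(site_omegas[:, v]):
            mask = site_omegas[:, v] == om
            P = P_for(om, v)
            rows = P[states[tree.parent[v], mask]]
            cdf = np.cumsum(rows, axis=1)
            u = rng.random(mask.sum())
            states[v, mask] = np.minimum(
                (u[:, None] > cdf).sum(axis=1), N_CODONS - 1)
    codons = np.array(SENSE_CODONS)
    return [codons[states[: tree.n_leaves, j]] for j in range(n_sites)]


def codon_site_fit(codon_column, tree: Tree, alternative: bool = True,
                   kappa: float = 2.0,
                   engine: CodonEngine | None = None) -> tuple[SiteFit, float]:
    """Fit one codon column; returns (fit, log-likelihood of the requested
    model: alternative or the omega_plus <= 1 null)."""
    part = codon_column_partials(codon_column)
    if int((part.sum(axis=1) == 1).sum()) < 3:
        raise SelectionError("fewer than 3 usable codons at this site")
    if engine is None:
        engine = CodonEngine(tree, kappa=kappa)
    fit = engine.fit_sites(part[:, None, :])[0]
    return fit, (fit.loglik_alt if alternative else fit.loglik_null)
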