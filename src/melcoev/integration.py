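"""Gene-level response statistics combining selection and coevolution calls.

For each "target" gene this module counts the coevolving site pairs whose
end in the target lies inside a positively selected codon (the gene's
coevolutionary response), the distinct such sites and their percentage of
the trimmed sequence, the fraction of tree branches on which selection on
the target co-localises with an inferred substitution at the partner site,
Pearson chi-square enrichment labels of each gene against the rest of the
system (BH-corrected), and a PCA ordination of the three influence metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coevolution import CoevProfile, pair_substitution_branches
from .selection import SiteSelectionCall, fdr_adjust
from .trees import Tree


class IntegrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pair counting (Table 2 analogue)
# ---------------------------------------------------------------------------

def count_coevolving_pairs(scans: dict[tuple[str, str], pd.DataFrame],
                           thresholds: dict[tuple[str, str], float]
                           ) -> pd.DataFrame:
    """Per-gene-pair counts of pairs with delta_aic above the pair's
    threshold, as a symmetric gene x gene table with an ``average`` column
    (row+column sum over the gene's partners divided by n_genes - 1;
    missing scans count as absent cells)."""
    genes = sorted({g for key in scans for g in key})
    table = pd.DataFrame(np.nan, index=genes, columns=genes)
    for (ga, gb), df in scans.items():
        theta = thresholds[(ga, gb)]
        n = int((df["delta_aic"].to_numpy() > theta).sum())
        table.loc[ga, gb] = n
        table.loc[gb, ga] = n
    avg = table.sum(axis=1, skipna=True) / max(len(genes) - 1, 1)
    table["average"] = avg
    return table


def positive_codons(calls: list[SiteSelectionCall]) -> set[int]:
    return {c.codon_index for c in calls if c.category == "positive"}


def select_response_pairs(scans: dict[tuple[str, str], pd.DataFrame],
                          selection: dict[str, list[SiteSelectionCall]],
                          thresholds: dict[tuple[str, str], float],
                          frame_offsets: dict[str, int] | None = None
                          ) -> pd.DataFrame:
    """Coevolving pairs with at least one nucleotide inside a positively
    selected codon, annotated with the target gene(s).

    The codon membership of a scan column comes from the trimming
    provenance carried in the scan (``orig_col_*``).  A pair may count for
    both genes when both ends are selected.
    """
    offsets = frame_offsets or {}
    pos = {g: positive_codons(c) for g, c in selection.items()}
    rows = []
    for (ga, gb), df in scans.items():
        if ga not in pos or gb not in pos:
            raise IntegrationError(f"missing selection calls for ({ga}, {gb})")
        if "orig_col_a" not in df.columns:
            raise IntegrationError("scan lacks trimming provenance columns")
        theta = thresholds[(ga, gb)]
        passing = df[df["delta_aic"].to_numpy() > theta]
        for _, r in passing.iterrows():
            codon_a = int((r["orig_col_a"] - offsets.get(ga, 0)) // 3)
            codon_b = int((r["orig_col_b"] - offsets.get(gb, 0)) // 3)
            ta = codon_a in pos[ga]
            tb = codon_b in pos[gb]
            if not (ta or tb):
                continue
            rows.append({
                "gene_a": ga, "col_a": int(r["col_a"]),
                "orig_col_a": int(r["orig_col_a"]), "codon_a": codon_a,
                "gene_b": gb, "col_b": int(r["col_b"]),
                "orig_col_b": int(r["orig_col_b"]), "codon_b": codon_b,
                "profile": r["profile"], "s": r["s"], "d": r["d"],
                "delta_aic": r["delta_aic"],
                "target_a": ta, "target_b": tb,
            })
    cols = ["gene_a", "col_a", "orig_col_a", "codon_a", "gene_b", "col_b",
            "orig_col_b", "codon_b", "profile", "s", "d", "delta_aic",
            "target_a", "target_b"]
    return pd.DataFrame(rows, columns=cols)


def _pairs_of_gene(response: pd.DataFrame, gene: str) -> pd.DataFrame:
    a = response[(response["gene_a"] == gene) & response["target_a"]]
    b = response[(response["gene_b"] == gene) & response["target_b"]]
    return pd.concat([a, b])


def distinct_site_stats(response: pd.DataFrame, gene_lengths: dict[str, int]
                        ) -> pd.DataFrame:
    """Per-gene response pair counts, distinct selected sites, and their
    percentage of the trimmed sequence (one decimal)."""
    rows = []
    for gene, length in gene_lengths.items():
        if length <= 0:
            raise IntegrationError(f"non-positive length for {gene}")
        mine = _pairs_of_gene(response, gene)
        sites = set()
        for _, r in mine.iterrows():
            sites.add(r["col_a"] if r["gene_a"] == gene else r["col_b"])
        rows.append({"gene": gene, "n_pairs": len(mine),
                     "n_distinct_sites": len(sites),
                     "seq_length_trimmed": length,
                     "pct_distinct_sites": round(100.0 * len(sites) / length, 1)})
    return pd.DataFrame(rows).set_index("gene")


def partner_pair_counts(response: pd.DataFrame, genes: list[str]
                        ) -> pd.DataFrame:
    """Table-1-style cells: response pairs of each target gene (rows) split
    by partner gene (columns); row sums equal the gene's pair totals."""
    table = pd.DataFrame(0, index=genes, columns=genes)
    for gene in genes:
        mine = _pairs_of_gene(response, gene)
        for _, r in mine.iterrows():
            partner = r["gene_b"] if r["gene_a"] == gene else r["gene_a"]
            table.loc[gene, partner] += 1
    return table


# ---------------------------------------------------------------------------
# branch overlap
# ---------------------------------------------------------------------------

def branch_overlap_pct(response: pd.DataFrame,
                       selection: dict[str, list[SiteSelectionCall]],
                       alignments: dict[str, "object"],
                       tree: Tree) -> dict[str, float]:
    """Percentage of tree branches where positive selection on a gene
    co-localises with a partner-site substitution of one of its response
    pairs (marginal ancestral reconstruction under the fitted pair model).
    """
    n_branches = tree.n_nodes - 1
    order = tree.leaf_names
    calls_by_codon = {g: {c.codon_index: c for c in calls}
                      for g, calls in selection.items()}
    out: dict[str, float] = {}
    for gene in selection:
        counted: set[int] = set()
        mine = _pairs_of_gene(response, gene)
        for _, r in mine.iterrows():
            target_is_a = r["gene_a"] == gene
            codon = r["codon_a"] if target_is_a else r["codon_b"]
            call = calls_by_codon[gene].get(int(codon))
            if call is None or not call.branches_selected:
                continue
            aln_a = alignments[r["gene_a"]]
            aln_b = alignments[r["gene_b"]]
            ia = {s: i for i, s in enumerate(aln_a.species)}
            ib = {s: i for i, s in enumerate(aln_b.species)}
            col_a = aln_a.sequences[[ia[x] for x in order], int(r["col_a"])]
            col_b = aln_b.sequences[[ib[x] for x in order], int(r["col_b"])]
            st1, st2 = r["profile"].split("/")
            changed = pair_substitution_branches(
                col_a, col_b, tree, CoevProfile(st1, st2),
                float(r["s"]), float(r["d"]))
            partner_pos = 1 if target_is_a else 0
            counted |= {b for b in call.branches_selected
                        if changed[b, partner_pos]}
        out[gene] = 100.0 * len(counted) / n_branches
    return out


# ---------------------------------------------------------------------------
# enrichment tests
# ---------------------------------------------------------------------------

def gene_vs_rest_chisq(counts: dict[str, int], exposures: dict[str, int],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Each gene's count rate versus the pooled rest of the system.

    2x2 Pearson chi-square without continuity correction; when any expected
    cell drops below 1 the test falls back to Fisher's exact test.  Labels
    after BH: 'above' / 'below' / 'ns'.
    """
    genes = list(counts)
    total_c = sum(counts.values())
    total_e = sum(exposures.values())
    rows = []
    for g in genes:
        c, e = counts[g], exposures[g]
        rc, re_ = total_c - c, total_e - e
        table = np.array([[c, e - c], [rc, re_ - rc]], float)
        if np.any(table < 0):
            raise IntegrationError(f"count exceeds exposure for {g}")
        expected = stats.contingency.expected_freq(table + 1e-12)
        if expected.min() < 1.0:
            _, p = stats.fisher_exact(np.round(table).astype(int))
            method = "fisher"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            method = "chisq"
        rate_g = c / e if e else 0.0
        rate_rest = rc / re_ if re_ else 0.0
        rows.append({"gene": g, "count": c, "exposure": e, "p": p,
                     "direction": "above" if rate_g > rate_rest else "below",
                     "method": method})
    df = pd.DataFrame(rows).set_index("gene")
    df["q"] = fdr_adjust(df["p"].to_numpy())
    df["label"] = np.where(df["q"] < alpha, df["direction"], "ns")
    return df


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    variables: list[str]
    loadings: np.ndarray          # (n_vars, n_components)
    scores: pd.DataFrame          # genes x components
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    retained: np.ndarray          # boolean, eigenvalue > 1


def pca_influence(metrics: pd.DataFrame) -> OrdinationResult:
    """PCA of the per-gene influence metrics on the correlation matrix.

    Variables are centred and scaled to unit variance; components with
    eigenvalue > 1 are retained; signs are fixed so the PC1 loadings are
    non-negative (influence increases along PC1).
    """
    if len(metrics) < 3:
        raise IntegrationError("need at least 3 genes for ordination")
    X = metrics.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(metrics.columns, keep) if not k]
        warnings.warn(f"zero-variance variables dropped: {dropped}")
    X = X[:, keep]
    names = [c for c, k in zip(metrics.columns, keep) if k]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        if vecs[:, k].sum() < 0:
            vecs[:, k] = -vecs[:, k]
    scores = Z @ vecs
    comp_names = [f"PC{i + 1}" for i in range(len(vals))]
    return OrdinationResult(
        variables=names,
        loadings=vecs,
        scores=pd.DataFrame(scores, index=metrics.index, columns=comp_names),
        eigenvalues=vals,
        explained_pct=100.0 * vals / vals.sum(),
        retained=vals > 1.0,
    )


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def build_table1(partner_counts: pd.DataFrame, site_stats: pd.DataFrame,
                 pair_labels: pd.Series, site_labels: pd.Series
                 ) -> pd.DataFrame:
    """Per-gene response table: partner cells, pair/site totals, percentage
    of trimmed length, chi-square labels."""
    out = partner_counts.copy()
    out["nb_pairs"] = site_stats["n_pairs"]
    out["nb_distinct_sites"] = site_stats["n_distinct_sites"]
    out["seq_length"] = site_stats["seq_length_trimmed"]
    out["pct_distinct_sites"] = site_stats["pct_distinct_sites"]
    out["pairs_label"] = pair_labels
    out["sites_label"] = site_labels
    return out
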