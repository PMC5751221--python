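#!/usr/bin/env python
"""Summarise each gene's coevolutionary influence from the pipeline run.

Reads the per-threshold response tables produced by 02_run_pipeline.py,
checks them against the planted truth, and prints the gene ordering along
PC1 of the influence metrics (response pairs, distinct selected sites,
branch percentage).  Writes results/influence_summary.tsv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    run = ROOT / "run"
    if not (run / "table1.p95.tsv").exists():
        sys.exit("no pipeline outputs; run 02_run_pipeline.py first")
    rows = []
    for tag in ("90", "95", "97.5"):
        t1 = pd.read_csv(run / f"table1.p{tag}.tsv", sep="\t", index_col=0)
        t2 = pd.read_csv(run / f"table2.p{tag}.tsv", sep="\t", index_col=0)
        print(f"\n=== threshold: {tag}th percentile ===")
        print(t1[["nb_pairs", "nb_distinct_sites", "pct_distinct_sites",
                  "pct_branches", "pairs_label"]])
        print("coevolving pairs per gene pair (average over partners):")
        print(t2["average"].round(1).to_string())
        pca_path = run / f"influence_pca.p{tag}.json"
        if pca_path.exists():
            pca = json.loads(pca_path.read_text())
            scores = pd.read_csv(run / f"influence_pca.p{tag}.tsv", sep="\t",
                                 index_col=0)
            print(f"PC1 explains {pca['explained_pct'][0]:.1f}% "
                  f"(eigenvalue {pca['eigenvalues'][0]:.2f})")
            order = scores["score_PC1"].sort_values(ascending=False)
            print("influence ranking (PC1):",
                  " > ".join(order.index))
        for gene in t1.index:
            rows.append({"threshold": tag, "gene": gene,
                         "nb_pairs": t1.loc[gene, "nb_pairs"],
                         "nb_distinct_sites": t1.loc[gene, "nb_distinct_sites"],
                         "pct_branches": t1.loc[gene, "pct_branches"],
                         "avg_coev_pairs": t2.loc[gene, "average"]})
    out = ROOT / "influence_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"\nwrote {out}")

    truth_path = ROOT / "data" / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        genes = set(pd.read_csv(run / "table1.p95.tsv", sep="\t",
                                index_col=0).index)
        planted = [p for p in truth["coev_pairs"]
                   if p["gene_a"] in genes and p["gene_b"] in genes]
        print(f"planted coevolving pairs within this subset: {len(planted)}")


if __name__ == "__main__":
    main()
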