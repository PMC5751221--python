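"""Published gene-level tables of the melanocortin-system study, as data.

The study reported, per target gene, the coevolving pair counts whose
nucleotides fall in positively selected codons (with partner breakdown),
the distinct selected sites and their percentage of the trimmed sequence,
and the full gene x gene matrix of coevolving pair counts at the 95th
percentile threshold.  These printed cells are inputs here; the functions
below recompute the derived statistics (means, SDs, per-gene averages,
percentages) from the cells by plain arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENES = ["ASIP", "AGRP", "POMC", "PCSK1", "PCSK2",
         "MC1R", "MC2R", "MC3R", "MC4R", "MC5R"]

# target gene -> (trimmed length nt, response pairs, distinct sites)
RESPONSE_TABLE = pd.DataFrame(
    {
        "length": [396, 396, 801, 2256, 1914, 951, 891, 969, 996, 972],
        "nb_pairs": [176, 141, 33, 322, 208, 311, 135, 209, 85, 192],
        "nb_distinct_sites": [22, 9, 8, 25, 13, 34, 21, 17, 10, 30],
    },
    index=GENES,
)

# gene x gene coevolving pair counts at the 95th-percentile threshold;
# None marks the absent POMC-PCSK2 scan
_PAIR_CELLS = {
    ("ASIP", "AGRP"): 181, ("ASIP", "POMC"): 101, ("ASIP", "PCSK1"): 519,
    ("ASIP", "PCSK2"): 170, ("ASIP", "MC1R"): 643, ("ASIP", "MC2R"): 913,
    ("ASIP", "MC3R"): 631, ("ASIP", "MC4R"): 105, ("ASIP", "MC5R"): 323,
    ("AGRP", "POMC"): 276, ("AGRP", "PCSK1"): 761, ("AGRP", "PCSK2"): 714,
    ("AGRP", "MC1R"): 477, ("AGRP", "MC2R"): 511, ("AGRP", "MC3R"): 364,
    ("AGRP", "MC4R"): 299, ("AGRP", "MC5R"): 352,
    ("POMC", "PCSK1"): 1348, ("POMC", "PCSK2"): None, ("POMC", "MC1R"): 606,
    ("POMC", "MC2R"): 682, ("POMC", "MC3R"): 104, ("POMC", "MC4R"): 340,
    ("POMC", "MC5R"): 192,
    ("PCSK1", "PCSK2"): 4012, ("PCSK1", "MC1R"): 2672,
    ("PCSK1", "MC2R"): 3105, ("PCSK1", "MC3R"): 927,
    ("PCSK1", "MC4R"): 2704, ("PCSK1", "MC5R"): 1137,
    ("PCSK2", "MC1R"): 2088, ("PCSK2", "MC2R"): 2207,
    ("PCSK2", "MC3R"): 1025, ("PCSK2", "MC4R"): 1410,
    ("PCSK2", "MC5R"): 1754,
    ("MC1R", "MC2R"): 1253, ("MC1R", "MC3R"): 1203, ("MC1R", "MC4R"): 1636,
    ("MC1R", "MC5R"): 1519,
    ("MC2R", "MC3R"): 1336, ("MC2R", "MC4R"): 1662, ("MC2R", "MC5R"): 2011,
    ("MC3R", "MC4R"): 1281, ("MC3R", "MC5R"): 1454,
    ("MC4R", "MC5R"): 1250,
}


def coevolving_pair_matrix() -> pd.DataFrame:
    """Symmetric gene x gene matrix (NaN diagonal and absent cell)."""
    m = pd.DataFrame(np.nan, index=GENES, columns=GENES)
    for (a, b), v in _PAIR_CELLS.items():
        if v is not None:
            m.loc[a, b] = v
            m.loc[b, a] = v
    return m


def per_gene_pair_averages() -> pd.Series:
    """Average coevolving pair count per gene over its nine partners
    (absent cells contribute nothing to the sum; divisor stays 9)."""
    m = coevolving_pair_matrix()
    return m.sum(axis=1, skipna=True) / (len(GENES) - 1)


def pair_count_stats() -> dict[str, float]:
    """Mean/SD of the selected-pair counts and of the per-gene coevolving
    pair averages (SDs with ddof=1)."""
    pairs = RESPONSE_TABLE["nb_pairs"].to_numpy(float)
    sites = RESPONSE_TABLE["nb_distinct_sites"].to_numpy(float)
    avg = per_gene_pair_averages().to_numpy()
    return {
        "mean_selected_pairs": float(pairs.mean()),
        "sd_selected_pairs": float(pairs.std(ddof=1)),
        "mean_selected_sites": float(sites.mean()),
        "sd_selected_sites": float(sites.std(ddof=1)),
        "mean_coevolving_pairs": float(avg.mean()),
        "sd_coevolving_pairs": float(avg.std(ddof=1)),
    }


def pct_distinct_sites() -> pd.Series:
    """Distinct selected sites as a percentage of trimmed length, one
    decimal (e.g. ASIP 22/396 -> 5.6)."""
    pct = (100.0 * RESPONSE_TABLE["nb_distinct_sites"]
           / RESPONSE_TABLE["length"])
    return pct.round(1)
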