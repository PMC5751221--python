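"""Percent-identity profiling of alignments.

Identity of a column is the frequency of its majority residue among the
informative residues (gaps and ambiguity codes are excluded from both the
numerator and the denominator).  The alignment-level value is the mean over
columns, reported as a percentage.  Positions with identity strictly above
the cutoff (default 95%) are flagged as highly conserved.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np

_PLAIN = frozenset("ACGT")


def column_identity(column) -> float:
    """Fraction of informative residues equal to the majority residue.

    A column with no informative residue (all gaps / ambiguity codes) has
    identity 0 by convention.
    """
    counts = Counter(c for c in column if c in _PLAIN)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return max(counts.values()) / total


@dataclass
class ConservationProfile:
    gene_name: str
    per_column_identity: np.ndarray
    cutoff: float = 0.95

    @property
    def mean_identity_percent(self) -> float:
        return 100.0 * float(np.mean(self.per_column_identity))

    @property
    def conserved_mask(self) -> np.ndarray:
        return self.per_column_identity > self.cutoff

    @property
    def uninformative_mask(self) -> np.ndarray:
        return self.per_column_identity == 0.0


def conservation_profile(aln, cutoff: float = 0.95) -> ConservationProfile:
    ident = np.array([column_identity(aln.sequences[:, j])
                      for j in range(aln.width)])
    return ConservationProfile(aln.gene_name, ident, cutoff)


def conserved_positions(profile: ConservationProfile,
                        cutoff: float | None = None) -> np.ndarray:
    """Column indices with identity strictly greater than the cutoff."""
    c = profile.cutoff if cutoff is None else cutoff
    return np.where(profile.per_column_identity > c)[0]


def write_profile_tsv(profile: ConservationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tidentity\tconserved\n")
        for j, x in enumerate(profile.per_column_identity):
            fh.write(f"{j}\t{x:.6f}\t{int(x > profile.cutoff)}\n")


def summary_json(profile: ConservationProfile) -> str:
    return json.dumps({
        "gene": profile.gene_name,
        "n_columns": int(len(profile.per_column_identity)),
        "mean_identity_percent": profile.mean_identity_percent,
        "cutoff": profile.cutoff,
        "n_conserved": int(profile.conserved_mask.sum()),
    }, indent=2)
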