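"""Alignment I/O, trimming, and inter-gene pairing.

Coding alignments come in as FASTA (one file per gene, species identifier =
first whitespace-delimited token of the record header).  Before any codon or
pair analysis the alignments are trimmed: fully conserved columns and columns
rich in ambiguity characters are removed, keeping a provenance map back to
the original coordinates so that downstream statistics can be expressed in
codon space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from .conservation import column_identity
from .trees import Tree

GAP = "-"
NUCS = "ACGT"
# IUPAC ambiguity codes -> compatible nucleotide sets
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    GAP: "ACGT", "?": "ACGT", ".": "ACGT",
}


class AlignmentError(ValueError):
    pass


class AlignmentLengthError(AlignmentError):
    pass


class DuplicateSpeciesError(AlignmentError):
    pass


class EmptyAlignmentError(AlignmentError):
    pass


class NoSharedSpeciesError(AlignmentError):
    pass


@dataclass
class GeneAlignment:
    """In-frame coding alignment for one gene.

    ``sequences`` is an (n_species, n_columns) matrix of single characters.
    ``orig_columns`` maps current columns back to the columns of the
    alignment as read from disk (identity before trimming).
    """

    gene_name: str
    species: list[str]
    sequences: np.ndarray
    frame_offset: int = 0
    is_trimmed: bool = False
    orig_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype="<U1")
        if self.sequences.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D")
        if len(self.species) != self.sequences.shape[0]:
            raise AlignmentError("species list does not match matrix rows")
        if len(set(self.species)) != len(self.species):
            raise DuplicateSpeciesError(
                f"duplicate species identifiers in {self.gene_name}")
        if self.orig_columns is None:
            self.orig_columns = np.arange(self.sequences.shape[1])
        self.orig_columns = np.asarray(self.orig_columns, dtype=np.int64)
        if len(self.orig_columns) != self.sequences.shape[1]:
            raise AlignmentError("column provenance does not match width")

    @property
    def n_species(self) -> int:
        return self.sequences.shape[0]

    @property
    def width(self) -> int:
        return self.sequences.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.sequences[:, j]

    def subset_species(self, keep: list[str]) -> "GeneAlignment":
        idx = {s: i for i, s in enumerate(self.species)}
        rows = [idx[s] for s in keep]
        return replace(self, species=list(keep), sequences=self.sequences[rows])

    def codon_of_column(self, j: int) -> int:
        """Codon index (in original coordinates) a current column belongs to."""
        return int((self.orig_columns[j] - self.frame_offset) // 3)


@dataclass
class PairedAlignment:
    """Two gene alignments restricted to their shared species.

    ``column_map[k] = (gene_name, original_column)`` for the k-th paired
    column (gene A's columns first, then gene B's).
    """

    gene_a: GeneAlignment
    gene_b: GeneAlignment
    shared_species: list[str]
    column_map: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if self.gene_a.species != self.gene_b.species:
            raise AlignmentError("paired parts must list identical species")
        if len(self.column_map) != self.gene_a.width + self.gene_b.width:
            raise AlignmentError("column map does not cover both parts")

    @property
    def width(self) -> int:
        return self.gene_a.width + self.gene_b.width


def read_alignment(path, gene_name: str) -> GeneAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyAlignmentError(f"no records in {path}")
    names = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentLengthError(
            f"ragged alignment in {path}: row lengths {sorted(lengths)}")
    matrix = np.array([list(s) for s in seqs], dtype="<U1")
    return GeneAlignment(gene_name=gene_name, species=names, sequences=matrix)


def write_alignment(aln: GeneAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp, row in zip(aln.species, aln.sequences):
            fh.write(f">{sp}\n{''.join(row)}\n")


def _is_ambiguous(chars: np.ndarray) -> np.ndarray:
    """True for symbols that are neither a plain nucleotide nor a gap."""
    plain = np.isin(chars, list(NUCS)) | (chars == GAP)
    return ~plain


def trim_alignment(aln: GeneAlignment, identity_cutoff: float = 1.0,
                   max_ambiguity_fraction: float = 0.2,
                   codon_mode: bool = False) -> GeneAlignment:
    """Drop fully conserved columns and ambiguity-rich columns.

    A column is removed when its identity reaches ``identity_cutoff``
    (default: exactly invariant) or when the fraction of ambiguity symbols
    (non-ACGT, non-gap) exceeds ``max_ambiguity_fraction``.  With
    ``codon_mode`` the removal is applied codon-wise: a whole codon is
    dropped as soon as one of its three columns qualifies, preserving frame.
    """
    n, width = aln.sequences.shape
    identity = np.array([column_identity(aln.sequences[:, j])
                         for j in range(width)])
    amb_frac = _is_ambiguous(aln.sequences).mean(axis=0)
    bad = (identity >= identity_cutoff) | (amb_frac > max_ambiguity_fraction)
    if codon_mode:
        codons = (aln.orig_columns - aln.frame_offset) // 3
        for c in np.unique(codons[bad]):
            bad |= codons == c
    keep = ~bad
    if not keep.any():
        raise EmptyAlignmentError(
            f"trimming removed every column of {aln.gene_name}")
    return replace(aln, sequences=aln.sequences[:, keep],
                   orig_columns=aln.orig_columns[keep], is_trimmed=True)


def trim_provenance_table(aln: GeneAlignment) -> list[tuple[int, str, int, int]]:
    """Rows of (trimmed_column, gene, original_column, original_codon)."""
    return [(j, aln.gene_name, int(aln.orig_columns[j]), aln.codon_of_column(j))
            for j in range(aln.width)]


def write_provenance(aln: GeneAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("trimmed_column\tgene\toriginal_column\toriginal_codon\n")
        for row in trim_provenance_table(aln):
            fh.write("\t".join(str(x) for x in row) + "\n")


def pair_genes(a: GeneAlignment, b: GeneAlignment,
               normalize=None) -> PairedAlignment:
    """Restrict two gene alignments to their shared species (sorted order).

    ``normalize`` optionally maps raw species identifiers to a join key
    (e.g. ``str.lower``); it is off by default to avoid silent mis-joins.
    """
    key = normalize if normalize is not None else (lambda s: s)
    keys_a = {key(s): s for s in a.species}
    keys_b = {key(s): s for s in b.species}
    shared_keys = sorted(set(keys_a) & set(keys_b))
    if not shared_keys:
        raise NoSharedSpeciesError(
            f"no shared species between {a.gene_name} and {b.gene_name}")
    shared = [keys_a[k] for k in shared_keys]
    sub_a = a.subset_species(shared)
    sub_b = b.subset_species([keys_b[k] for k in shared_keys])
    # unify the species labels of part b with part a's labels
    sub_b = replace(sub_b, species=list(shared))
    cmap = [(a.gene_name, int(c)) for c in sub_a.orig_columns]
    cmap += [(b.gene_name, int(c)) for c in sub_b.orig_columns]
    return PairedAlignment(sub_a, sub_b, shared, cmap)


def read_tree(path) -> Tree:
    return Tree.read(path)


def write_tree(tree: Tree, path) -> None:
    tree.write(path)
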