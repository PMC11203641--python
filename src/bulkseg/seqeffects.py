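"""Coding-sequence consequences of a deletion: translation, frame, protein diff.

Models what a short deletion does to a coding sequence — frameshift versus
in-frame classification by length modulo 3, translation of the wild-type
and mutated CDS with the standard genetic code, and a protein-level diff
(substituted and deleted residues) computed by trimming the longest common
prefix and suffix, which is exact for single-indel comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodingSequence",
    "DeletionSpec",
    "Translation",
    "ProteinDiff",
    "protein_length_from_cds",
    "translate_cds",
    "apply_deletion",
    "classify_deletion_effect",
    "diff_proteins",
    "read_fasta",
    "write_fasta",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A CDS: id plus an A/C/G/T nucleotide string."""

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        if len(self.nucleotides) < 3:
            raise ValueError("a CDS must be at least one codon long")
        bad = next(
            (i for i, b in enumerate(self.nucleotides) if b not in _VALID_BASES), None
        )
        if bad is not None:
            raise ValueError(
                f"invalid or ambiguous base {self.nucleotides[bad]!r} at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class DeletionSpec:
    """A deletion of ``length`` nucleotides starting at 1-based CDS offset ``start``."""

    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start is 1-based and must be >= 1")
        if self.length < 1:
            raise ValueError("deletion length must be >= 1")


@dataclass(frozen=True)
class Translation:
    """A translated protein; ``truncated`` flags an internal stop codon."""

    protein: str
    truncated: bool


@dataclass(frozen=True)
class ProteinDiff:
    """Residue-level difference between two proteins."""

    n_substituted: int
    n_deleted: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.n_substituted < 0 or self.n_deleted < 0:
            raise ValueError("diff counts must be nonnegative")


def protein_length_from_cds(cds_len: int) -> int:
    """Protein length encoded by a CDS of ``cds_len`` nucleotides.

    One residue per codon minus the terminal stop codon: a 990 bp coding
    region encodes 329 amino acids.
    """
    if cds_len < 6 or cds_len % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3 and at least 6")
    return cds_len // 3 - 1


def translate_cds(cds: CodingSequence | str) -> Translation:
    """Translate a CDS with the standard genetic code.

    The trailing stop codon is dropped.  An internal stop truncates the
    product and sets ``truncated`` (frameshifts routinely create premature
    stops, so this is an expected outcome, not an error).
    """
    if not isinstance(cds, CodingSequence):
        cds = CodingSequence(id="", nucleotides=cds)  # validates bases and length
    seq = cds.nucleotides
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3 for translation")
    full = str(Seq(seq).translate())
    if full.endswith("*"):
        full = full[:-1]
    stop = full.find("*")
    if stop >= 0:
        return Translation(protein=full[:stop], truncated=True)
    return Translation(protein=full, truncated=False)


def apply_deletion(cds: CodingSequence | str, spec: DeletionSpec) -> str:
    """Remove ``spec.length`` nucleotides from the CDS; flanks are untouched."""
    seq = cds.nucleotides if isinstance(cds, CodingSequence) else cds
    if spec.start + spec.length - 1 > len(seq):
        raise ValueError(
            f"deletion {spec.start}+{spec.length} exceeds CDS length {len(seq)}"
        )
    return seq[: spec.start - 1] + seq[spec.start - 1 + spec.length :]


def classify_deletion_effect(spec: DeletionSpec) -> str:
    """``"frameshift"`` iff the deleted length is not a multiple of 3."""
    return "inframe_deletion" if spec.length % 3 == 0 else "frameshift"


def diff_proteins(wt_protein: str, mut_protein: str) -> ProteinDiff:
    """Residue-level diff between a wild-type and a mutant protein.

    Trims the longest common prefix, then the longest common suffix of the
    remainders.  ``n_deleted`` is the net residue loss of the mutant core
    relative to the wild-type core (floored at 0); ``n_substituted`` counts
    position-wise mismatches over the shorter core when both cores are
    aligned at their left edge.  For proteins differing by one indel plus
    local substitutions this equals the global-alignment answer.
    """
    if not wt_protein or not mut_protein:
        raise ValueError("proteins must be non-empty")
    prefix = 0
    while (
        prefix < min(len(wt_protein), len(mut_protein))
        and wt_protein[prefix] == mut_protein[prefix]
    ):
        prefix += 1
    wt_core, mut_core = wt_protein[prefix:], mut_protein[prefix:]
    suffix = 0
    while (
        suffix < min(len(wt_core), len(mut_core))
        and wt_core[len(wt_core) - 1 - suffix] == mut_core[len(mut_core) - 1 - suffix]
    ):
        suffix += 1
    if suffix:
        wt_core, mut_core = wt_core[:-suffix], mut_core[:-suffix]
    n_deleted = max(len(wt_core) - len(mut_core), 0)
    n_sub = sum(a != b for a, b in zip(wt_core, mut_core))
    if not wt_core and not mut_core:
        description = "identical proteins"
    else:
        description = (
            f"{n_sub} substituted and {n_deleted} deleted residue(s) in "
            f"wild-type interval {prefix + 1}..{prefix + max(len(wt_core), 1)}"
        )
    return ProteinDiff(n_substituted=n_sub, n_deleted=n_deleted, description=description)


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read CDS sequences from a FASTA file (uppercased)."""
    return [
        CodingSequence(id=rec.id, nucleotides=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs to FASTA; works for nucleotide or protein."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
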