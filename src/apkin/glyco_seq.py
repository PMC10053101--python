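"""N-glycosylation sequon scanning and protein-chain mass accounting.

A sequon is the tripeptide motif N-X-[S/T] with X any residue except proline;
asparagines in such motifs are the candidate N-glycosylation acceptor sites.
Positions are reported 1-based on the *untrimmed* chain so a site such as
"N141" is directly comparable across trimmed and untrimmed views.

Chain masses are average (not monoisotopic) masses: the sum of average residue
masses over the retained span plus one water, in kDa.  Mature-chain masses
remove the signal peptide (positions 1..signal_end) and, optionally, the
C-terminal region beyond the GPI-anchor ω-site; both boundaries are
user-supplied inputs (this module does not predict them).  The difference
between an observed mature (glycosylated) mass and the computed pre-mature
chain mass is the glycoform mass shift attributable to the glycan moieties.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .core_io import ApkinError, DomainError

# ExPASy-style average residue (amino-acid minus water) masses, Da
AVERAGE_RESIDUE_MASS_DA = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_DA = 18.01528
RESIDUE_MASS_TABLE_VERSION = "expasy-average-1"


class SequenceError(ApkinError):
    """A sequence contains a non-canonical letter; the message names the
    1-based position."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with optional processing boundaries.

    ``signal_end`` is the last residue of the signal peptide; ``gpi_omega``
    the ω-site residue where the GPI anchor attaches (the mature chain ends
    there).  Both are 1-based and user-supplied.
    """

    id: str
    sequence: str
    signal_end: int | None = None
    gpi_omega: int | None = None

    def __post_init__(self):
        seq = self.sequence
        if not seq:
            raise SequenceError(f"{self.id}: empty sequence")
        for i, aa in enumerate(seq, start=1):
            if aa not in AVERAGE_RESIDUE_MASS_DA:
                raise SequenceError(
                    f"{self.id}: non-canonical letter {aa!r} at position {i}"
                )
        if self.signal_end is not None and not 1 <= self.signal_end < len(seq):
            raise DomainError(f"signal_end {self.signal_end} out of range")
        if self.gpi_omega is not None:
            if not 1 <= self.gpi_omega <= len(seq):
                raise DomainError(f"gpi_omega {self.gpi_omega} out of range")
            if self.signal_end is not None and self.signal_end >= self.gpi_omega:
                raise DomainError("signal_end must precede gpi_omega")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequonReport:
    """Sequon positions (1-based, strictly increasing) with their 3-residue
    contexts, plus the chain mass used for glycoform bookkeeping."""

    record_id: str
    positions: tuple[int, ...]
    motif_context: tuple[str, ...]
    chain_mass_kDa: float


def scan_nglyc_sequons(record: ProteinRecord) -> tuple[int, ...]:
    """All and only the 1-based positions i with seq[i]=N, seq[i+1]≠P and
    seq[i+2] in {S, T}; overlapping sequons are each reported."""
    seq = record.sequence
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T"):
            hits.append(i + 1)
    return tuple(hits)


def average_mass(record: ProteinRecord, trim: str = "none") -> float:
    """Average mass, in kDa, of the (optionally trimmed) chain.

    ``trim``: ``none`` keeps the full sequence; ``remove_signal`` keeps
    positions signal_end+1..end; ``remove_signal_and_gpi`` keeps
    signal_end+1..gpi_omega.  Boundaries must be present when used.
    """
    if trim not in ("none", "remove_signal", "remove_signal_and_gpi"):
        raise DomainError(f"unknown trim mode {trim!r}")
    start, stop = 0, len(record.sequence)
    if trim in ("remove_signal", "remove_signal_and_gpi"):
        if record.signal_end is None:
            raise DomainError("trim requested but signal_end is absent")
        start = record.signal_end
    if trim == "remove_signal_and_gpi":
        if record.gpi_omega is None:
            raise DomainError("trim requested but gpi_omega is absent")
        stop = record.gpi_omega
    span = record.sequence[start:stop]
    if not span:
        raise DomainError("trimmed span is empty")
    mass_da = sum(AVERAGE_RESIDUE_MASS_DA[aa] for aa in span) + WATER_DA
    return mass_da / 1000.0


def sequon_report(record: ProteinRecord, trim: str = "none") -> SequonReport:
    positions = scan_nglyc_sequons(record)
    contexts = tuple(record.sequence[p - 1 : p + 2] for p in positions)
    return SequonReport(record.id, positions, contexts, average_mass(record, trim))


def glycoform_mass_shift(mature_kDa: float, premature_kDa: float) -> float:
    """Mass difference (kDa, sign preserved) between an observed mature
    glycoform and the pre-mature chain."""
    if mature_kDa <= 0 or premature_kDa <= 0:
        raise DomainError("masses must be > 0")
    return mature_kDa - premature_kDa


def read_fasta(path) -> list[ProteinRecord]:
    """Read one or more protein records from a FASTA file."""
    records = [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(Path(path)), "fasta")
    ]
    if not records:
        raise ApkinError(f"{path}: no FASTA records")
    return records
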