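"""Protein sequence sets: FASTA I/O, length filtering, proteome summaries.

A :class:`Proteome` is the unit the whole analysis operates on: an ordered
collection of identified amino-acid sequences from one species, optionally
tagged with a taxonomic group (green algae, oomycetes, diatom, yellow algae,
red algae). Sequences are normalised at ingestion: uppercased, terminal stop
characters stripped, and ambiguity codes (B, Z, U, O) mapped to X so that
downstream motif scanners operate over a defined alphabet.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard residues plus X for anything ambiguous.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(STANDARD_RESIDUES + "X")

#: Ambiguity / non-standard codes folded into X at ingestion.
_AMBIGUOUS = {"B", "Z", "U", "O", "J"}

GROUPS = ("green_algae", "oomycetes", "diatom", "yellow_algae", "red_algae", "other")


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""


def normalize_sequence(raw: str, *, protein_id: str = "?") -> str:
    """Uppercase, strip terminal stops, fold ambiguity codes into X.

    Internal '*' characters are rejected: a stop in the middle of a protein
    sequence indicates a broken translation, not a residue.
    """
    seq = raw.upper().rstrip("*")
    if "*" in seq:
        raise ValueError(f"internal stop codon in sequence of {protein_id!r}")
    if not seq:
        raise ValueError(f"empty sequence for {protein_id!r}")
    folded = []
    n_folded = 0
    for ch in seq:
        if ch in _AMBIGUOUS:
            folded.append("X")
            n_folded += 1
        elif ch in ALPHABET:
            folded.append(ch)
        else:
            raise ValueError(f"illegal residue {ch!r} in sequence of {protein_id!r}")
    if n_folded:
        logger.warning(
            "%s: %d non-standard residue(s) mapped to X", protein_id, n_folded
        )
    return "".join(folded)


@dataclass
class ProteinRecord:
    """One identified amino-acid sequence.

    Coordinates used anywhere against this record are 1-based inclusive.
    """

    protein_id: str
    species_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id or any(c.isspace() for c in self.protein_id):
            raise ValueError(f"bad protein_id {self.protein_id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """Ordered, duplicate-free collection of records from one species."""

    species_id: str
    records: list[ProteinRecord] = field(default_factory=list)
    group: str = "other"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise ValueError(f"duplicate protein_id {rec.protein_id!r}")
            seen.add(rec.protein_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.protein_id == protein_id:
                return rec
        raise KeyError(protein_id)

    @property
    def total_aa(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def ids(self) -> list[str]:
        return [r.protein_id for r in self.records]


@dataclass
class ProteomeSummary:
    species_id: str
    n_records: int
    total_aa: int
    mean_length: float | None  # None for an empty proteome


@dataclass
class FilterResult:
    """Outcome of a length filter: the retained proteome plus removal counts."""

    proteome: Proteome
    n_input: int
    n_removed: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed


def read_fasta(path: str | Path | io.TextIOBase, species_id: str, group: str = "other") -> Proteome:
    """Read a FASTA file into a :class:`Proteome`.

    The protein id is the first whitespace-delimited token of the header; the
    remainder is kept as a free-text description. Sequences are normalised
    (uppercase, terminal '*' stripped, ambiguity codes folded to X).
    """
    if isinstance(path, (str, Path)):
        with open(path) as handle:
            return read_fasta(handle, species_id, group)
    text = path.read()
    _check_leading_garbage(text)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = normalize_sequence(str(entry.seq), protein_id=entry.id)
        records.append(
            ProteinRecord(
                protein_id=entry.id,
                species_id=species_id,
                sequence=seq,
                description=entry.description[len(entry.id):].strip(),
            )
        )
    return Proteome(species_id=species_id, records=records, group=group)


def _check_leading_garbage(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            return
        raise FastaParseError(f"line {lineno}: sequence data before any FASTA header")


def write_fasta(proteome: Proteome, path: str | Path, *, width: int = 60) -> None:
    """Write a proteome back to FASTA (fixed line width, id + description header)."""
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=rec.description)
        for rec in proteome
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def filter_by_length(
    proteome: Proteome, min_len: int = 50, max_len: int = 4000
) -> FilterResult:
    """Drop records shorter than ``min_len`` or longer than ``max_len``.

    Boundaries are inclusive: records of exactly ``min_len`` or ``max_len``
    residues are kept. Input order of the survivors is preserved.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = [r for r in proteome if min_len <= len(r) <= max_len]
    filtered = Proteome(
        species_id=proteome.species_id, records=kept, group=proteome.group
    )
    return FilterResult(
        proteome=filtered, n_input=len(proteome), n_removed=len(proteome) - len(kept)
    )


def summarize(proteome: Proteome) -> ProteomeSummary:
    n = len(proteome)
    total = proteome.total_aa
    return ProteomeSummary(
        species_id=proteome.species_id,
        n_records=n,
        total_aa=total,
        mean_length=(total / n) if n else None,
    )


def write_summary(proteomes: Iterable[Proteome], path: str | Path) -> None:
    """Per-protein length table: protein_id, species_id, length (TSV)."""
    with open(path, "w") as out:
        out.write("protein_id\tspecies_id\tlength\n")
        for proteome in proteomes:
            for rec in proteome:
                out.write(f"{rec.protein_id}\t{rec.species_id}\t{len(rec)}\n")
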