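"""FASTA reading/writing and labeled-dataset assembly for PrLD sequences.

Sequences are expected to be pre-delimited prion-like domains (PrLDs) over
the 20 canonical amino acids; delimitation of PrLDs from full-length
proteins is out of scope and should be done with dedicated tools (PLAAC,
PAPA, PrionScan, PrionW) before using this package.

Parsing is delegated to Biopython's FASTA reader; validation (canonical
alphabet, unique ids) is layered on top because every downstream feature
(propensity scale, pKa table, cysteine count) is defined only on the 20
canonical residues.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import (
    DuplicateIdError,
    FastaFormatError,
    InvalidResidueError,
    LabelingError,
)

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)


@dataclass(frozen=True)
class SequenceRecord:
    """One PrLD: identifier, free-text description and residue string."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be non-empty")
        if not self.residues:
            raise InvalidResidueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in CANONICAL_RESIDUES:
                raise InvalidResidueError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Ordered PrLD records with aligned binary labels.

    Positive = recruited into stress-granule foci upon heat stress;
    negative = not recruited.
    """

    records: list[SequenceRecord] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise LabelingError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        for lab in self.labels:
            if lab not in LABELS:
                raise LabelingError(f"unknown label {lab!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(1 for lab in self.labels if lab == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for lab in self.labels if lab == NEGATIVE)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=[self.labels[i] for i in indices],
        )


def parse_fasta(text: str, skip_invalid: bool = False) -> list[SequenceRecord]:
    """Parse FASTA text into validated records.

    Residues are uppercased and concatenated across wrapped lines; record
    order is preserved. CRLF line endings and trailing whitespace are
    tolerated.

    Parameters
    ----------
    text:
        FASTA-formatted text with at least one ``>`` header.
    skip_invalid:
        If True, records containing non-canonical residues are dropped with
        a warning instead of raising :class:`InvalidResidueError`.
    """
    stripped = text.lstrip()
    if not stripped or not stripped.startswith(">"):
        raise FastaFormatError("input is not FASTA: no '>' header line found")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(io.StringIO(text), "fasta"):
        rec_id = bio_rec.id
        if not rec_id:
            raise FastaFormatError("encountered a header with an empty id")
        if rec_id in seen:
            raise DuplicateIdError(f"duplicate record id {rec_id!r}")
        seen.add(rec_id)
        description = bio_rec.description
        if description.startswith(rec_id):
            description = description[len(rec_id):].strip()
        residues = str(bio_rec.seq).upper().replace(" ", "")
        try:
            records.append(
                SequenceRecord(id=rec_id, residues=residues, description=description)
            )
        except InvalidResidueError:
            if skip_invalid:
                logger.warning("skipping record %r: non-canonical residues", rec_id)
            else:
                raise
    if not records and not skip_invalid:
        raise FastaFormatError("no records parsed from input")
    return records


def write_fasta(records: Iterable[SequenceRecord], line_width: int = 60) -> str:
    """Render records as FASTA text; inverse of :func:`parse_fasta`."""
    if line_width < 1:
        raise ValueError(f"line_width must be positive, got {line_width}")
    chunks: list[str] = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        chunks.append(header + "\n")
        for i in range(0, len(rec.residues), line_width):
            chunks.append(rec.residues[i : i + line_width] + "\n")
    return "".join(chunks)


def parse_label_table(text: str) -> dict[str, str]:
    """Parse a two-column TSV ``id<TAB>label`` into a mapping.

    Blank lines and ``#`` comment lines are ignored; labels must be
    ``positive`` or ``negative``.
    """
    table: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise LabelingError(f"label table line {lineno}: expected 'id<TAB>label'")
        rec_id, label = parts[0].strip(), parts[1].strip().lower()
        if label not in LABELS:
            raise LabelingError(
                f"label table line {lineno}: unknown label {label!r} "
                f"(expected one of {LABELS})"
            )
        if rec_id in table:
            raise DuplicateIdError(f"label table: duplicate id {rec_id!r}")
        table[rec_id] = label
    return table


def write_label_table(dataset: LabeledDataset) -> str:
    """Render a dataset's labels as the two-column TSV format."""
    return "".join(
        f"{rec.id}\t{lab}\n" for rec, lab in zip(dataset.records, dataset.labels)
    )


def load_labeled_dataset(
    fasta_text: str, label_table: Mapping[str, str]
) -> LabeledDataset:
    """Join FASTA records with a label mapping into a :class:`LabeledDataset`.

    Every record id must be present in ``label_table``; extra labels are
    permitted (the table may cover a superset of the FASTA).
    """
    records = parse_fasta(fasta_text)
    labels: list[str] = []
    for rec in records:
        if rec.id not in label_table:
            raise LabelingError(f"no label provided for record {rec.id!r}")
        labels.append(label_table[rec.id])
    dataset = LabeledDataset(records=records, labels=labels)
    logger.info(
        "loaded dataset: %d records (%d positive, %d negative)",
        len(dataset),
        dataset.n_positive,
        dataset.n_negative,
    )
    return dataset
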