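"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open, on the forward strand of the
genome they refer to; readers and writers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

DNA_ALPHABET = frozenset("ACGT")
DEFAULT_WINDOW_LENGTH = 81

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PROMOTER = "promoter"
NON_PROMOTER = "non-promoter"
LABELS = frozenset({PROMOTER, NON_PROMOTER})
ORIGINS = frozenset({"PPD", "CDS", "SRS", "fixture"})

#: dataset stage tags, mirroring the raw -> filtered -> merged workflow
STAGE_TAGS = frozenset({"P0", "C0", "R0", "P", "C", "R", "D"})


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class Genome:
    """A named nucleotide sequence with a species tag."""

    genome_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - (DNA_ALPHABET | {"N"})
        if bad:
            raise ValueError(
                f"genome {self.genome_id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class TssRecord:
    """A stranded transcription start site anchored on a genome."""

    genome_id: str
    position: int  # 0-based index of the TSS base
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"TSS at {self.position}: strand must be + or -")
        if self.position < 0:
            raise ValueError(f"TSS position {self.position} is negative")


@dataclass(frozen=True, slots=True)
class CdsRecord:
    """A protein-coding interval, 0-based half-open."""

    genome_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"CDS {self.start}-{self.end}: strand must be + or -")
        if self.end - self.start < 1:
            raise ValueError(f"CDS {self.start}-{self.end}: empty interval")
        if self.start < 0:
            raise ValueError(f"CDS start {self.start} is negative")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class LabeledSequence:
    """A fixed-length window tagged with label, species and origin."""

    seq_id: str
    species_id: str
    sequence: str
    label: str
    origin: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"{self.seq_id}: label {self.label!r} not in {sorted(LABELS)}")
        if self.origin not in ORIGINS:
            raise ValueError(f"{self.seq_id}: origin {self.origin!r} not in {sorted(ORIGINS)}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.seq_id}: illegal characters {sorted(bad)}")


@dataclass(slots=True)
class SequenceSet:
    """An ordered collection of labeled windows at one pipeline stage.

    ``stage_tag`` follows the raw/filtered/merged naming: P0/C0/R0 are
    the raw promoter, CDS-negative and synthetic-negative sets; P/C/R
    their redundancy-filtered versions; D a merged balanced dataset.
    """

    records: list[LabeledSequence] = field(default_factory=list)
    stage_tag: str | None = None
    window_length: int = DEFAULT_WINDOW_LENGTH

    def __post_init__(self) -> None:
        if self.stage_tag is not None and self.stage_tag not in STAGE_TAGS:
            raise ValueError(f"unknown stage tag {self.stage_tag!r}")
        self.validate()

    def validate(self) -> None:
        for rec in self.records:
            if len(rec.sequence) != self.window_length:
                raise ValueError(
                    f"{rec.seq_id}: sequence length {len(rec.sequence)} != "
                    f"configured window length {self.window_length}"
                )
        if self.stage_tag in {"P0", "P"}:
            self._require_single_label(PROMOTER)
        elif self.stage_tag in {"C0", "C", "R0", "R"}:
            self._require_single_label(NON_PROMOTER)

    def _require_single_label(self, label: str) -> None:
        for rec in self.records:
            if rec.label != label:
                raise ValueError(
                    f"stage {self.stage_tag}: record {rec.seq_id} has label "
                    f"{rec.label!r}, expected {label!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.records)

    def species_ids(self) -> list[str]:
        """Distinct species in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.species_id, None)
        return list(seen)

    def by_species(self) -> dict[str, list[LabeledSequence]]:
        out: dict[str, list[LabeledSequence]] = {}
        for rec in self.records:
            out.setdefault(rec.species_id, []).append(rec)
        return out

    def subset(self, records: list[LabeledSequence], stage_tag: str | None = None) -> "SequenceSet":
        return SequenceSet(records=records, stage_tag=stage_tag, window_length=self.window_length)

    def sequences(self) -> list[str]:
        return [rec.sequence for rec in self.records]

    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]


@dataclass(frozen=True, slots=True)
class PredictionRecord:
    """Per-sequence classifier output joined with ground truth."""

    seq_id: str
    species_id: str
    true_label: str
    probability: float  # promoter-class score

    def __post_init__(self) -> None:
        if self.true_label not in LABELS:
            raise ValueError(f"{self.seq_id}: label {self.true_label!r} not in {sorted(LABELS)}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"{self.seq_id}: probability {self.probability} outside [0, 1]"
            )
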