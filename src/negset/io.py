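"""Readers and writers for FASTA, BED6, GFF3 and the internal TSV tables.

Internal coordinates are 0-based half-open everywhere; only this module
converts. BED is 0-based half-open on disk (no conversion); GFF3 is
1-based closed (converted on the way in and out).
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .core import (
    CdsRecord,
    DNA_ALPHABET,
    Genome,
    LabeledSequence,
    PredictionRecord,
    SequenceSet,
    TssRecord,
)

DATASET_COLUMNS = ["seq_id", "species_id", "sequence", "label", "origin"]
PREDICTION_COLUMNS = ["seq_id", "species_id", "true_label", "probability"]


class ParseError(ValueError):
    """A file violated the format contract; the message names the spot."""


# ---------------------------------------------------------------------------
# FASTA

def _species_from_description(record: SeqRecord) -> str:
    for token in record.description.split():
        if token.startswith("species="):
            return token[len("species="):]
    return record.id


def read_fasta(path: str | os.PathLike, *, permissive: bool = False) -> list[Genome]:
    """Load genomes from FASTA, uppercasing soft-masked sequence.

    Characters outside A/C/G/T/N raise :class:`ParseError` by default;
    with ``permissive=True`` they are replaced by N.
    """
    genomes: list[Genome] = []
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise ParseError(f"{path}: empty file")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            bad = set(seq) - (DNA_ALPHABET | {"N"})
            if bad:
                if not permissive:
                    raise ParseError(
                        f"{path}: record {record.id!r}: illegal characters "
                        f"{sorted(bad)} (pass permissive=True to map them to N)"
                    )
                seq = "".join(c if c in DNA_ALPHABET else "N" for c in seq)
            genomes.append(
                Genome(genome_id=record.id, species_id=_species_from_description(record), sequence=seq)
            )
    if not genomes:
        raise ParseError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | os.PathLike) -> None:
    """Write genomes as FASTA wrapped at 70 columns, tagging the species."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.genome_id, description=f"species={g.species_id}")
        for g in genomes
    ]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=70)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Annotations (BED6 / GFF3)

def _check_bounds(position: int, end: int, genome: Genome | None, where: str) -> None:
    if genome is not None and end > len(genome):
        raise ParseError(f"{where}: coordinate {end} outside genome "
                         f"{genome.genome_id!r} of length {len(genome)}")
    if position < 0:
        raise ParseError(f"{where}: negative coordinate {position}")


def read_annotations(
    path: str | os.PathLike,
    kind: str,
    dialect: str,
    genome: Genome | None = None,
) -> list[TssRecord] | list[CdsRecord]:
    """Read TSS or CDS records from a BED6 or GFF3 file.

    Parameters
    ----------
    kind : {"tss", "cds"}
    dialect : {"BED", "GFF3"}
        Must be declared explicitly; BED is 0-based half-open, GFF3 is
        1-based closed. A TSS from GFF3 is ``start-1`` on '+' and
        ``end-1`` on '-'.
    genome : optional
        When given, coordinates are validated against its length.
    """
    if kind not in {"tss", "cds"}:
        raise ValueError(f"kind must be 'tss' or 'cds', got {kind!r}")
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"dialect must be 'BED' or 'GFF3', got {dialect!r}")

    records: list[TssRecord | CdsRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            where = f"{path}: line {lineno}"
            if dialect == "BED":
                if len(fields) < 6:
                    raise ParseError(f"{where}: BED6 requires 6 columns, got {len(fields)}")
                chrom, start_s, end_s, _name, _score, strand = fields[:6]
                start, end = int(start_s), int(end_s)
            else:
                if len(fields) < 8:
                    raise ParseError(f"{where}: GFF3 requires >= 8 columns, got {len(fields)}")
                chrom, _src, _type, start_s, end_s, _score, strand = fields[:7]
                start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            if strand not in {"+", "-"}:
                raise ParseError(f"{where}: missing or invalid strand {strand!r} "
                                 "(strand is required for window extraction)")
            if kind == "tss":
                position = start if strand == "+" else end - 1
                _check_bounds(position, position + 1, genome, where)
                records.append(TssRecord(genome_id=chrom, position=position, strand=strand))
            else:
                _check_bounds(start, end, genome, where)
                records.append(CdsRecord(genome_id=chrom, start=start, end=end, strand=strand))
    return records


def write_annotations(
    records: Iterable[TssRecord] | Iterable[CdsRecord],
    path: str | os.PathLike,
    dialect: str = "BED",
) -> None:
    """Write TSS (1-bp features) or CDS intervals as BED6 or GFF3."""
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"dialect must be 'BED' or 'GFF3', got {dialect!r}")
    with open(path, "w") as handle:
        for rec in records:
            if isinstance(rec, TssRecord):
                start, end, feat = rec.position, rec.position + 1, "TSS"
            else:
                start, end, feat = rec.start, rec.end, "CDS"
            if dialect == "BED":
                handle.write(f"{rec.genome_id}\t{start}\t{end}\t{feat}\t.\t{rec.strand}\n")
            else:
                handle.write(
                    f"{rec.genome_id}\tnegset\t{feat}\t{start + 1}\t{end}\t.\t{rec.strand}\t.\t.\n"
                )


# ---------------------------------------------------------------------------
# Tabular datasets and predictions

def read_dataset(
    path: str | os.PathLike,
    stage_tag: str | None = None,
    window_length: int = 81,
) -> SequenceSet:
    """Read a labeled-sequence TSV; invariants enforced per row."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        seq = str(row.sequence)
        if len(seq) != window_length:
            raise ParseError(
                f"{path}: sequence {row.seq_id!r} has length {len(seq)}, "
                f"expected {window_length}"
            )
        records.append(
            LabeledSequence(
                seq_id=str(row.seq_id),
                species_id=str(row.species_id),
                sequence=seq,
                label=str(row.label),
                origin=str(row.origin),
            )
        )
    return SequenceSet(records=records, stage_tag=stage_tag, window_length=window_length)


def write_dataset(dataset: SequenceSet, path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [
            (r.seq_id, r.species_id, r.sequence, r.label, r.origin)
            for r in dataset.records
        ],
        columns=DATASET_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | os.PathLike) -> list[PredictionRecord]:
    """Read a prediction TSV; probabilities outside [0, 1] are rejected."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        prob = float(row.probability)
        if not (0.0 <= prob <= 1.0):
            raise ParseError(
                f"{path}: record {row.seq_id!r}: probability {prob} outside [0, 1]"
            )
        records.append(
            PredictionRecord(
                seq_id=str(row.seq_id),
                species_id=str(row.species_id),
                true_label=str(row.true_label),
                probability=prob,
            )
        )
    return records


def write_predictions(records: Iterable[PredictionRecord], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [(r.seq_id, r.species_id, r.true_label, r.probability) for r in records],
        columns=PREDICTION_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
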