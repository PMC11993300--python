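"""Window extraction: promoter windows around TSS and random CDS negatives.

The promoter window spans ``upstream`` nt before the TSS through
``downstream`` nt after it (default -60/+20, 81 nt total), with the TSS
base at window offset ``upstream``. On the reverse strand the window is
the reverse complement of the mirrored genomic slice, so the TSS lands
at the same offset in window coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    CdsRecord,
    DNA_ALPHABET,
    Genome,
    LabeledSequence,
    NON_PROMOTER,
    PROMOTER,
    SequenceSet,
    TssRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class WindowConfig:
    upstream: int = 60
    downstream: int = 20

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream and downstream must be >= 0")

    @property
    def length(self) -> int:
        return self.upstream + 1 + self.downstream


def gc_content(sequence: str) -> float:
    """Fraction of G and C bases; rejects empty or ambiguous input."""
    if not sequence:
        raise ValueError("gc_content of an empty sequence is undefined")
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise ValueError(f"gc_content: illegal characters {sorted(bad)} "
                         "(windows containing N must be filtered upstream)")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def extract_promoter_window(
    genome: Genome,
    tss: TssRecord,
    config: WindowConfig = WindowConfig(),
    origin: str = "fixture",
) -> LabeledSequence | None:
    """Extract one promoter window, or None when it must be skipped.

    Skips (with a debug log) windows that run off the genome or contain
    N; contig-edge TSS are expected in real assemblies, so this is not
    an error.
    """
    up, down = config.upstream, config.downstream
    if tss.strand == "+":
        start, end = tss.position - up, tss.position + down + 1
    else:
        start, end = tss.position - down, tss.position + up + 1
    if start < 0 or end > len(genome):
        logger.debug("TSS %s:%d%s: window out of bounds, skipped",
                     tss.genome_id, tss.position, tss.strand)
        return None
    window = genome.sequence[start:end]
    if tss.strand == "-":
        window = reverse_complement(window)
    if "N" in window:
        logger.debug("TSS %s:%d%s: window contains N, skipped",
                     tss.genome_id, tss.position, tss.strand)
        return None
    return LabeledSequence(
        seq_id=f"{genome.genome_id}:{tss.position}:{tss.strand}",
        species_id=genome.species_id,
        sequence=window,
        label=PROMOTER,
        origin=origin,
    )


def extract_promoters(
    genome: Genome,
    tss_records: list[TssRecord],
    config: WindowConfig = WindowConfig(),
    origin: str = "fixture",
) -> tuple[list[LabeledSequence], int]:
    """Extract all valid promoter windows; returns (windows, n_skipped)."""
    out, skipped = [], 0
    for tss in tss_records:
        if tss.genome_id != genome.genome_id:
            continue
        rec = extract_promoter_window(genome, tss, config, origin=origin)
        if rec is None:
            skipped += 1
        else:
            out.append(rec)
    if skipped:
        logger.warning("%s: skipped %d promoter windows (out of bounds or N)",
                       genome.genome_id, skipped)
    return out, skipped


def sample_cds_negatives(
    genome: Genome,
    cds_records: list[CdsRecord],
    n_target: int,
    config: WindowConfig = WindowConfig(),
    seed: int | None = None,
    stranded: bool = True,
) -> list[LabeledSequence]:
    """Sample ``n_target`` windows uniformly over CDS bases, with replacement.

    A CDS is chosen with probability proportional to its number of valid
    start positions (length - window + 1), then a uniform start within
    it, so every eligible genomic window is equally likely. Reverse
    strand CDS yield the reverse-complemented (coding-orientation)
    sequence unless ``stranded=False``.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    if n_target == 0:
        return []
    window = config.length
    eligible = [c for c in cds_records
                if c.genome_id == genome.genome_id and len(c) >= window]
    if not eligible:
        raise ValueError(
            f"{genome.genome_id}: no CDS of length >= {window} to sample from"
        )
    starts = np.array([len(c) - window + 1 for c in eligible], dtype=float)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(eligible), size=n_target, p=starts / starts.sum())
    out: list[LabeledSequence] = []
    for i, idx in enumerate(which):
        cds = eligible[idx]
        offset = int(rng.integers(0, len(cds) - window + 1))
        s = cds.start + offset
        seq = genome.sequence[s:s + window]
        if stranded and cds.strand == "-":
            seq = reverse_complement(seq)
        if "N" in seq:
            # keep the count deterministic: resample this draw from a
            # fresh uniform start until N-free (CDS are rarely masked)
            for _ in range(100):
                offset = int(rng.integers(0, len(cds) - window + 1))
                s = cds.start + offset
                seq = genome.sequence[s:s + window]
                if stranded and cds.strand == "-":
                    seq = reverse_complement(seq)
                if "N" not in seq:
                    break
            else:
                raise ValueError(f"{genome.genome_id}: CDS {cds.start}-{cds.end} "
                                 "appears saturated with N")
        out.append(
            LabeledSequence(
                seq_id=f"{genome.genome_id}:CDS:{i}:{s}",
                species_id=genome.species_id,
                sequence=seq,
                label=NON_PROMOTER,
                origin="CDS",
            )
        )
    return out


def extract_all(
    genomes: list[Genome],
    tss_records: list[TssRecord],
    cds_records: list[CdsRecord],
    config: WindowConfig = WindowConfig(),
    ratio: float = 2.0,
    seed: int | None = None,
    promoter_origin: str = "fixture",
) -> tuple[SequenceSet, SequenceSet]:
    """Build the raw positive (P0) and CDS-negative (C0) sets.

    Per species, the negative count is ``ratio`` times the number of
    surviving promoter windows (default 2x, so that enough negatives
    remain after redundancy filtering to balance the dataset).
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    pos: list[LabeledSequence] = []
    neg: list[LabeledSequence] = []
    for i, genome in enumerate(genomes):
        p, _ = extract_promoters(genome, tss_records, config, origin=promoter_origin)
        if not p:
            logger.warning("%s: no valid promoter windows, species skipped",
                           genome.genome_id)
            continue
        n_target = int(round(ratio * len(p)))
        c = sample_cds_negatives(genome, cds_records, n_target, config, seed=seed + i)
        pos.extend(p)
        neg.extend(c)
    return (
        SequenceSet(records=pos, stage_tag="P0", window_length=config.length),
        SequenceSet(records=neg, stage_tag="C0", window_length=config.length),
    )
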