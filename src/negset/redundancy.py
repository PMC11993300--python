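"""Redundancy reduction and cross-filtering at an identity threshold.

All sequences in this pipeline are fixed-length windows, so the builtin
engine defines identity as the ungapped, end-to-end fraction of
matching positions — a deterministic, order-stable reading of the
CD-HIT criterion (which sorts by length and uses banded alignment;
lengths are all equal here, so input order is the greedy tiebreak). An
``external-cdhit`` engine shells out to ``cd-hit-est`` for users who
want exact parity with that program.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import SequenceSet

_CODE = {c: i for i, c in enumerate("ACGT")}


@dataclass(frozen=True, slots=True)
class IdentityConfig:
    threshold: float = 0.8
    word_size: int = 5  # k-mer prescreen word length
    engine: str = "builtin"
    prescreen: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold {self.threshold} outside (0, 1]")
        if not (1 <= self.word_size <= 12):
            raise ValueError(f"word_size {self.word_size} outside [1, 12]")
        if self.engine not in {"builtin", "external-cdhit"}:
            raise ValueError(f"unknown engine {self.engine!r}")


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped end-to-end identity: matching positions / length."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _encode(sequences: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    return arr.reshape(len(sequences), -1)


def _word_prescreen_floor(length: int, config: IdentityConfig) -> int:
    """Minimum same-offset shared words any pair at >= threshold must have.

    A pair with at most d mismatches destroys at most ``word_size * d``
    of the ``length - word_size + 1`` aligned words. When the bound is
    <= 0 the prescreen can prove nothing and never skips a pair — which
    is the case at the default 0.8 threshold on 81-mers with word 5.
    """
    m_min = int(np.ceil(config.threshold * length))
    d_max = length - m_min
    return (length - config.word_size + 1) - config.word_size * d_max


def _word_sets(sequences: list[str], k: int) -> list[set[tuple[int, str]]]:
    return [
        {(i, seq[i:i + k]) for i in range(len(seq) - k + 1)}
        for seq in sequences
    ]


def _one_hot_f32(sequences: list[str]) -> np.ndarray:
    """(n, 4L) float32 one-hot; dot product of two rows = match count."""
    arr = _encode(sequences)
    lut = np.zeros(256, dtype=np.int64)
    for c, i in _CODE.items():
        lut[ord(c)] = i
    codes = lut[arr]
    out = np.zeros((*codes.shape, 4), dtype=np.float32)
    np.put_along_axis(out, codes[..., None], 1.0, axis=2)
    return out.reshape(len(sequences), -1)


def _greedy_dedup_indices(seqs: list[str], min_matches: int, chunk: int = 1024) -> list[int]:
    """Greedy survivor indices via blocked one-hot matmul (exact)."""
    enc = _one_hot_f32(seqs)
    kept: list[int] = []
    for lo in range(0, len(seqs), chunk):
        block = enc[lo:lo + chunk]
        if kept:
            vs_kept = (block @ enc[kept].T) >= min_matches
            conflict_prev = vs_kept.any(axis=1)
        else:
            conflict_prev = np.zeros(block.shape[0], dtype=bool)
        within = (block @ block.T) >= min_matches
        kept_local: list[int] = []
        for i in range(block.shape[0]):
            if conflict_prev[i]:
                continue
            if kept_local and within[i, kept_local].any():
                continue
            kept_local.append(i)
        kept.extend(lo + i for i in kept_local)
    return kept


def dedup_within(dataset: SequenceSet, config: IdentityConfig = IdentityConfig()) -> SequenceSet:
    """Greedy incremental clustering within one set.

    Records are visited in input order; a record survives iff its
    identity to every previously kept record is below the threshold
    (exact duplicates fall out of the same rule). The k-mer prescreen
    only ever skips identity computations for pairs it can prove are
    below threshold, so it never changes the result; at the default
    threshold/word size its sound bound proves nothing and the blocked
    exact path runs instead.
    """
    if config.engine == "external-cdhit":
        return _external_cdhit(dataset, against=None, config=config)
    seqs = dataset.sequences()
    if not seqs:
        return dataset.subset([], stage_tag=_filtered_tag(dataset.stage_tag))
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("dedup_within requires uniform sequence length")
    min_matches = int(np.ceil(config.threshold * length))
    floor = _word_prescreen_floor(length, config) if config.prescreen else 0
    if floor <= 0:
        kept_idx = _greedy_dedup_indices(seqs, min_matches)
    else:
        kept_idx = _greedy_dedup_prescreened(seqs, min_matches, floor, config)
    records = [dataset.records[i] for i in kept_idx]
    return dataset.subset(records, stage_tag=_filtered_tag(dataset.stage_tag))


def _greedy_dedup_prescreened(
    seqs: list[str], min_matches: int, floor: int, config: IdentityConfig
) -> list[int]:
    words = _word_sets(seqs, config.word_size)
    encoded = _encode(seqs)
    kept_idx: list[int] = []
    for i in range(len(seqs)):
        candidates = [k for k in kept_idx if len(words[i] & words[k]) >= floor]
        redundant = False
        if candidates:
            matches = (encoded[candidates] == encoded[i]).sum(axis=1)
            redundant = bool((matches >= min_matches).any())
        if not redundant:
            kept_idx.append(i)
    return kept_idx


def cross_filter(
    negatives: SequenceSet,
    positives: SequenceSet,
    config: IdentityConfig = IdentityConfig(),
) -> SequenceSet:
    """Drop negatives at >= threshold identity to any positive.

    Positives are authoritative and never modified.
    """
    if config.engine == "external-cdhit":
        return _external_cdhit(negatives, against=positives, config=config)
    if not len(negatives) or not len(positives):
        return negatives.subset(list(negatives.records),
                                stage_tag=_filtered_tag(negatives.stage_tag))
    neg_seqs, pos_seqs = negatives.sequences(), positives.sequences()
    length = len(pos_seqs[0])
    if any(len(s) != length for s in neg_seqs):
        raise ValueError("cross_filter requires uniform sequence length")
    min_matches = int(np.ceil(config.threshold * length))
    floor = _word_prescreen_floor(length, config) if config.prescreen else 0
    if floor <= 0:
        pos_enc = _one_hot_f32(pos_seqs)
        neg_enc = _one_hot_f32(neg_seqs)
        keep_mask = np.ones(len(neg_seqs), dtype=bool)
        for lo in range(0, len(neg_seqs), 1024):
            block = neg_enc[lo:lo + 1024]
            hits = (block @ pos_enc.T) >= min_matches
            keep_mask[lo:lo + block.shape[0]] = ~hits.any(axis=1)
        kept = [rec for rec, ok in zip(negatives.records, keep_mask) if ok]
        return negatives.subset(kept, stage_tag=_filtered_tag(negatives.stage_tag))
    pos_enc = _encode(pos_seqs)
    neg_enc = _encode(neg_seqs)
    pos_words = _word_sets(pos_seqs, config.word_size)
    neg_words = _word_sets(neg_seqs, config.word_size)
    kept = []
    for i, rec in enumerate(negatives.records):
        cand = [j for j in range(len(pos_seqs))
                if len(neg_words[i] & pos_words[j]) >= floor]
        if not cand:
            kept.append(rec)
            continue
        matches = (pos_enc[cand] == neg_enc[i]).sum(axis=1)
        if not (matches >= min_matches).any():
            kept.append(rec)
    return negatives.subset(kept, stage_tag=_filtered_tag(negatives.stage_tag))


def _filtered_tag(tag: str | None) -> str | None:
    return {"P0": "P", "C0": "C", "R0": "R"}.get(tag, tag)


# ---------------------------------------------------------------------------
# Optional external engine

def _external_cdhit(
    dataset: SequenceSet,
    against: SequenceSet | None,
    config: IdentityConfig,
) -> SequenceSet:
    """Run cd-hit-est (dedup) or cd-hit-est-2d (cross-filter) if installed."""
    exe = "cd-hit-est" if against is None else "cd-hit-est-2d"
    if shutil.which(exe) is None:
        raise RuntimeError(
            f"{exe} not found on PATH; use engine='builtin' or install CD-HIT"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fa = tmp / "in.fa"
        with open(fa, "w") as fh:
            for rec in dataset.records:
                fh.write(f">{rec.seq_id}\n{rec.sequence}\n")
        out = tmp / "out.fa"
        cmd = [exe]
        if against is not None:
            fa2 = tmp / "ref.fa"
            with open(fa2, "w") as fh:
                for rec in against.records:
                    fh.write(f">{rec.seq_id}\n{rec.sequence}\n")
            cmd += ["-i", str(fa2), "-i2", str(fa)]
        else:
            cmd += ["-i", str(fa)]
        cmd += ["-o", str(out), "-c", str(config.threshold), "-n", str(config.word_size)]
        subprocess.run(cmd, check=True, capture_output=True)
        kept_ids = {
            line[1:].split()[0]
            for line in out.read_text().splitlines()
            if line.startswith(">")
        }
    records = [r for r in dataset.records if r.seq_id in kept_ids]
    return dataset.subset(records, stage_tag=_filtered_tag(dataset.stage_tag))
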