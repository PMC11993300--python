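"""Sliding-window promoter probability tracks over genomic sequence.

Each window's promoter probability is attributed to every position the
window covers; a position's track value is the mean over its covering
windows. Near interval edges fewer windows cover a position, so the
mean simply runs over fewer values — no sequence is fabricated by
padding. An alternative ``tss-offset`` attribution assigns each
window's probability only to its TSS slot (window offset 60).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Genome, TssRecord

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class ScanProfile:
    genome_id: str
    start: int
    end: int  # 0-based half-open scanned interval
    values: np.ndarray  # mean probability per position, NaN where uncovered
    coverage: np.ndarray  # windows covering each position
    window: int
    stride: int

    def position_index(self) -> np.ndarray:
        return np.arange(self.start, self.end)


def _predictor_probs(predictor, windows: list[str]) -> np.ndarray:
    """Promoter probability from an estimator, a 1-column fn, or a callable."""
    if hasattr(predictor, "promoter_proba"):
        return np.asarray(predictor.promoter_proba(windows), dtype=float)
    if hasattr(predictor, "predict_proba"):
        out = np.asarray(predictor.predict_proba(windows), dtype=float)
        return out[:, 1] if out.ndim == 2 else out
    return np.asarray(predictor(windows), dtype=float)


def scan(
    predictor,
    genome: Genome,
    interval: tuple[int, int] | None = None,
    stride: int = 1,
    window: int = 81,
    attribute: str = "full-window",
    batch_size: int = 512,
) -> ScanProfile:
    """Scan an interval at the given stride and build the probability track.

    Windows containing N are skipped and simply do not contribute to
    coverage. The result is independent of ``batch_size``.
    """
    start, end = interval if interval is not None else (0, len(genome))
    if not (0 <= start < end <= len(genome)):
        raise ValueError(f"interval [{start}, {end}) outside genome of length {len(genome)}")
    if end - start < window:
        raise ValueError(f"interval length {end - start} shorter than window {window}")
    if attribute not in {"full-window", "tss-offset"}:
        raise ValueError(f"unknown attribution mode {attribute!r}")
    length = end - start
    sums = np.zeros(length)
    coverage = np.zeros(length, dtype=int)
    starts = list(range(start, end - window + 1, stride))
    n_skipped = 0
    for b in range(0, len(starts), batch_size):
        batch = starts[b:b + batch_size]
        windows, kept = [], []
        for s in batch:
            seq = genome.sequence[s:s + window]
            if "N" in seq:
                n_skipped += 1
                continue
            windows.append(seq)
            kept.append(s)
        if not windows:
            continue
        probs = _predictor_probs(predictor, windows)
        for s, p in zip(kept, probs):
            i = s - start
            if attribute == "full-window":
                sums[i:i + window] += p
                coverage[i:i + window] += 1
            else:
                sums[i + 60] += p
                coverage[i + 60] += 1
    if n_skipped:
        logger.warning("%s: skipped %d windows containing N", genome.genome_id, n_skipped)
    values = np.full(length, np.nan)
    covered = coverage > 0
    values[covered] = sums[covered] / coverage[covered]
    return ScanProfile(genome_id=genome.genome_id, start=start, end=end,
                       values=values, coverage=coverage, window=window, stride=stride)


def write_track(profile: ScanProfile, path, precision: int = 6) -> None:
    """Write the profile as bedGraph, merging runs of equal value.

    Coordinates are 0-based half-open per the bedGraph convention;
    values are fixed to ``precision`` decimals and runs are merged on
    the formatted value, so a round-trip parse reproduces the file's
    numbers exactly. Uncovered (NaN) positions are omitted.
    """
    with open(path, "w") as fh:
        run_start = None
        run_value = None
        for i, v in enumerate(profile.values):
            text = None if np.isnan(v) else f"{v:.{precision}f}"
            if text != run_value:
                if run_value is not None:
                    fh.write(f"{profile.genome_id}\t{profile.start + run_start}\t"
                             f"{profile.start + i}\t{run_value}\n")
                run_start, run_value = i, text
        if run_value is not None:
            fh.write(f"{profile.genome_id}\t{profile.start + run_start}\t"
                     f"{profile.end}\t{run_value}\n")


def signal_at_tss(
    profile: ScanProfile,
    tss_records: list[TssRecord],
    flank: int = 100,
) -> list[dict]:
    """Local track deviation around each TSS.

    For each TSS inside the profile: mean value over
    [tss - flank, tss + flank] minus the mean value over the rest of
    the profile. Sign is kept, so both direct peaks and inverted dips
    (a model behaving as 1 - P) are visible. TSS outside the interval
    are skipped with a warning.
    """
    out = []
    values = profile.values
    for tss in tss_records:
        if tss.genome_id != profile.genome_id:
            continue
        if not (profile.start <= tss.position < profile.end):
            logger.warning("TSS %s:%d outside scanned interval, skipped",
                           tss.genome_id, tss.position)
            continue
        lo = max(profile.start, tss.position - flank) - profile.start
        hi = min(profile.end, tss.position + flank + 1) - profile.start
        inside = values[lo:hi]
        outside = np.concatenate([values[:lo], values[hi:]])
        inside_mean = float(np.nanmean(inside)) if np.any(~np.isnan(inside)) else np.nan
        outside_mean = float(np.nanmean(outside)) if outside.size and np.any(~np.isnan(outside)) else np.nan
        out.append({
            "genome_id": tss.genome_id,
            "position": tss.position,
            "strand": tss.strand,
            "inside_mean": inside_mean,
            "outside_mean": outside_mean,
            "deviation": inside_mean - outside_mean,
        })
    return out
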