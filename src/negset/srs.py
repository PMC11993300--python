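"""Synthetic random sequence (SRS) negatives matched to promoter GC.

The per-species promoter GC distribution is estimated with a Gaussian
kernel density (Scott's-rule bandwidth); GC targets for the synthetic
negatives are then drawn from that density, and each 81-nt sequence is
synthesized position-wise at its target composition. The resulting
negative set shares the species' promoter GC distribution (mean
difference under 2 percentage points at corpus sizes of a few hundred
sequences and up), which removes composition as a shortcut feature for
downstream classifiers.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from sklearn.base import BaseEstimator

from .core import NON_PROMOTER, SequenceSet, LabeledSequence
from .windows import gc_content

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: bandwidth when every training value is identical (degenerate KDE)
DEGENERATE_BANDWIDTH = 0.01


class GcKde(BaseEstimator):
    """Gaussian KDE over GC fractions, with a sampler.

    Parameters
    ----------
    bandwidth : "scott" or float
        Scott's rule is ``n**(-1/5) * sd`` in GC-fraction units; when
        the sample standard deviation is zero (all training values
        identical) the bandwidth falls back to 0.01.

    Attributes
    ----------
    sample_values_ : ndarray
        The GC fractions the density was fitted on.
    bandwidth_ : float
        The realized kernel width.
    """

    def __init__(self, bandwidth: str | float = "scott", species_id: str | None = None):
        self.bandwidth = bandwidth
        self.species_id = species_id

    def fit(self, gc_values) -> "GcKde":
        values = np.asarray(list(gc_values), dtype=float)
        if values.size == 0:
            raise ValueError(f"GcKde({self.species_id}): no GC values to fit on")
        if np.any((values < 0) | (values > 1)):
            raise ValueError(f"GcKde({self.species_id}): GC values outside [0, 1]")
        if self.bandwidth == "scott":
            sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
            bw = values.size ** (-1 / 5) * sd
            if bw <= 0.0:
                bw = DEGENERATE_BANDWIDTH
        else:
            bw = float(self.bandwidth)
            if bw <= 0:
                raise ValueError("bandwidth must be > 0")
        self.sample_values_ = values
        self.bandwidth_ = bw
        return self

    def density(self, grid) -> np.ndarray:
        """KDE density evaluated on ``grid`` (for inspection/plots)."""
        grid = np.asarray(grid, dtype=float)[:, None]
        z = (grid - self.sample_values_[None, :]) / self.bandwidth_
        k = np.exp(-0.5 * z ** 2) / np.sqrt(2 * np.pi)
        return k.mean(axis=1) / self.bandwidth_

    def sample(self, n: int, seed: int | None = None) -> np.ndarray:
        """Draw ``n`` GC fractions from the fitted density.

        Each draw picks a training value uniformly and adds Gaussian
        noise of s.d. equal to the bandwidth; draws landing outside
        [0, 1] are rejected and redrawn, keeping the density proper
        without boundary mass spikes.
        """
        if seed is None:
            raise ValueError("seed is required (reproducibility contract)")
        if n < 0:
            raise ValueError("n must be >= 0")
        rng = np.random.default_rng(seed)
        out = np.empty(n, dtype=float)
        filled = 0
        while filled < n:
            todo = n - filled
            centers = self.sample_values_[rng.integers(0, self.sample_values_.size, size=todo)]
            draws = centers + rng.normal(0.0, self.bandwidth_, size=todo)
            ok = (draws >= 0.0) & (draws <= 1.0)
            k = int(ok.sum())
            out[filled:filled + k] = draws[ok]
            filled += k
        return out

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "bandwidth": self.bandwidth_,
            "n_training_values": int(self.sample_values_.size),
            "training_mean_gc": float(self.sample_values_.mean()),
        }


def fit_gc_kde(promoters: SequenceSet, species_id: str, bandwidth: str | float = "scott") -> GcKde:
    """Fit the per-species GC density on a promoter set."""
    values = [gc_content(r.sequence) for r in promoters if r.species_id == species_id]
    if not values:
        raise ValueError(f"no promoters for species {species_id!r}")
    return GcKde(bandwidth=bandwidth, species_id=species_id).fit(values)


def sample_gc(kde: GcKde, n: int, seed: int | None = None) -> np.ndarray:
    return kde.sample(n, seed=seed)


def synthesize_sequence(
    gc_target: float,
    length: int = 81,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> str:
    """One random sequence at the target composition.

    Default mode draws each position i.i.d. with
    P(G) = P(C) = gc_target/2 and P(A) = P(T) = (1-gc_target)/2, so the
    realized GC varies binomially around the target. ``exact=True``
    instead places round(gc_target*length) G/C bases and shuffles.
    """
    if not (0.0 <= gc_target <= 1.0):
        raise ValueError(f"gc_target {gc_target} outside [0, 1]")
    if length < 1:
        raise ValueError("length must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("seed is required (reproducibility contract)")
        rng = np.random.default_rng(seed)
    if exact:
        n_gc = int(round(gc_target * length))
        n_g = n_gc // 2 + int(rng.random() < 0.5) * (n_gc % 2)
        n_at = length - n_gc
        n_a = n_at // 2 + int(rng.random() < 0.5) * (n_at % 2)
        codes = np.array([2] * n_g + [1] * (n_gc - n_g) + [0] * n_a + [3] * (n_at - n_a))
        rng.shuffle(codes)
    else:
        p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
        codes = rng.choice(4, size=length, p=p)
    return "".join(_BASES[codes])


def generate_srs(
    promoters: SequenceSet,
    ratio: float = 2.0,
    seed: int | None = None,
    bandwidth: str | float = "scott",
    length: int | None = None,
    exact: bool = False,
) -> tuple[SequenceSet, dict]:
    """Build the raw synthetic negative set (R0) from a promoter set.

    Per species: fit the GC KDE on its promoters, draw
    ``ratio * n_promoters`` GC targets, synthesize one sequence per
    target. Returns the R0 set and a JSON-serializable sidecar with the
    fitted KDE parameters (for reproducibility audits).
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    length = promoters.window_length if length is None else length
    records: list[LabeledSequence] = []
    sidecar: dict = {"bandwidth_rule": bandwidth, "ratio": ratio, "seed": seed, "species": []}
    for i, (species, recs) in enumerate(promoters.by_species().items()):
        if not recs:
            logger.warning("species %s: zero promoters, skipped", species)
            continue
        kde = GcKde(bandwidth=bandwidth, species_id=species).fit(
            [gc_content(r.sequence) for r in recs]
        )
        n = int(round(ratio * len(recs)))
        targets = kde.sample(n, seed=seed + i)
        rng = np.random.default_rng(seed + 100_003 + i)
        for j, gc in enumerate(targets):
            records.append(
                LabeledSequence(
                    seq_id=f"{species}:SRS:{j}",
                    species_id=species,
                    sequence=synthesize_sequence(float(gc), length=length, rng=rng, exact=exact),
                    label=NON_PROMOTER,
                    origin="SRS",
                )
            )
        sidecar["species"].append(kde.to_dict() | {"n_generated": n})
    return SequenceSet(records=records, stage_tag="R0", window_length=length), sidecar


def dump_sidecar(sidecar: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
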