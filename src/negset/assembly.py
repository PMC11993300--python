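"""Merging filtered sets into balanced datasets and splitting them.

Balancing is per species: exactly as many negatives as surviving
positives are drawn (without replacement, seeded), so the per-species
label balance in the merged dataset D is exact. The train/validation
split is stratified by species x label with largest-remainder rounding,
so even small species keep representation in both partitions — a
prerequisite for any per-species audit of the trained model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import LabeledSequence, NON_PROMOTER, PROMOTER, SequenceSet

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class DatasetSplit:
    train: SequenceSet
    validation: SequenceSet
    train_fraction: float
    seed: int


def balance_and_merge(
    positives: SequenceSet,
    negatives: SequenceSet,
    seed: int | None = None,
    keep_first: bool = False,
) -> SequenceSet:
    """Merge positives with an equal per-species number of negatives.

    Negatives are sampled without replacement (uniform, seeded) when
    oversupplied; ``keep_first=True`` instead keeps the first
    ``n_positives`` negatives per species (deterministic debugging
    mode). The merged set is shuffled (seeded). Raises when any species
    has fewer negatives than positives — no partial output.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    pos_by_sp = positives.by_species()
    neg_by_sp = negatives.by_species()
    shortfalls = {
        sp: (len(pos_by_sp[sp]), len(neg_by_sp.get(sp, [])))
        for sp in pos_by_sp
        if len(neg_by_sp.get(sp, [])) < len(pos_by_sp[sp])
    }
    if shortfalls:
        detail = "; ".join(
            f"{sp}: {n_neg} negatives < {n_pos} positives"
            for sp, (n_pos, n_neg) in sorted(shortfalls.items())
        )
        raise ValueError(f"insufficient negatives after filtering: {detail}")
    rng = np.random.default_rng(seed)
    merged: list[LabeledSequence] = []
    for sp, pos_recs in pos_by_sp.items():
        neg_recs = neg_by_sp[sp]
        if keep_first:
            chosen = neg_recs[: len(pos_recs)]
        else:
            idx = rng.choice(len(neg_recs), size=len(pos_recs), replace=False)
            chosen = [neg_recs[i] for i in np.sort(idx)]
        merged.extend(pos_recs)
        merged.extend(chosen)
    order = rng.permutation(len(merged))
    merged = [merged[i] for i in order]
    return SequenceSet(records=merged, stage_tag="D", window_length=positives.window_length)


def split_dataset(
    dataset: SequenceSet,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> DatasetSplit:
    """Stratified (species x label) train/validation partition.

    Per-stratum train counts are rounded by largest remainder against
    the global fraction; a stratum with fewer than 2 records goes
    entirely to train (with a warning) since it cannot be split.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction {train_fraction} outside (0, 1)")
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(dataset.records):
        strata.setdefault((rec.species_id, rec.label), []).append(i)

    keys = list(strata)
    exact = np.array([len(strata[k]) * train_fraction for k in keys])
    floors = np.floor(exact).astype(int)
    remainder_total = int(round(exact.sum())) - floors.sum()
    # largest remainders get the leftover training slots
    order = np.argsort(-(exact - floors), kind="stable")
    counts = floors.copy()
    for j in order[:remainder_total]:
        counts[j] += 1

    train_idx: list[int] = []
    val_idx: list[int] = []
    for k, n_train in zip(keys, counts):
        members = strata[k]
        if len(members) < 2:
            logger.warning("stratum %s has <2 records; assigned to train", k)
            train_idx.extend(members)
            continue
        n_train = min(max(int(n_train), 1), len(members) - 1)
        perm = rng.permutation(len(members))
        train_idx.extend(members[i] for i in perm[:n_train])
        val_idx.extend(members[i] for i in perm[n_train:])
    train_idx.sort()
    val_idx.sort()
    return DatasetSplit(
        train=dataset.subset([dataset.records[i] for i in train_idx], stage_tag=dataset.stage_tag),
        validation=dataset.subset([dataset.records[i] for i in val_idx], stage_tag=dataset.stage_tag),
        train_fraction=train_fraction,
        seed=seed,
    )


def min_promoter_filter(
    datasets: dict[str, SequenceSet] | SequenceSet,
    min_count: int = 200,
) -> dict[str, SequenceSet] | SequenceSet:
    """Drop species with <= ``min_count`` promoters (strictly more survive).

    Mirrors the corpus pre-selection rule requiring more than 200
    promoters per species. Accepts either a single set or a mapping of
    named sets sharing the same species universe; species counts are
    taken from promoter-labeled records.
    """
    single = isinstance(datasets, SequenceSet)
    mapping = {"_": datasets} if single else dict(datasets)
    counts: dict[str, int] = {}
    for ds in mapping.values():
        for rec in ds.records:
            if rec.label == PROMOTER:
                counts[rec.species_id] = counts.get(rec.species_id, 0) + 1
    keep = {sp for sp, n in counts.items() if n > min_count}
    dropped = sorted(set(counts) - keep)
    if dropped:
        logger.info("min_promoter_filter: dropped species %s (<= %d promoters)",
                    dropped, min_count)
    out = {
        name: ds.subset([r for r in ds.records if r.species_id in keep],
                        stage_tag=ds.stage_tag)
        for name, ds in mapping.items()
    }
    return out["_"] if single else out
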