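"""The seven performance metrics and GC-content bias diagnostics.

Reports carry specificity (Sp), sensitivity (Sn), precision (Pre),
accuracy (Acc), Matthews correlation coefficient (MCC), F1 and ROC AUC,
globally and per species. Ratios with a zero denominator are reported
as NaN with an explicit reason — small species must never get
fabricated numbers. GC is a fraction internally and percentage points
in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import PROMOTER, PredictionRecord, SequenceSet
from .windows import gc_content

CATEGORIES = ("TP", "TN", "FP", "FN")


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(slots=True)
class MetricReport:
    sp: float
    sn: float
    pre: float
    acc: float
    mcc: float
    f1: float
    roc_auc: float
    scope: str = "global"
    counts: ConfusionCounts | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "scope": self.scope, "sp": self.sp, "sn": self.sn, "pre": self.pre,
            "acc": self.acc, "mcc": self.mcc, "f1": self.f1, "roc_auc": self.roc_auc,
            "undefined": dict(self.undefined),
        }


def confusion(
    predictions: list[PredictionRecord], threshold: float = 0.5
) -> ConfusionCounts:
    """Tally confusion counts; probability >= threshold predicts promoter."""
    if not predictions:
        raise ValueError("confusion of an empty prediction list is undefined")
    tp = tn = fp = fn = 0
    for rec in predictions:
        predicted_pos = rec.probability >= threshold
        actual_pos = rec.true_label == PROMOTER
        if predicted_pos and actual_pos:
            tp += 1
        elif predicted_pos:
            fp += 1
        elif actual_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def categorize(rec: PredictionRecord, threshold: float = 0.5) -> str:
    predicted_pos = rec.probability >= threshold
    actual_pos = rec.true_label == PROMOTER
    if actual_pos:
        return "TP" if predicted_pos else "FN"
    return "FP" if predicted_pos else "TN"


def _ratio(num: float, den: float, name: str, undefined: dict[str, str]) -> float:
    if den == 0:
        undefined[name] = f"denominator of {name} is zero"
        return math.nan
    return num / den


def metrics(
    counts: ConfusionCounts,
    predictions: list[PredictionRecord] | None = None,
    scope: str = "global",
) -> MetricReport:
    """Compute the seven metrics from counts (+ predictions for ROC AUC)."""
    und: dict[str, str] = {}
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sp = _ratio(tn, tn + fp, "sp", und)
    sn = _ratio(tp, tp + fn, "sn", und)
    pre = _ratio(tp, tp + fp, "pre", und)
    acc = _ratio(tp + tn, counts.total, "acc", und)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        und["mcc"] = "a row or column of the confusion matrix is empty"
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    if math.isnan(pre) or math.isnan(sn) or (pre + sn) == 0:
        und["f1"] = "precision + sensitivity is zero or undefined"
        f1 = math.nan
    else:
        f1 = 2 * pre * sn / (pre + sn)
    roc = math.nan
    if predictions is None:
        und["roc_auc"] = "no per-record probabilities supplied"
    else:
        y = [1 if r.true_label == PROMOTER else 0 for r in predictions]
        if len(set(y)) < 2:
            und["roc_auc"] = "only one class present"
        else:
            roc = float(roc_auc_score(y, [r.probability for r in predictions]))
    return MetricReport(sp=sp, sn=sn, pre=pre, acc=acc, mcc=mcc, f1=f1,
                        roc_auc=roc, scope=scope, counts=counts, undefined=und)


def metrics_from_records(
    predictions: list[PredictionRecord], threshold: float = 0.5, scope: str = "global"
) -> MetricReport:
    return metrics(confusion(predictions, threshold), predictions, scope=scope)


def per_species_report(
    predictions: list[PredictionRecord], threshold: float = 0.5
) -> dict[str, MetricReport]:
    """Metrics within each species subset, in first-appearance order."""
    groups: dict[str, list[PredictionRecord]] = {}
    for rec in predictions:
        groups.setdefault(rec.species_id, []).append(rec)
    return {
        sp: metrics_from_records(recs, threshold, scope=sp)
        for sp, recs in groups.items()
    }


# ---------------------------------------------------------------------------
# GC diagnostics

def _tukey_quartiles(values: np.ndarray) -> tuple[float, float]:
    """Quartiles by the median-of-halves rule.

    The sorted data are split at the median; with an odd count the
    median itself belongs to neither half. Q1/Q3 are the medians of the
    lower/upper halves.
    """
    v = np.sort(values)
    n = v.size
    half = n // 2
    lower, upper = v[:half], v[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def gc_by_category(
    predictions: list[PredictionRecord],
    sequences: SequenceSet,
    threshold: float = 0.5,
    per_species: bool = False,
) -> pd.DataFrame:
    """GC summary statistics per confusion category (percentage points).

    Every prediction must join to a sequence by ``seq_id``. Returns one
    row per category (and per species when requested) with count, mean,
    median, Tukey quartiles and range; empty categories get count 0 and
    NaN statistics.
    """
    seq_map = {rec.seq_id: rec.sequence for rec in sequences.records}
    rows = []
    grouped: dict[tuple[str, str], list[float]] = {}
    for rec in predictions:
        if rec.seq_id not in seq_map:
            raise ValueError(f"prediction {rec.seq_id!r} has no matching sequence")
        gc = gc_content(seq_map[rec.seq_id]) * 100.0
        key_species = rec.species_id if per_species else "all"
        grouped.setdefault((key_species, categorize(rec, threshold)), []).append(gc)
    species_axis = sorted({k[0] for k in grouped}) or ["all"]
    for sp in species_axis:
        for cat in CATEGORIES:
            values = np.array(grouped.get((sp, cat), []))
            if values.size:
                q1, q3 = _tukey_quartiles(values)
                rows.append((sp, cat, values.size, values.mean(), float(np.median(values)),
                             q1, q3, values.min(), values.max()))
            else:
                rows.append((sp, cat, 0, *(math.nan,) * 6))
    return pd.DataFrame(
        rows,
        columns=["species_id", "category", "count", "mean_gc", "median_gc",
                 "q1_gc", "q3_gc", "min_gc", "max_gc"],
    )


def delta_gc(positives: SequenceSet, negatives: SequenceSet) -> pd.DataFrame:
    """Per-species and pooled mean-GC difference in percentage points.

    ``delta_gc`` is the absolute difference; ``signed_delta_gc`` keeps
    the direction (negative mean minus positive mean). A species present
    in only one set gets NaN deltas.
    """
    def means(ds: SequenceSet) -> dict[str, float]:
        groups: dict[str, list[float]] = {}
        for rec in ds.records:
            groups.setdefault(rec.species_id, []).append(gc_content(rec.sequence))
        return {sp: 100.0 * float(np.mean(v)) for sp, v in groups.items()}

    pos_means, neg_means = means(positives), means(negatives)
    rows = []
    for sp in sorted(set(pos_means) | set(neg_means)):
        p, n = pos_means.get(sp, math.nan), neg_means.get(sp, math.nan)
        signed = n - p
        rows.append((sp, p, n, abs(signed), signed))
    if positives.records and negatives.records:
        p = 100.0 * float(np.mean([gc_content(r.sequence) for r in positives.records]))
        n = 100.0 * float(np.mean([gc_content(r.sequence) for r in negatives.records]))
        rows.append(("pooled", p, n, abs(n - p), n - p))
    return pd.DataFrame(
        rows, columns=["species_id", "mean_gc_positives", "mean_gc_negatives",
                       "delta_gc", "signed_delta_gc"],
    )


def export_embeddings(
    sequences: SequenceSet,
    path,
    model=None,
    predictions: list[PredictionRecord] | None = None,
    vectors: np.ndarray | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Write per-sequence vectors + labels + GC for external projection.

    Vectors come from the model's penultimate layer (``model.embed``)
    or are passed through from an imported table; a model without a
    natural embedding (e.g. a random forest) raises with a hint to
    supply imported vectors. The TSV is ready for any projection tool
    (e.g. UMAP run elsewhere).
    """
    if vectors is None:
        if model is None or not hasattr(model, "embed"):
            raise ValueError(
                "this model exposes no embedding; pass precomputed `vectors` "
                "(e.g. exported from an external transformer model) instead"
            )
        vectors = np.asarray(model.embed(sequences.sequences()))
    else:
        vectors = np.asarray(vectors)
    if vectors.shape[0] != len(sequences):
        raise ValueError(
            f"{vectors.shape[0]} vectors for {len(sequences)} sequences"
        )
    cat_map = {}
    if predictions is not None:
        cat_map = {r.seq_id: categorize(r, threshold) for r in predictions}
    rows = []
    for rec, vec in zip(sequences.records, vectors):
        rows.append({
            "seq_id": rec.seq_id,
            "species_id": rec.species_id,
            "label": rec.label,
            "category": cat_map.get(rec.seq_id, ""),
            "gc_percent": 100.0 * gc_content(rec.sequence),
            **{f"v{i}": float(x) for i, x in enumerate(vec)},
        })
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
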