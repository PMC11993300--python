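"""Metric formulas, per-species reports and GC diagnostics vs oracles."""

import math

import numpy as np
import pytest

from negset.core import PredictionRecord
from negset.evaluation import (
    ConfusionCounts,
    confusion,
    delta_gc,
    export_embeddings,
    gc_by_category,
    metrics,
    metrics_from_records,
    per_species_report,
)
from .conftest import make_set, random_sequence


def pred(seq_id, label, prob, species="spA"):
    return PredictionRecord(seq_id, species, label, prob)


def brute_auc(records):
    pos = [r.probability for r in records if r.true_label == "promoter"]
    neg = [r.probability for r in records if r.true_label == "non-promoter"]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct(self):
        records = [pred(f"p{i}", "promoter", 0.9) for i in range(3)] + \
                  [pred(f"n{i}", "non-promoter", 0.1) for i in range(4)]
        assert confusion(records) == ConfusionCounts(tp=3, tn=4, fp=0, fn=0)

    def test_tie_at_threshold_counts_positive(self):
        assert confusion([pred("n", "non-promoter", 0.5)]).fp == 1
        assert confusion([pred("p", "promoter", 0.5)]).tp == 1

    def test_matches_manual_tally(self):
        rng = np.random.default_rng(0)
        records = [
            pred(f"r{i}", rng.choice(["promoter", "non-promoter"]), float(rng.random()))
            for i in range(10)
        ]
        counts = confusion(records)
        manual = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for r in records:
            key = ("t" if (r.probability >= 0.5) == (r.true_label == "promoter") else "f")
            key += "p" if r.probability >= 0.5 else "n"
            manual[key] += 1
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (
            manual["tp"], manual["tn"], manual["fp"], manual["fn"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([])


class TestMetrics:
    def test_worked_example(self):
        report = metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert report.sp == pytest.approx(0.8)
        assert report.sn == pytest.approx(0.6)
        assert report.pre == pytest.approx(0.75)
        assert report.acc == pytest.approx(0.7)
        assert report.mcc == pytest.approx(10 / math.sqrt(4 * 5 * 5 * 6))
        assert report.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_separation(self):
        records = [pred("p", "promoter", 0.9), pred("n", "non-promoter", 0.1)]
        report = metrics_from_records(records)
        for v in (report.sp, report.sn, report.pre, report.acc, report.mcc,
                  report.f1, report.roc_auc):
            assert v == 1.0

    def test_constant_probability_gives_auc_half(self):
        records = [pred("p", "promoter", 0.5), pred("n", "non-promoter", 0.5),
                   pred("p2", "promoter", 0.5)]
        assert metrics_from_records(records).roc_auc == pytest.approx(0.5)

    def test_undefined_ratios_reported_not_fabricated(self):
        report = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(report.pre) and "pre" in report.undefined
        assert math.isnan(report.sn) and "sn" in report.undefined
        assert math.isnan(report.mcc)

    def test_formulas_match_independent_evaluation_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            r = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            if tn + fp:
                assert r.sp == pytest.approx(tn / (tn + fp))
            if tp + fn:
                assert r.sn == pytest.approx(tp / (tp + fn))
            denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            if denom:
                assert r.mcc == pytest.approx((tp * tn - fp * fn) / denom)

    def test_auc_equals_pair_enumeration(self):
        rng = np.random.default_rng(2)
        records = [
            pred(f"r{i}", "promoter" if rng.random() < 0.5 else "non-promoter",
                 float(rng.choice([0.1, 0.3, 0.5, 0.7, 0.9])))
            for i in range(100)
        ]
        got = metrics_from_records(records).roc_auc
        assert got == pytest.approx(brute_auc(records))


class TestPerSpecies:
    def test_perfect_and_chance_species(self):
        rng = np.random.default_rng(3)
        good = [pred(f"g{i}", "promoter", 0.9, "good") for i in range(20)] + \
               [pred(f"gn{i}", "non-promoter", 0.1, "good") for i in range(20)]
        chance = [
            pred(f"c{i}", "promoter" if i % 2 else "non-promoter",
                 float(rng.random()), "chance")
            for i in range(200)
        ]
        reports = per_species_report(good + chance)
        assert reports["good"].acc == 1.0 and reports["good"].roc_auc == 1.0
        assert abs(reports["chance"].roc_auc - 0.5) < 0.15

    def test_single_species_matches_global(self):
        records = [pred("a", "promoter", 0.8), pred("b", "non-promoter", 0.3)]
        (only,) = per_species_report(records).values()
        assert only.acc == metrics_from_records(records).acc

    def test_counts_aggregate_to_pooled(self):
        rng = np.random.default_rng(4)
        records = [
            pred(f"r{i}", rng.choice(["promoter", "non-promoter"]),
                 float(rng.random()), rng.choice(["s1", "s2", "s3"]))
            for i in range(200)
        ]
        pooled = confusion(records)
        per = per_species_report(records)
        assert sum(m.counts.tp for m in per.values()) == pooled.tp
        assert sum(m.counts.total for m in per.values()) == pooled.total


class TestGcByCategory:
    def test_all_tp_with_half_gc(self):
        seqs = make_set(["ATGC" * 20 + "A"] * 4, label="promoter", origin="fixture")
        records = [pred(r.seq_id, "promoter", 0.9, "spX") for r in seqs]
        frame = gc_by_category(records, seqs)
        tp = frame[frame.category == "TP"].iloc[0]
        assert tp["count"] == 4
        assert tp.mean_gc == pytest.approx(100 * 40 / 81)
        assert (frame[frame.category != "TP"]["count"] == 0).all()

    def test_quartiles_match_median_of_halves_oracle(self):
        # 8 sequences with GC counts 0..7 out of 81
        seqs = make_set(["G" * k + "A" * (81 - k) for k in range(8)],
                        label="promoter", origin="fixture")
        records = [pred(r.seq_id, "promoter", 0.9, "spX") for r in seqs]
        frame = gc_by_category(records, seqs)
        tp = frame[frame.category == "TP"].iloc[0]
        gcs = sorted(100 * k / 81 for k in range(8))
        assert tp.q1_gc == pytest.approx(np.median(gcs[:4]))
        assert tp.q3_gc == pytest.approx(np.median(gcs[4:]))
        assert tp.median_gc == pytest.approx((gcs[3] + gcs[4]) / 2)

    def test_category_counts_partition_predictions(self):
        rng = np.random.default_rng(5)
        seqs = make_set([random_sequence(rng) for _ in range(30)],
                        label="promoter", origin="fixture")
        records = [
            pred(r.seq_id, rng.choice(["promoter", "non-promoter"]),
                 float(rng.random()), "spX")
            for r in seqs
        ]
        frame = gc_by_category(records, seqs)
        assert frame["count"].sum() == len(records)
        counts = confusion(records)
        by_cat = dict(zip(frame.category, frame["count"]))
        assert (by_cat["TP"], by_cat["TN"], by_cat["FP"], by_cat["FN"]) == (
            counts.tp, counts.tn, counts.fp, counts.fn)

    def test_unjoined_prediction_rejected(self):
        seqs = make_set(["A" * 81])
        with pytest.raises(ValueError, match="ghost"):
            gc_by_category([pred("ghost", "promoter", 0.9)], seqs)


class TestDeltaGc:
    def test_identical_sets_have_zero_delta(self):
        rng = np.random.default_rng(6)
        seqs = [random_sequence(rng) for _ in range(10)]
        pos = make_set(seqs, label="promoter", origin="fixture")
        neg = make_set(seqs)
        frame = delta_gc(pos, neg)
        assert (frame.delta_gc.abs() < 1e-12).all()

    def test_known_difference_in_percentage_points(self):
        # 32/81 vs 36/81 GC bases: difference ~4.94 points
        pos = make_set(["G" * 32 + "A" * 49] * 5, label="promoter", origin="fixture")
        neg = make_set(["G" * 36 + "A" * 45] * 5)
        row = delta_gc(pos, neg).iloc[0]
        assert row.delta_gc == pytest.approx(100 * 4 / 81)
        assert row.signed_delta_gc == pytest.approx(100 * 4 / 81)

    def test_species_missing_from_one_side_gets_nan(self):
        rng = np.random.default_rng(7)
        pos = make_set([random_sequence(rng)], label="promoter",
                       origin="fixture", species="only_pos")
        neg = make_set([random_sequence(rng)], species="only_neg")
        frame = delta_gc(pos, neg).set_index("species_id")
        assert math.isnan(frame.loc["only_pos"].delta_gc)
        assert math.isnan(frame.loc["only_neg"].delta_gc)


class TestExportEmbeddings:
    def test_vector_pass_through(self, tmp_path):
        rng = np.random.default_rng(8)
        seqs = make_set([random_sequence(rng) for _ in range(6)],
                        label="promoter", origin="fixture")
        vectors = rng.random((6, 2))
        frame = export_embeddings(seqs, tmp_path / "emb.tsv", vectors=vectors)
        assert len(frame) == 6
        assert frame[["v0", "v1"]].to_numpy() == pytest.approx(vectors)

    def test_model_without_embedding_rejected_with_hint(self):
        rng = np.random.default_rng(9)
        seqs = make_set([random_sequence(rng)])

        class NoEmbed:
            pass

        with pytest.raises(ValueError, match="vectors"):
            export_embeddings(seqs, None, model=NoEmbed())

    def test_row_count_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        seqs = make_set([random_sequence(rng) for _ in range(3)])
        with pytest.raises(ValueError, match="3 sequences"):
            export_embeddings(seqs, None, vectors=np.zeros((2, 4)))
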