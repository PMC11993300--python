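"""Sliding-window scan: averaging, tracks, TSS-local deviations."""

import numpy as np
import pytest

from negset.core import Genome, TssRecord
from negset.genome_scan import ScanProfile, scan, signal_at_tss, write_track
from .conftest import random_sequence


class ConstantPredictor:
    def __init__(self, p):
        self.p = p

    def promoter_proba(self, windows):
        return np.full(len(windows), self.p)


class MotifIndicator:
    """1.0 for windows containing TATAAT, else 0.0."""

    def promoter_proba(self, windows):
        return np.array([1.0 if "TATAAT" in w else 0.0 for w in windows])


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(0)
    return Genome("g", "sp", random_sequence(rng, 2000, gc=1.0))  # G/C only: no TATAAT


class TestScan:
    def test_constant_predictor_gives_constant_track(self, genome):
        profile = scan(ConstantPredictor(0.7), genome, (100, 500))
        assert np.allclose(profile.values, 0.7)
        assert profile.coverage[0] == 1  # edge position covered by one window
        assert profile.coverage[200] == 81

    def test_single_window_interval(self, genome):
        profile = scan(ConstantPredictor(0.3), genome, (0, 81))
        assert profile.values.shape == (81,)
        assert np.allclose(profile.values, 0.3)
        assert (profile.coverage == 1).all()

    def test_indicator_predictor_localizes_planted_site(self, genome):
        seq = list(genome.sequence)
        seq[1000:1006] = "TATAAT"
        g = Genome("g", "sp", "".join(seq))
        profile = scan(MotifIndicator(), g, (500, 1500))
        values = profile.values
        idx = profile.position_index()
        hot = idx[values > 0]
        assert hot.size > 0
        assert hot.min() >= 1006 - 81 and hot.max() <= 1000 + 81
        assert np.allclose(values[(idx < 1006 - 81) | (idx > 1000 + 80)], 0.0)

    def test_averaging_conservation_identity(self, genome):
        rng = np.random.default_rng(1)

        class RandomButFixed:
            def promoter_proba(self, windows):
                return np.array([
                    (hash(w) % 1000) / 1000.0 for w in windows
                ])

        predictor = RandomButFixed()
        profile = scan(predictor, genome, (200, 600))
        starts = range(200, 600 - 81 + 1)
        window_probs = predictor.promoter_proba(
            [genome.sequence[s:s + 81] for s in starts])
        lhs = np.nansum(profile.values * profile.coverage)
        assert lhs == pytest.approx(81 * window_probs.sum())

    def test_batch_size_invariance(self, genome):
        a = scan(MotifIndicator(), genome, (0, 400), batch_size=7)
        b = scan(MotifIndicator(), genome, (0, 400), batch_size=512)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.coverage, b.coverage)

    def test_n_windows_skipped(self):
        rng = np.random.default_rng(2)
        seq = random_sequence(rng, 300)
        seq = seq[:150] + "N" + seq[151:]
        g = Genome("g", "sp", seq)
        profile = scan(ConstantPredictor(1.0), g, (0, 300))
        assert profile.coverage[150] == 0 and np.isnan(profile.values[150])
        far = profile.coverage[20]
        assert far > 0

    def test_stride_and_tss_attribution(self, genome):
        profile = scan(ConstantPredictor(0.4), genome, (0, 300), stride=10,
                       attribute="tss-offset")
        covered = profile.coverage > 0
        assert covered.sum() == len(range(0, 300 - 81 + 1, 10))
        assert np.allclose(profile.values[covered], 0.4)

    def test_bad_intervals(self, genome):
        with pytest.raises(ValueError, match="shorter"):
            scan(ConstantPredictor(0.5), genome, (0, 50))
        with pytest.raises(ValueError, match="outside"):
            scan(ConstantPredictor(0.5), genome, (0, 99999))


class TestWriteTrack:
    def test_constant_profile_single_line(self, tmp_path):
        profile = ScanProfile("g", 0, 100, np.full(100, 0.25), np.ones(100, int), 81, 1)
        path = tmp_path / "t.bedGraph"
        write_track(profile, path)
        lines = path.read_text().splitlines()
        assert lines == ["g\t0\t100\t0.250000"]

    def test_round_trip_values(self, tmp_path, genome):
        profile = scan(MotifIndicator(), genome, (0, 300))
        path = tmp_path / "t.bedGraph"
        write_track(profile, path)
        rebuilt = np.full(300, np.nan)
        for line in path.read_text().splitlines():
            _, start, end, value = line.split("\t")
            rebuilt[int(start):int(end)] = float(value)
        mask = ~np.isnan(profile.values)
        assert np.allclose(rebuilt[mask], np.round(profile.values[mask], 6))

    def test_runs_are_contiguous_and_non_overlapping(self, tmp_path):
        values = np.array([0.1] * 10 + [0.2] * 5 + [0.1] * 3)
        profile = ScanProfile("g", 50, 68, values, np.ones(18, int), 81, 1)
        path = tmp_path / "t.bedGraph"
        write_track(profile, path)
        spans = [tuple(map(int, l.split("\t")[1:3]))
                 for l in path.read_text().splitlines()]
        assert spans == [(50, 60), (60, 65), (65, 68)]


class TestSignalAtTss:
    def test_flat_profile_zero_deviation(self):
        profile = ScanProfile("g", 0, 500, np.full(500, 0.6), np.ones(500, int), 81, 1)
        out = signal_at_tss(profile, [TssRecord("g", 250, "+")], flank=50)
        assert out[0]["deviation"] == pytest.approx(0.0)

    def test_constructed_dip_arithmetic(self):
        values = np.full(1000, 0.8)
        values[490:511] = 0.4  # dip of -0.4 over 21 positions
        profile = ScanProfile("g", 0, 1000, values, np.ones(1000, int), 81, 1)
        (out,) = signal_at_tss(profile, [TssRecord("g", 500, "+")], flank=100)
        inside = values[400:601].mean()
        outside = np.concatenate([values[:400], values[601:]]).mean()
        assert out["deviation"] == pytest.approx(inside - outside)
        assert out["deviation"] < 0

    def test_tss_outside_interval_skipped(self):
        profile = ScanProfile("g", 100, 300, np.full(200, 0.5), np.ones(200, int), 81, 1)
        assert signal_at_tss(profile, [TssRecord("g", 50, "+")]) == []

    def test_planted_tss_stand_out_against_random_positions(self):
        """Trained model signal at real TSS beats a permutation baseline."""
        from negset.fixtures import SpeciesSpec, make_species_panel
        from negset.windows import extract_all
        from negset.srs import generate_srs
        from negset.assembly import balance_and_merge, split_dataset
        from negset.models import train

        spec = SpeciesSpec(species_id="sp", genome_length=120_000,
                           background_gc=0.52, promoter_gc=0.50,
                           n_promoters=150, motif_mutation_rate=0.05)
        panel = make_species_panel([spec], seed=54)
        P0, _ = extract_all(panel.genomes, panel.tss_records,
                            panel.cds_records, seed=55)
        R0, _ = generate_srs(P0, ratio=1, seed=56)
        D = balance_and_merge(P0, R0, seed=57)
        split = split_dataset(D, seed=58)
        model = train("CNN", {"epochs": 8}, split.train, seed=59)

        genome = panel.genomes[0]
        # forward-strand loci only: the scan reads the forward strand
        tss = [t for t in panel.tss_records if t.strand == "+"][:10]
        lo = max(0, min(t.position for t in tss) - 500)
        hi = min(len(genome), max(t.position for t in tss) + 500)
        profile = scan(model, genome, (lo, hi), stride=1, attribute="tss-offset")
        planted = [abs(r["deviation"]) for r in signal_at_tss(profile, tss, flank=10)]
        rng = np.random.default_rng(60)
        occupied = {t.position for t in panel.tss_records}
        random_pos = []
        while len(random_pos) < 50:
            p = int(rng.integers(lo + 100, hi - 100))
            if all(abs(p - q) > 150 for q in occupied):
                random_pos.append(p)
        baseline = [
            abs(r["deviation"])
            for r in signal_at_tss(profile, [TssRecord(genome.genome_id, p, "+")
                                             for p in random_pos], flank=10)
        ]
        assert np.median(planted) > np.percentile(baseline, 95)
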