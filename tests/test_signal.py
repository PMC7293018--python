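"""Signal matrices, density profiles, K-means clustering, width stats,
and track correlation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tssbind.core import GenomicInterval, PeakCall
from tssbind.signal import (
    BinnedTrack,
    SignalMatrix,
    build_signal_matrix,
    compare_group_signal,
    kmeans_positional,
    peak_width_stats,
    sample_correlation,
    subcluster,
    summit_histogram,
    tag_density_profile,
    track_from_bedgraph,
)
from tssbind.simulate import GenomeConfig, PeakMixtureConfig, generate_genome, generate_peaks

from conftest import make_transcript


def constant_track(value=1.0, length=100_000, binsize=20):
    t = BinnedTrack({"chr1": length}, binsize)
    t.values["chr1"][:] = value
    return t


def impulse_track(pos, length=100_000, binsize=20, value=1.0):
    t = BinnedTrack({"chr1": length}, binsize)
    t.values["chr1"][pos // binsize] = value
    return t


class TestSignalMatrix:
    def test_constant_coverage_all_ones(self):
        anchors = [make_transcript(start=10_000), make_transcript(start=50_000)]
        m = build_signal_matrix(constant_track(), anchors, 3000, 20)
        assert m.values.shape == (2, 300)
        assert np.allclose(m.values, 1.0)

    def test_impulse_lands_at_offset(self):
        t = make_transcript(start=10_000, strand="+")
        track = impulse_track(10_000 + 240)
        m = build_signal_matrix(track, [t], 3000, 20)
        nz = np.flatnonzero(m.values[0])
        assert len(nz) == 1
        assert m.bin_centers[nz[0]] == 250  # bin [240, 260)

    def test_minus_strand_orientation_matches_plus(self):
        """An impulse 240 bp downstream in transcription direction falls in
        the same matrix bin regardless of strand."""
        plus = make_transcript(start=10_000, strand="+")
        minus = make_transcript(start=50_000 - 1699, strand="-")
        track = impulse_track(plus.tss + 240)
        track.values["chr1"][(minus.tss - 240) // 20] = 1.0
        m = build_signal_matrix(track, [plus, minus], 3000, 20)
        assert np.flatnonzero(m.values[0]).tolist() == \
            np.flatnonzero(m.values[1]).tolist()

    def test_missing_chromosome_dropped(self):
        anchors = [make_transcript(chrom="chr9", start=10_000)]
        m = build_signal_matrix(constant_track(), anchors, 3000, 20)
        assert m.dropped == 1 and m.values.shape[0] == 0

    def test_orientation_invariance_under_coordinate_reversal(self):
        """Reversing the genome's coordinate system (and flipping strands)
        leaves TSS-relative rows unchanged."""
        L = 100_000
        plus = make_transcript(start=10_000, strand="+")
        track = BinnedTrack({"chr1": L}, 20)
        rng = np.random.default_rng(0)
        track.values["chr1"][:] = rng.random(len(track.values["chr1"]))
        row_fwd = build_signal_matrix(track, [plus], 3000, 20).values[0]
        # mirrored genome: position x -> L-1-x, gene becomes minus-strand
        mirrored = BinnedTrack({"chr1": L}, 20)
        mirrored.values["chr1"][:] = track.values["chr1"][::-1]
        minus = make_transcript(start=L - 10_000 - 1700, strand="-")
        assert minus.tss == L - 1 - plus.tss
        row_rev = build_signal_matrix(mirrored, [minus], 3000, 20).values[0]
        assert np.allclose(row_fwd, row_rev)


class TestDensityProfile:
    def test_planted_single_offset_mode(self):
        prof = summit_histogram([240] * 500, window=3000, binsize=20)
        assert prof.primary_mode == 250  # center of bin [240, 260)
        assert abs(prof.primary_mode_refined - 240) <= 20

    def test_symmetric_tie_breaks_positive(self):
        prof = summit_histogram([-245] * 100 + [235] * 100, 3000, 20)
        assert prof.primary_mode > 0

    def test_mixture_mode_and_shoulder(self):
        """70/30 mix of N(+240,120) and N(-240,120) at n=20k: mode within
        one bin of +240, shoulder within two bins of -240."""
        rng = np.random.default_rng(123)
        d = np.concatenate([rng.normal(240, 120, 14_000),
                            rng.normal(-240, 120, 6_000)])
        prof = summit_histogram(d, 3000, 20)
        assert abs(prof.primary_mode_refined - 240) <= 20
        assert abs(prof.shoulder - (-240)) <= 40

    def test_mode_recovery_over_20_seeds(self):
        """Default five-component mixture: +240 mode recovered within one
        bin for each of 20 generator seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 10_000
            lab = rng.choice(5, n, p=[0.25, 0.15, 0.10, 0.10, 0.40])
            d = np.empty(n)
            d[lab == 0] = rng.normal(240, 120, (lab == 0).sum())
            d[lab == 1] = rng.normal(-240, 120, (lab == 1).sum())
            d[lab == 2] = rng.normal(2000, 300, (lab == 2).sum())
            d[lab == 3] = rng.normal(-2000, 300, (lab == 3).sum())
            d[lab == 4] = rng.uniform(-3000, 3000, (lab == 4).sum())
            prof = summit_histogram(d, 3000, 20)
            assert abs(prof.primary_mode_refined - 240) <= 20, f"seed {seed}"

    def test_all_zero_flagged(self):
        m = SignalMatrix(["r"], 3000, 20, np.zeros((1, 300)))
        prof = tag_density_profile(m)
        assert prof.primary_mode is None and prof.flagged


def two_group_matrix(n_per=50, offs=(240, -240), seed=0):
    rng = np.random.default_rng(seed)
    centers = np.arange(-3000 + 10, 3000, 20)
    rows, truth = [], []
    for gi, off in enumerate(offs):
        for _ in range(n_per):
            o = off + rng.normal(0, 60)
            rows.append(np.maximum(0, 1 - np.abs(centers - o) / 500))
            truth.append(gi)
    ids = [f"r{i}" for i in range(len(rows))]
    return SignalMatrix(ids, 3000, 20, np.array(rows)), np.array(truth)


class TestKmeans:
    def test_separable_two_groups_perfect_ari(self):
        m, truth = two_group_matrix()
        a = kmeans_positional(m, 2, seed=1)
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_k_equals_rows_zero_inertia(self):
        m, _ = two_group_matrix(n_per=3, offs=(240, -240, 2000), seed=2)
        a = kmeans_positional(m, 9, seed=0)
        assert a.inertia == pytest.approx(0.0, abs=1e-9)
        assert len(set(a.labels)) == 9

    def test_seeded_determinism(self):
        m, _ = two_group_matrix()
        a = kmeans_positional(m, 2, seed=5)
        b = kmeans_positional(m, 2, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_cluster_one_is_strongest(self):
        m, truth = two_group_matrix()
        m.values[truth == 1] *= 10  # group at -240 is much stronger
        a = kmeans_positional(m, 2, seed=0)
        strong_rows = np.array(a.labels)[truth == 1]
        assert (strong_rows == 1).all()

    def test_default_mixture_ari(self, small_genome):
        """k=4 on the default mixture recovers the localized components
        (near/far on either side) with ARI >= 0.8."""
        _, transcripts, _, truth = small_genome
        cfg = GenomeConfig(n_chroms=2, chrom_length=4_000_000, n_genes=500,
                           seed=21)
        # larger, sparser layout so per-promoter rows do not overlap
        _, transcripts, _, truth = generate_genome(cfg)
        mix = PeakMixtureConfig(seed=22)
        peaks, track, ptruth = generate_peaks(transcripts, mix, 500,
                                              truth["chrom_sizes"])
        from tssbind.core import TssIndex, assign_nearest_tss
        index = TssIndex(transcripts)
        anns = [assign_nearest_tss(p, index) for p in peaks]
        m = build_signal_matrix(track, anns, 3000, 20)
        a = kmeans_positional(m, 4, seed=23)
        comp = dict(zip(ptruth["peak_id"], ptruth["component"]))
        pairs = [(comp[r], l) for r, l in zip(a.row_ids, a.labels)
                 if comp[r] != "diffuse"]
        t, l = zip(*pairs)
        assert adjusted_rand_score(t, l) >= 0.8


class TestSubcluster:
    def test_far_components_separated(self):
        """A combination-like mixture (far +/-2 kb, over-TSS, flat) yields
        sub-centroids whose modes match the planted components."""
        rng = np.random.default_rng(3)
        centers = np.arange(-3000 + 10, 3000, 20)
        rows, truth = [], []
        for gi, off in enumerate((2000, -2000, 0)):
            for _ in range(40):
                o = off + rng.normal(0, 100)
                rows.append(np.maximum(0, 1 - np.abs(centers - o) / 500))
                truth.append(gi)
        for _ in range(40):  # weak/no-pattern rows
            rows.append(rng.random(len(centers)) * 0.05)
            truth.append(3)
        ids = [f"r{i}" for i in range(len(rows))]
        m = SignalMatrix(ids, 3000, 20, np.array(rows))
        outer = kmeans_positional(m, 1, seed=0)  # everything in one cluster
        sub = subcluster(m, outer, 1, k=4, seed=4)
        modes = [centers[int(np.argmax(c))] for c in sub.centroids]
        assert any(mo > 1500 for mo in modes)
        assert any(mo < -1500 for mo in modes)
        assert "upstream_far" in sub.notes and "downstream_far" in sub.notes

    def test_identical_rows_degenerate_flagged(self):
        rows = np.tile(np.linspace(0, 1, 300), (10, 1))
        m = SignalMatrix([f"r{i}" for i in range(10)], 3000, 20, rows)
        outer = kmeans_positional(m, 1, seed=0)
        sub = subcluster(m, outer, 1, k=4, seed=0)
        assert "degenerate" in sub.notes or len(set(sub.labels)) < 4

    def test_subset_smaller_than_k_errors(self):
        m, _ = two_group_matrix(n_per=2)
        outer = kmeans_positional(m, 2, seed=0)
        small_label = min(outer.sizes, key=outer.sizes.get)
        with pytest.raises(ValueError):
            subcluster(m, outer, small_label, k=4)


class TestWidths:
    def test_simple_stats(self):
        peaks = [PeakCall(GenomicInterval("c", 0, 100), 50),
                 PeakCall(GenomicInterval("c", 200, 500), 300)]
        mean, median, n = peak_width_stats(peaks)
        assert (mean, median, n) == (200, 200, 2)

    def test_single_peak(self):
        p = PeakCall(GenomicInterval("c", 0, 1816), 900)
        assert peak_width_stats([p])[0] == 1816

    def test_lognormal_median_within_2pct(self):
        rng = np.random.default_rng(11)
        widths = rng.lognormal(np.log(1800), 0.25, 10_000)
        peaks = [PeakCall(GenomicInterval("c", 0, int(w)), 0)
                 for w in np.maximum(widths, 2)]
        _, median, _ = peak_width_stats(peaks)
        assert abs(median - 1800) / 1800 < 0.02

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            peak_width_stats([])


class TestCorrelation:
    def test_self_correlation_unity(self):
        t = constant_track()
        rng = np.random.default_rng(1)
        t.values["chr1"][:] = rng.random(len(t.values["chr1"]))
        t2 = constant_track()
        t2.values["chr1"][:] = t.values["chr1"]
        _, corr = sample_correlation({"a": t, "b": t2}, bin=10_000)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        tracks = {}
        for name in ("a", "b"):
            t = BinnedTrack({"chr1": 2_000_000}, 200)
            t.values["chr1"][:] = rng.exponential(1, len(t.values["chr1"]))
            tracks[name] = t
        _, corr = sample_correlation(tracks, bin=200)
        assert abs(corr[0, 1]) < 0.05

    def test_zero_variance_flagged_nan(self):
        flat = constant_track(value=2.0)
        noisy = constant_track()
        noisy.values["chr1"][:] = np.random.default_rng(0).random(
            len(noisy.values["chr1"])
        )
        _, corr = sample_correlation({"flat": flat, "noisy": noisy})
        assert np.isnan(corr[0, 1])


class TestGroupSignal:
    def make_matrix(self):
        rows = np.ones((6, 10))
        rows[:3] *= 3.0
        return SignalMatrix([f"r{i}" for i in range(6)], 100, 20, rows)

    def test_identical_groups_ratio_one(self):
        rows = np.ones((4, 10))
        m = SignalMatrix(["a", "b", "c", "d"], 100, 20, rows)
        out = compare_group_signal(m, ["a", "b"], ["c", "d"])
        assert out["ratio"] == pytest.approx(1.0)

    def test_planted_threefold(self):
        m = self.make_matrix()
        out = compare_group_signal(m, ["r0", "r1", "r2"], ["r3", "r4", "r5"])
        assert out["ratio"] == pytest.approx(3.0)

    def test_zero_group_flagged_infinite(self):
        m = self.make_matrix()
        m.values[3:] = 0
        out = compare_group_signal(m, ["r0", "r1"], ["r3", "r4"])
        assert np.isinf(out["ratio"]) and out["flagged"]

    def test_empty_group_errors(self):
        m = self.make_matrix()
        with pytest.raises(ValueError):
            compare_group_signal(m, [], ["r0"])


class TestTrackFromBedgraph:
    def test_rebinning_weighted_mean(self):
        records = [("chr1", 0, 10, 2.0), ("chr1", 10, 20, 4.0)]
        t = track_from_bedgraph(records, binsize=20)
        assert t.values["chr1"][0] == pytest.approx(3.0)
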