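import numpy as np
import pandas as pd
import pytest

from meiocross import coverage_profiles as cp


def rec(mapq, xs=False, xm=0, read_id="r1", mate=1, chrom="c", pos=100):
    return cp.AlignmentRecord(read_id, mate, chrom, pos, mapq, xs, xm)


class TestFilterAlignments:
    def test_unique_high_mapq_kept(self):
        rng = np.random.default_rng(0)
        assert cp.filter_alignments([rec(42)], rng) is rec(42).__class__(
            "r1", 1, "c", 100, 42, False, 0
        ) or cp.filter_alignments([rec(42)], rng).mapq == 42

    def test_excess_mismatches_discarded(self):
        rng = np.random.default_rng(0)
        assert cp.filter_alignments([rec(42, xm=3)], rng) is None

    def test_low_mapq_multi_all_discarded(self):
        rng = np.random.default_rng(0)
        assert cp.filter_alignments([rec(9), rec(8)], rng) is None

    def test_secondary_score_demotes_to_multi_rule(self):
        rng = np.random.default_rng(0)
        kept = cp.filter_alignments([rec(44, xs=True, pos=1), rec(30, xs=True, pos=2)], rng)
        assert kept is not None and kept.mapq == 44

    def test_tie_break_deterministic_given_seed(self):
        cands = [rec(30, xs=True, pos=1), rec(30, xs=True, pos=2), rec(30, xs=True, pos=3)]
        picks_a = [cp.filter_alignments(cands, np.random.default_rng(7)) for _ in range(5)]
        picks_b = [cp.filter_alignments(cands, np.random.default_rng(7)) for _ in range(5)]
        assert all(p.position == picks_a[0].position for p in picks_a)
        assert picks_a[0].position == picks_b[0].position

    def test_never_more_than_one_kept(self):
        rng = np.random.default_rng(1)
        cands = [rec(42), rec(50, pos=500)]
        kept = cp.filter_alignments(cands, rng)
        assert isinstance(kept, cp.AlignmentRecord)

    def test_sam_stream_pair_rule(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:c\tLN:100000\n"
            # proper pair, both unique
            "p1\t99\tc\t100\t42\t50M\t=\t300\t250\t" + "A" * 50 + "\t" + "I" * 50 + "\tXM:i:0\n"
            "p1\t147\tc\t300\t42\t50M\t=\t100\t-250\t" + "A" * 50 + "\t" + "I" * 50 + "\tXM:i:1\n"
            # pair with one failing mate (too many mismatches): both dropped
            "p2\t99\tc\t500\t42\t50M\t=\t700\t250\t" + "A" * 50 + "\t" + "I" * 50 + "\tXM:i:0\n"
            "p2\t147\tc\t700\t42\t50M\t=\t500\t-250\t" + "A" * 50 + "\t" + "I" * 50 + "\tXM:i:5\n"
        )
        kept = cp.filter_sam(sam, seed=0)
        assert sorted((k.read_id, k.mate) for k in kept) == [("p1", 1), ("p1", 2)]


class TestWindowedCoverage:
    def test_constant_signal(self):
        t = cp.windowed_coverage({"c": np.full(35, 5.0)}, 10)
        assert np.allclose(t.values["c"], 5.0)

    def test_partial_terminal_window_uses_actual_width(self):
        x = np.concatenate([np.ones(25), np.zeros(5)])
        t = cp.windowed_coverage({"c": x}, 10)
        assert np.allclose(t.values["c"], [1.0, 1.0, 0.5])

    def test_window_spanning_chromosome_is_global_mean(self):
        x = np.arange(10.0)
        t = cp.windowed_coverage({"c": x}, 100)
        assert t.values["c"][0] == pytest.approx(x.mean())


class TestNormalization:
    def test_library_sum_invariant(self):
        a = cp.windowed_coverage({"c": np.random.default_rng(0).poisson(5, 1000).astype(float)}, 10)
        b = cp.windowed_coverage({"c": np.random.default_rng(1).poisson(50, 1000).astype(float)}, 10)
        na, nb = cp.normalize_library_sum(a), cp.normalize_library_sum(b)
        sum_a = sum((v * 10).sum() for v in na.values.values())
        sum_b = sum((v * 10).sum() for v in nb.values.values())
        assert sum_a == pytest.approx(sum_b)

    def test_equal_tracks_give_zero_log_ratio(self):
        t = cp.windowed_coverage({"c": np.arange(100.0)}, 10)
        out = cp.normalize_log2_ratio(t, t)
        assert np.allclose(out.values["c"], 0.0)

    def test_local_doubling_gives_log2_one(self):
        # two windows; same library sums, chip doubles the first window
        chip = cp.CoverageTrack(10, {"c": np.array([2.0, 1.0])})
        inp = cp.CoverageTrack(10, {"c": np.array([1.0, 2.0])})
        out = cp.normalize_log2_ratio(chip, inp, pseudocount=1e-9)
        assert out.values["c"][0] == pytest.approx(1.0, abs=1e-6)

    def test_zero_input_window_stays_finite(self):
        chip = cp.CoverageTrack(10, {"c": np.array([3.0, 0.0])})
        inp = cp.CoverageTrack(10, {"c": np.array([0.0, 3.0])})
        out = cp.normalize_log2_ratio(chip, inp, pseudocount=1.0)
        assert np.isfinite(out.values["c"]).all()

    def test_windowing_mismatch_rejected(self):
        a = cp.CoverageTrack(10, {"c": np.zeros(5)})
        b = cp.CoverageTrack(20, {"c": np.zeros(5)})
        with pytest.raises(ValueError):
            cp.normalize_log2_ratio(a, b)


def features(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


class TestGeneMetaprofile:
    def test_constant_track_gives_flat_profile(self):
        track = cp.CoverageTrack(1, {"c": np.full(10_000, 4.0)})
        feats = features([("c", 4001, 5000, "+"), ("c", 6001, 7000, "-")])
        mp = cp.gene_metaprofile(track, feats, body_bins=10, flank_bp=2000, flank_window_bp=20)
        assert mp.matrix.shape == (2, 100 + 10 + 100)
        assert np.allclose(mp.mean_profile, 4.0)

    def test_flanks_zero_when_signal_only_in_body(self):
        vals = np.zeros(10_000)
        vals[4000:5000] = 2.0
        track = cp.CoverageTrack(1, {"c": vals})
        mp = cp.gene_metaprofile(track, features([("c", 4001, 5000, "+")]), body_bins=5)
        n_fl = mp.n_flank_windows
        assert np.allclose(mp.matrix[0, :n_fl], 0.0)
        assert np.allclose(mp.matrix[0, -n_fl:], 0.0)
        assert np.allclose(mp.matrix[0, n_fl:-n_fl], 2.0)

    def test_linear_signal_bin_means_match_overlap_arithmetic(self):
        vals = np.zeros(5000, dtype=float)
        vals[999:1099] = np.arange(100, dtype=float)  # feature 1000..1099, signal 0..99
        track = cp.CoverageTrack(1, {"c": vals})
        mp = cp.gene_metaprofile(
            track, features([("c", 1000, 1099, "+")]), body_bins=4, flank_bp=100,
            flank_window_bp=20,
        )
        body = mp.matrix[0, mp.n_flank_windows: mp.n_flank_windows + 4]
        assert np.allclose(body, [12.0, 37.0, 62.0, 87.0])

    def test_minus_strand_rows_are_reversed(self):
        vals = np.zeros(5000)
        vals[999:1099] = np.arange(100)
        track = cp.CoverageTrack(1, {"c": vals})
        plus = cp.gene_metaprofile(track, features([("c", 1000, 1099, "+")]), body_bins=4,
                                   flank_bp=100, flank_window_bp=20)
        minus = cp.gene_metaprofile(track, features([("c", 1000, 1099, "-")]), body_bins=4,
                                    flank_bp=100, flank_window_bp=20)
        assert np.allclose(minus.matrix[0], plus.matrix[0][::-1])

    def test_feature_outside_track_rejected(self):
        track = cp.CoverageTrack(1, {"c": np.zeros(100)})
        with pytest.raises(ValueError, match="outside"):
            cp.gene_metaprofile(track, features([("c", 50, 500, "+")]))


class TestTrackCorrelation:
    def test_region_restriction(self, toy_layout):
        rng = np.random.default_rng(0)
        n = 10  # 10-kb windows over the 100-kb toy chromosome
        arm_sig = rng.normal(size=n)
        a = cp.CoverageTrack(10_000, {"chr": arm_sig})
        # b equals a on the arms but is sign-flipped inside the pericentromere
        mask = cp._region_mask(a, toy_layout, "pericentromeres", "chr")
        b_vals = np.where(mask, -arm_sig, arm_sig)
        b = cp.CoverageTrack(10_000, {"chr": b_vals})
        assert cp.track_correlation(a, b, toy_layout, "arms") == pytest.approx(1.0)
        assert cp.track_correlation(a, b, toy_layout, "pericentromeres") == pytest.approx(-1.0)

    def test_monotone_transform_preserves_rs(self, toy_layout):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        a = cp.CoverageTrack(10_000, {"chr": x})
        b = cp.CoverageTrack(10_000, {"chr": np.exp(x)})
        assert cp.track_correlation(a, b, toy_layout, "all") == pytest.approx(1.0)

    def test_too_few_windows_rejected(self, toy_layout):
        a = cp.CoverageTrack(50_000, {"chr": np.array([1.0, 2.0])})
        with pytest.raises(ValueError):
            cp.track_correlation(a, a, toy_layout, "all")


class TestBedgraphIO:
    def test_roundtrip(self, tmp_path):
        t = cp.CoverageTrack(10, {"c": np.array([1.5, 0.0, 2.25])})
        path = tmp_path / "t.bedgraph"
        cp.write_bedgraph(t, path)
        back = cp.read_bedgraph(path, 10)
        assert np.allclose(back.values["c"], t.values["c"])
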