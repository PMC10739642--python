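"""Peak-caller contracts: deduplication, the Poisson tail and BH q-values
against independent oracles, local-background arithmetic, and end-to-end
calling behaviour on simulated libraries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meriptools as mt
from meriptools.fragments import AlignedFragmentSet, Fragment
from meriptools.peaks import _sliding_mean


def poisson_tail_oracle(k: int, lam: float) -> float:
    """Direct series: P(X >= k) = 1 - sum_{i<k} e^-lam lam^i / i!"""
    acc = 0.0
    term = math.exp(-lam)
    for i in range(k):
        acc += term
        term *= lam / (i + 1)
    return 1.0 - acc


def bh_oracle(p):
    """Naive BH: q_i = min_{j: p_j >= p_i} min(1, p_j * m / rank_j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = min(prev, 1.0)
    return q


class TestDeduplicate:
    def test_identical_fragments_collapse_to_one(self):
        f = Fragment.contiguous("chr1", 10, 160)
        s = AlignedFragmentSet("s", "IP", fragments=[f, f, f])
        assert len(mt.deduplicate(s)) == 1

    def test_distinct_fragments_unchanged_and_sorted(self):
        frags = [
            Fragment.contiguous("chr1", 50, 200),
            Fragment.contiguous("chr1", 10, 160),
        ]
        out = mt.deduplicate(AlignedFragmentSet("s", "IP", fragments=frags))
        assert len(out) == 2
        assert out.fragments == sorted(frags)

    def test_strand_is_part_of_the_duplicate_key(self):
        a = Fragment.contiguous("chr1", 10, 160, "+")
        b = Fragment.contiguous("chr1", 10, 160, "-")
        out = mt.deduplicate(AlignedFragmentSet("s", "IP", fragments=[a, b]))
        assert len(out) == 2

    def test_order_independent_result(self):
        frags = [Fragment.contiguous("chr1", i * 7, i * 7 + 150) for i in range(20)]
        fwd = mt.deduplicate(AlignedFragmentSet("s", "IP", fragments=frags))
        rev = mt.deduplicate(AlignedFragmentSet("s", "IP", fragments=frags[::-1]))
        assert fwd.fragments == rev.fragments


class TestPoissonTail:
    def test_k_zero_is_one(self):
        assert mt.poisson_upper_tail(0, 3.7) == 1.0

    def test_hand_values(self):
        assert mt.poisson_upper_tail(5, 1.0) == pytest.approx(0.003659847, abs=1e-9)
        assert mt.poisson_upper_tail(1, 1.0) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_matches_series_oracle_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(0, 51))
            lam = float(rng.uniform(0.01, 20.0))
            assert abs(mt.poisson_upper_tail(k, lam) - poisson_tail_oracle(k, lam)) < 1e-9

    def test_stable_at_large_lambda(self):
        p = mt.poisson_upper_tail(11_000, 1e4)
        assert 0.0 < p < 1.0

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            mt.poisson_upper_tail(3, 0.0)


class TestBhQvalues:
    def test_single_p_unchanged(self):
        assert mt.bh_qvalues([0.03]).tolist() == [0.03]

    def test_hand_examples(self):
        assert np.allclose(mt.bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(mt.bh_qvalues([0.001, 0.5, 0.9]), [0.003, 0.75, 0.9])

    def test_matches_naive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
            assert np.allclose(mt.bh_qvalues(p), bh_oracle(list(p)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_dominates_p_and_stays_in_unit_interval(self, p):
        q = mt.bh_qvalues(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mt.bh_qvalues([0.5, 1.5])


class TestLocalLambda:
    def _counts(self, arr, total):
        return mt.BinnedTrack(10, {"chr1": np.asarray(arr, float)}, total,
                              kind="counts")

    def test_uniform_coverage_local_equals_background(self):
        # constant 2 fragments/bin everywhere; G = chromosome length
        counts = self._counts(np.full(2000, 2.0), total=1000)
        cfg = mt.PeakCallerConfig(effective_genome_size=20_000)
        lb = mt.local_lambda(counts, "chr1", 10_000, cfg, 1.0, {"chr1": 20_000})
        assert lb.lambda_bg == pytest.approx(2.0)
        assert lb.lambda_local == pytest.approx(lb.lambda_bg)

    def test_spike_in_small_window_dominates(self):
        arr = np.zeros(2000)
        arr[995:1005] = 50.0  # confined to the 1-kb window around bin 1000
        counts = self._counts(arr, total=500)
        cfg = mt.PeakCallerConfig(effective_genome_size=20_000, d_window=0)
        lb = mt.local_lambda(counts, "chr1", 10_000, cfg, 1.0, {"chr1": 20_000})
        assert lb.lambda_local == pytest.approx(lb.lambda_windows[1000])
        assert lb.lambda_windows[1000] > lb.lambda_windows[10_000] > lb.lambda_bg

    def test_constructed_window_means_hand_computed(self):
        # bin-count mass: 20 inside the 1-kb window, 40 within 5 kb,
        # 60 within 10 kb; windows span 2*half+1 bins
        arr = np.zeros(2000)
        arr[970] = arr[1030] = 10.0
        arr[800] = arr[1200] = 10.0
        arr[600] = arr[1400] = 10.0
        counts = self._counts(arr, total=60)
        cfg = mt.PeakCallerConfig(effective_genome_size=20_000, d_window=0)
        lb = mt.local_lambda(counts, "chr1", 10_000, cfg, 1.0, {"chr1": 20_000})
        assert lb.lambda_windows[1000] == pytest.approx(20 / 101)
        assert lb.lambda_windows[5000] == pytest.approx(40 / 501)
        assert lb.lambda_windows[10_000] == pytest.approx(60 / 1001)
        assert lb.lambda_bg == pytest.approx(60 / 2000)
        assert lb.lambda_local == pytest.approx(20 / 101)

    def test_scalar_matches_vectorized_track(self, tiny_study):
        from meriptools.peaks import _lambda_local_tracks

        ann = tiny_study.annotation
        counts = mt.bin_coverage(
            tiny_study.get("cond0", 1, "input"), ann.chrom_lengths, 10, "counts"
        )
        cfg = mt.PeakCallerConfig()
        tracks = _lambda_local_tracks(counts, cfg, ann.chrom_lengths, 1.0)
        rng = np.random.default_rng(3)
        chrom = "chr1"
        n = len(counts.values[chrom])
        for b in rng.integers(600, n - 600, size=10):
            lb = mt.local_lambda(counts, chrom, int(b) * 10, cfg, 1.0,
                                 ann.chrom_lengths)
            assert tracks[chrom][b] == pytest.approx(lb.lambda_local)

    def test_depth_ratio_must_be_positive(self):
        counts = self._counts(np.ones(100), 10)
        with pytest.raises(ValueError):
            mt.local_lambda(counts, "chr1", 50, mt.PeakCallerConfig(), 0.0,
                            {"chr1": 1000})


class TestCallPeaks:
    def test_ip_identical_to_input_yields_no_peaks(self, dedup_rep1, study):
        ip, _ = dedup_rep1
        clone = AlignedFragmentSet("clone", "input", fragments=list(ip.fragments))
        peaks = mt.call_peaks(ip, clone, mt.PeakCallerConfig(),
                              study.annotation.chrom_lengths)
        assert peaks == []

    def test_emitted_peaks_satisfy_contracts(self, called_peaks):
        cfg = mt.PeakCallerConfig()
        by_chrom = {}
        for pk in called_peaks:
            assert pk.length >= cfg.min_peak_length
            assert pk.start <= pk.summit < pk.end
            assert pk.q < cfg.q_cutoff
            assert pk.q >= pk.p
            assert pk.fold_enrichment > 1.0
            by_chrom.setdefault(pk.chrom, []).append((pk.start, pk.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_stricter_cutoff_never_adds_peaks(self, study, dedup_rep1):
        ip, inp = dedup_rep1
        lengths = study.annotation.chrom_lengths
        counts = [
            len(mt.call_peaks(ip, inp, mt.PeakCallerConfig(q_cutoff=q), lengths))
            for q in (0.05, 1e-3, 1e-10)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_recovers_planted_sites_with_high_precision(self, called_peaks, study):
        recall, precision = mt.evaluate_peak_calls(
            called_peaks, study.truth.all_sites, tolerance_bp=200
        )
        assert recall >= 0.8 and precision >= 0.8

    def test_direction_asymmetry_swapped_call_misses_sites(self, study, dedup_rep1):
        """Forward calls localize planted sites; swapping IP and input must
        not: the swapped call's site precision collapses to ~0."""
        ip, inp = dedup_rep1
        lengths = study.annotation.chrom_lengths
        fwd = mt.call_peaks(ip, inp, mt.PeakCallerConfig(), lengths)
        swapped = mt.call_peaks(inp, ip, mt.PeakCallerConfig(), lengths)
        _, prec_fwd = mt.evaluate_peak_calls(fwd, study.truth.all_sites)
        _, prec_swap = mt.evaluate_peak_calls(swapped, study.truth.all_sites)
        assert prec_fwd >= 0.8
        assert prec_swap < 0.2

    def test_empty_ip_warns_and_returns_empty(self, study):
        empty = AlignedFragmentSet("e", "IP")
        inp = study.get("cond0", 1, "input")
        with pytest.warns(UserWarning):
            assert mt.call_peaks(empty, inp, mt.PeakCallerConfig(),
                                 study.annotation.chrom_lengths) == []


def test_sliding_mean_window_is_centered_and_edge_normalized():
    x = np.zeros(50)
    x[25] = 10.0
    m = _sliding_mean(x, 10)  # 11-bin centered window
    assert m[25] == pytest.approx(10 / 11)
    assert m[20] == pytest.approx(10 / 11)
    assert m[19] == 0.0
    edge = _sliding_mean(np.ones(50), 10)
    assert edge[0] == pytest.approx(1.0)  # truncated window, not zero-padded
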