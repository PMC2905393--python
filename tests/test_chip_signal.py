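import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresschip.chip_signal import (
    Occupancy,
    ProbeTrack,
    SERParams,
    call_sers,
    estimate_fdr,
    find_apex,
    lowess_normalize,
    mad_threshold,
    quantile_normalize,
    smooth,
    smooth_track,
    window_binom_p,
)


def make_track(values, step=17):
    values = np.asarray(values, dtype=float)
    return ProbeTrack("chr1", np.arange(values.size) * step, values)


# ------------------------------------------------------------- normalisation


class TestLowess:
    def test_identical_channels_give_zero_ratios(self, rng):
        x = rng.uniform(100, 10_000, size=500)
        out = lowess_normalize(x, x)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_intensity_dependent_bias_removed(self, rng):
        wce = rng.uniform(100, 10_000, size=2000)
        bias = 0.5 * np.log10(wce)
        chip = wce * 2.0 ** (bias + rng.normal(0, 0.05, wce.size))
        out = lowess_normalize(chip, wce)
        a = 0.5 * (np.log2(chip) + np.log2(wce))
        slope = np.polyfit(a, out, 1)[0]
        assert abs(slope) < 0.01
        assert abs(np.median(out)) < 1e-12

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            lowess_normalize(np.array([1.0, -1.0]), np.array([1.0, 1.0]))


class TestQuantileNormalize:
    def test_identical_tracks_unchanged(self):
        v = np.array([0.3, -1.0, 2.0])
        a, b = quantile_normalize([v, v.copy()])
        assert np.allclose(a, v) and np.allclose(b, v)

    def test_hand_quantile_mean(self):
        a, b = quantile_normalize([np.array([1.0, 2, 3]), np.array([2.0, 4, 6])])
        assert np.allclose(a, [1.5, 3, 4.5])
        assert np.allclose(b, [1.5, 3, 4.5])

    def test_sorted_outputs_identical(self, rng):
        a, b = quantile_normalize([rng.normal(size=100), rng.normal(1, 2, 100)])
        assert np.array_equal(np.sort(a), np.sort(b))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize([np.zeros(3), np.zeros(4)])


# ------------------------------------------------------------------ threshold


class TestMadThreshold:
    def test_constant_track(self):
        assert mad_threshold(np.full(10, 3.7)) == pytest.approx(3.7)

    def test_hand_computation(self):
        # median 3, unscaled MAD 1 -> 3 + 2.5*1
        assert mad_threshold(np.array([1, 2, 3, 4, 100.0]), 2.5) == pytest.approx(5.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad_threshold(np.array([]))

    def test_gaussian_tail_fraction(self, rng):
        # 2.5 unscaled-MAD above the median is ~1.686 sigma: upper tail ~4.6%,
        # close to but not exactly the advertised top-3% rank cut
        x = rng.normal(size=200_000)
        frac = np.mean(x > mad_threshold(x, 2.5))
        assert 0.035 <= frac <= 0.055


class TestWindowBinomP:
    def test_zero_exceedances_certain(self):
        assert window_binom_p(0, 9, 0.03) == 1.0

    def test_closed_form_all_exceed(self):
        assert window_binom_p(9, 9, 0.5) == pytest.approx(0.5**9)

    def test_small_tail(self):
        # exact tail sum: sum_{j>=4} C(9,j) 0.03^j 0.97^(9-j)
        exact = sum(
            __import__("math").comb(9, j) * 0.03**j * 0.97 ** (9 - j)
            for j in range(4, 10)
        )
        assert window_binom_p(4, 9, 0.03) == pytest.approx(exact, rel=1e-12)
        assert window_binom_p(4, 9, 0.03) == pytest.approx(9.0e-5, rel=0.01)

    def test_invalid_pr_rejected(self):
        with pytest.raises(ValueError):
            window_binom_p(1, 9, 0.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        L=st.integers(min_value=1, max_value=10),
        m=st.integers(min_value=0, max_value=10),
        pr=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_matches_exhaustive_pattern_enumeration(self, L, m, pr):
        m = min(m, L)
        total = 0.0
        for pattern in itertools.product([0, 1], repeat=L):
            if sum(pattern) >= m:
                k = sum(pattern)
                total += pr**k * (1 - pr) ** (L - k)
        assert window_binom_p(m, L, pr) == pytest.approx(total, rel=1e-9)


# ------------------------------------------------------------------ smoothing


class TestSmooth:
    def test_constant_preserved(self):
        v = np.full(30, 1.25)
        assert np.allclose(smooth(v, 5, 3), v)

    def test_triple_boxcar_impulse_response(self):
        v = np.zeros(31)
        v[15] = 1.0
        out = smooth(v, 5, 3)
        assert out[15] == pytest.approx(19 / 125)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=50),
        st.integers(min_value=0, max_value=4),
    )
    def test_averaging_never_exceeds_max(self, values, rounds):
        v = np.array(values)
        out = smooth(v, 5, rounds)
        assert out.max() <= v.max() + 1e-12
        assert out.min() >= v.min() - 1e-12


class TestFindApex:
    def test_symmetric_peak_apex_at_center(self):
        track = make_track([0, 1, 2, 3, 2, 1, 0])
        pos, level = find_apex(0, 6, track)
        assert pos == track.positions[3]
        assert level == 3

    def test_monotone_ramp_apex_at_last(self):
        track = make_track([0, 1, 2, 3, 4])
        pos, _ = find_apex(0, 4, track)
        assert pos == track.positions[4]

    def test_ties_break_leftmost(self):
        track = make_track([0, 5, 5, 0])
        pos, _ = find_apex(0, 3, track)
        assert pos == track.positions[1]


# -------------------------------------------------------------------- calling


def planted_track(n=200, center=100, height=3.0, halfwidth_probes=8, noise=None):
    v = np.zeros(n) if noise is None else noise
    idx = np.arange(n)
    v = v + height * np.clip(1 - np.abs(idx - center) / halfwidth_probes, 0, None)
    return make_track(v)


class TestCallSers:
    def test_flat_track_yields_nothing(self):
        assert call_sers(make_track(np.zeros(100)), threshold=0.5,
                         exceed_fraction=0.03) == []

    def test_three_consecutive_probes_insufficient(self):
        v = np.zeros(100)
        v[50:53] = 5.0
        out = call_sers(make_track(v), threshold=1.0, exceed_fraction=0.03)
        assert out == []

    def test_four_consecutive_probes_sufficient(self):
        v = np.zeros(100)
        v[50:54] = 5.0
        out = call_sers(make_track(v), threshold=1.0, exceed_fraction=0.03)
        assert len(out) == 1

    def test_noiseless_peak_apex_near_plant(self):
        track = planted_track()
        out = call_sers(track, threshold=0.5, exceed_fraction=0.03)
        assert len(out) == 1
        assert abs(out[0].apex - track.positions[100]) <= 17

    def test_shift_invariance(self):
        track = planted_track()
        shifted = track.with_values(track.values + 2.0)
        a = call_sers(track, threshold=0.5, exceed_fraction=0.03)
        b = call_sers(shifted, threshold=2.5, exceed_fraction=0.03)
        assert [(s.start_bp, s.end_bp, s.apex) for s in a] == [
            (s.start_bp, s.end_bp, s.apex) for s in b
        ]

    def test_every_ser_has_min_consecutive_above_threshold(self, rng):
        v = rng.normal(0, 1, size=3000)
        v[100:110] += 6
        v[500:505] += 6
        track = make_track(v)
        thr = mad_threshold(v)
        params = SERParams()
        for ser in call_sers(track, params, threshold=thr,
                             exceed_fraction=float(np.mean(v > thr))):
            run = track.values[ser.start_index : ser.end_index + 1]
            assert ser.n_probes >= params.min_consecutive
            assert np.all(run > thr)

    def test_separated_runs_are_distinct_sers(self):
        v = np.zeros(100)
        v[20:26] = 5.0
        v[40:46] = 5.0
        out = call_sers(make_track(v), threshold=1.0, exceed_fraction=0.03)
        assert len(out) == 2

    def test_short_track_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert call_sers(make_track(np.zeros(5))) == []


class TestEstimateFdr:
    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr(make_track(np.zeros(100)), n_perm=0)

    def test_pure_noise_fdr_near_one(self, rng):
        v = rng.normal(0, 1, size=5000)
        fdr = estimate_fdr(make_track(v), n_perm=20, seed=0)
        assert np.isnan(fdr) or fdr > 0.3

    def test_strong_signal_low_fdr(self, dataset, default_config):
        fdr = estimate_fdr(dataset.chip_tracks, n_perm=25, seed=5)
        assert fdr < 0.04


class TestOccupancyInvariants:
    def test_apex_must_lie_inside_bounds(self):
        with pytest.raises(ValueError):
            Occupancy("chr1", 0, 3, 100, 200, 500, 2.0, 4)
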