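"""STFT/MWT numerics: oracle agreement, kernel geometry, comb responses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tripwave import (
    CombSpec,
    SpectralParams,
    build_kernel,
    calibration_factor,
    dft_coefficient,
    encode_indicators,
    make_comb,
    mwt_psd,
    normalize_track,
    single_track_indicators,
    stft_psd,
)


class TestDftCoefficient:
    def test_all_zero_segment(self):
        assert dft_coefficient(np.zeros(30), 30, 7) == 0

    def test_dc_term_counts_ones(self):
        assert dft_coefficient(np.ones(24), 24, 0) == pytest.approx(24)

    def test_period3_comb_magnitude(self):
        # each of the N/3 pulses contributes unit phase at k = N/3
        N = 90
        comb = np.zeros(N)
        comb[::3] = 1
        assert abs(dft_coefficient(comb, N, N // 3)) == pytest.approx(N / 3)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            dft_coefficient(np.zeros(10), 10, 10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dft_coefficient(np.zeros(9), 10, 1)


class TestStft:
    def test_homopolymer_has_no_period3_power(self):
        ind = encode_indicators("A" * 400)
        track = stft_psd(ind, SpectralParams(window=180))
        interior = track.values[~track.edge]
        assert np.allclose(interior, 0.0, atol=1e-16)

    def test_comb_peaks_inside_active_interval(self, ind_p3):
        track = stft_psd(ind_p3, SpectralParams(window=180))
        v = track.values / track.values.max()
        assert 300 < int(np.argmax(v)) < 600
        assert v[:150].max() < 0.05 and v[750:].max() < 0.05

    def test_window_longer_than_sequence(self):
        with pytest.raises(ValueError):
            stft_psd(encode_indicators("ACGT" * 10), SpectralParams(window=180))

    def test_random_dna_mean_far_below_comb_peak(self, ind_p3):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        params = SpectralParams(window=180)
        rand = stft_psd(encode_indicators(seq), params)
        comb = stft_psd(ind_p3, params)
        assert rand.values[~rand.edge].mean() < 0.1 * comb.values.max()

    @given(st.integers(0, 2**31 - 1), st.integers(60, 120))
    def test_oracle_equivalence(self, seed, window):
        """Sliding STFT equals the brute-force DFT sum at every tested center."""
        window -= window % 3
        rng = np.random.default_rng(seed)
        L = int(rng.integers(window, 3 * window))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        ind = encode_indicators(seq)
        params = SpectralParams(window=window)
        track = stft_psd(ind, params)
        k = window // 3
        centers = rng.integers(window // 2, L - (window - 1 - window // 2), size=5)
        for c in centers:
            start = c - window // 2
            expected = sum(
                abs(dft_coefficient(row[start : start + window], window, k)) ** 2
                for row in ind.tracks
            )
            assert track.values[c] == pytest.approx(expected, rel=1e-9, abs=1e-12)
            assert not track.edge[c]


class TestKernel:
    @pytest.mark.parametrize("a", [2.5, 5.0, 10.0])
    def test_carrier_period_independent_of_scale(self, a):
        k = build_kernel(SpectralParams(a=a, b=3))
        center = len(k.offsets) // 2
        phases = k.taps[[center, center + 3, center + 6]] / k.envelope[[center, center + 3, center + 6]]
        assert np.allclose(phases, phases[0])

    def test_envelope_peak_at_center(self):
        k = build_kernel(SpectralParams())
        assert np.argmax(k.envelope) == len(k.offsets) // 2
        assert np.allclose(k.envelope, k.envelope[::-1])  # symmetric

    def test_effective_width_decreases_with_scale(self):
        def width(a):
            k = build_kernel(SpectralParams(a=a))
            w = k.envelope**2
            return np.sqrt(np.sum(w * k.offsets**2) / np.sum(w))

        assert width(10.0) < width(5.0) < width(2.5)

    def test_omega0_is_derived(self):
        p = SpectralParams(N=1200, b=3)
        assert p.omega0 == 400

    @pytest.mark.parametrize(
        "kwargs", [dict(a=0), dict(a=-1), dict(b=1), dict(N=2, b=3), dict(window=100)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpectralParams(**kwargs)


class TestMwt:
    def test_all_zero_input_gives_zero_track(self):
        ind = single_track_indicators(np.zeros(900, dtype=np.uint8))
        # a lone N-run encodes to all-zero channels as well
        track = mwt_psd(ind)
        assert np.allclose(track.values, 0.0)

    def test_comb_peak_location_and_boundary(self, ind_p3):
        track = mwt_psd(ind_p3)
        v = track.values / track.values.max()
        assert 300 <= int(np.argmax(v)) <= 600
        above = np.where(v > 0.2)[0]
        assert abs(above[0] - 300) <= 10 and abs(above[-1] - 600) <= 10
        assert v[:250].max() < 0.05 and v[650:].max() < 0.05

    def test_alias_amplitude_ratios(self, ind_p3, ind_p6, ind_p9):
        """Pure 2p/3p combs alias into the period-3 band at 1/4 and 1/9 power."""
        p3 = mwt_psd(ind_p3, scale="raw").max
        p6 = mwt_psd(ind_p6, scale="raw").max
        p9 = mwt_psd(ind_p9, scale="raw").max
        assert p6 / p3 == pytest.approx(1 / 4, rel=0.1)
        assert p9 / p3 == pytest.approx(1 / 9, rel=0.1)

    def test_calibrated_peak_heights(self, ind_p3, ind_p6, ind_p9):
        assert mwt_psd(ind_p3).max == pytest.approx(0.25, rel=0.15)
        assert mwt_psd(ind_p6).max == pytest.approx(0.062, rel=0.15)
        assert mwt_psd(ind_p9).max == pytest.approx(0.027, rel=0.15)

    def test_b6_captures_p6_with_same_amplitude_as_aliased_b3(self, ind_p6):
        b3 = mwt_psd(ind_p6, SpectralParams(b=3), scale="raw").max
        b6 = mwt_psd(ind_p6, SpectralParams(b=6), scale="raw").max
        assert 0.8 <= b6 / b3 <= 1.25

    def test_peak_amplitude_decreases_with_scale(self, ind_p3):
        peaks = [mwt_psd(ind_p3, SpectralParams(a=a), scale="raw").max for a in (2.5, 5.0, 10.0)]
        assert peaks[0] > peaks[1] > peaks[2]

    def test_boundary_sharpness_increases_with_scale(self, ind_p3):
        def transition_width(a):
            v = mwt_psd(ind_p3, SpectralParams(a=a)).values
            v = v / v.max()
            left = v[:450]
            return int(np.argmax(left > 0.8)) - int(np.argmax(left > 0.2))

        assert transition_width(10.0) < transition_width(5.0) < transition_width(2.5)

    def test_translation_equivariance(self):
        base = make_comb(CombSpec(length=1200, start=300, end=600))
        shifted = make_comb(CombSpec(length=1200, start=303, end=603))
        t0 = mwt_psd(single_track_indicators(base)).values
        t1 = mwt_psd(single_track_indicators(shifted)).values
        assert np.allclose(t0[200:700], t1[203:703], rtol=1e-9, atol=1e-12)

    def test_single_channel_equals_four_channel_with_nulls(self, comb_p3):
        """PSD of a lone track reduces to |U|^2: adding null channels changes nothing."""
        ind = single_track_indicators(comb_p3)
        only = mwt_psd(ind).values
        tracks = ind.tracks.copy()
        tracks[1] = tracks[0]  # duplicate into a second channel -> doubles PSD
        doubled = mwt_psd(type(ind)("x", tracks)).values
        assert np.allclose(doubled, 2 * only)

    def test_sequence_shorter_than_period(self):
        with pytest.raises(ValueError):
            mwt_psd(encode_indicators("AC"), SpectralParams(b=3))

    def test_literal_convention_is_available_but_distinct(self, ind_p3):
        lit = mwt_psd(ind_p3, convention="literal", scale="raw")
        default = mwt_psd(ind_p3, scale="raw")
        assert np.all(np.isfinite(lit.values))
        assert not np.allclose(lit.values, default.values)

    def test_calibration_factor_independent_of_b(self):
        assert calibration_factor(SpectralParams(b=3)) == calibration_factor(SpectralParams(b=6))


class TestNormalizeTrack:
    def test_self_normalization(self, ind_p3):
        t = normalize_track(mwt_psd(ind_p3))
        assert t.max == pytest.approx(1.0)
        assert t.normalization == "max"

    def test_shared_reference_preserves_ratio(self, ind_p3, ind_p6):
        t3, t6 = mwt_psd(ind_p3, scale="raw"), mwt_psd(ind_p6, scale="raw")
        ratio = t6.max / t3.max
        ref = t3.max
        n3, n6 = normalize_track(t3, ref), normalize_track(t6, ref)
        assert n6.max / n3.max == pytest.approx(ratio)

    def test_null_track_unchanged(self):
        t = mwt_psd(single_track_indicators(np.zeros(300, dtype=np.uint8)))
        n = normalize_track(t)
        assert np.allclose(n.values, 0.0) and n.normalization == "max"

    def test_nonpositive_reference_rejected(self, ind_p3):
        with pytest.raises(ValueError):
            normalize_track(mwt_psd(ind_p3), 0.0)
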