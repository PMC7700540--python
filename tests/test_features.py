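import math

import numpy as np
import pytest

from harkit import features as ft
from harkit.types import WindowFrame

import oracles


def make_frame(x, y=None, z=None, rate=100.0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
    return WindowFrame(
        axes=np.column_stack([x, y, z]), start_index=0, sampling_rate=rate
    )


class TestTimeDomain:
    def test_magnitude_mean_345(self):
        f = make_frame([3.0] * 8, [4.0] * 8, [0.0] * 8)
        assert ft.signal_magnitude_mean(f) == pytest.approx(5.0)

    def test_magnitude_mean_zero_frame(self):
        assert ft.signal_magnitude_mean(make_frame(np.zeros(8))) == 0.0

    def test_zcr_all_positive_is_zero(self):
        assert ft.zero_crossing_rate(np.ones(10)) == 0.0

    def test_zcr_alternating_is_one(self):
        s = np.array([1.0, -1.0] * 4)
        assert ft.zero_crossing_rate(s) == pytest.approx(1.0)

    def test_peaks_on_ramp(self):
        neg, pos = ft.peak_features(np.arange(1.0, 9.0))
        assert (neg, pos) == (1.0, 8.0)

    def test_peaks_constant_fallback(self):
        neg, pos = ft.peak_features(np.full(6, 2.5))
        assert (neg, pos) == (2.5, 2.5)

    def test_peaks_symmetric(self):
        neg, pos = ft.peak_features(np.array([-5.0, 0, 0, 0, 0, 5.0]))
        assert (neg, pos) == (-5.0, 5.0)

    def test_std_closed_form(self):
        assert ft.std_feature([1, 2, 3, 4]) == pytest.approx(math.sqrt(5 / 3))
        assert ft.std_feature([2, 2, 2]) == 0.0

    def test_std_length_one_raises(self):
        with pytest.raises(ValueError):
            ft.std_feature([1.0])

    def test_mode_constant(self):
        assert ft.mode_feature(np.full(5, 4.2)) == 4.2

    def test_mode_majority_bin(self):
        v = ft.mode_feature(np.array([0.0, 0.0, 0.0, 1.0]))
        assert 0.0 <= v < 0.1  # center of the bin containing 0

    def test_sma_literal_signed_sum(self):
        f = make_frame([1.0, 1.0], [2.0, 2.0], [3.0, 3.0])
        assert ft.signal_magnitude_area(f) == pytest.approx(6.0)
        assert ft.signal_magnitude_area(make_frame(np.zeros(4))) == 0.0

    def test_sma_absolute_option(self):
        f = make_frame([-1.0, -1.0], [2.0, 2.0], [0.0, 0.0])
        assert ft.signal_magnitude_area(f) == pytest.approx(1.0)
        assert ft.signal_magnitude_area(f, absolute=True) == pytest.approx(3.0)

    def test_energy(self):
        assert ft.signal_energy([1.0, -1.0, 1.0, -1.0]) == 1.0

    def test_correlation_affine_dependence(self):
        x = np.arange(10.0)
        f = make_frame(x, 2 * x + 1, x[::-1])
        r_xy, r_yz, r_zx = ft.correlation_features(f)
        assert r_xy == pytest.approx(1.0)
        assert r_zx == pytest.approx(-1.0)

    def test_correlation_constant_axis_zero(self, caplog):
        f = make_frame(np.arange(8.0), np.arange(8.0), np.full(8, 3.0))
        with caplog.at_level("WARNING"):
            _, r_yz, r_zx = ft.correlation_features(f)
        assert r_yz == 0.0 and r_zx == 0.0


class TestFrequencyDomain:
    def test_fundamental_of_pure_tone(self):
        t = np.arange(200) / 100.0
        f0 = ft.fundamental_frequency(np.sin(2 * np.pi * 2.0 * t), 100.0)
        assert abs(f0 - 2.0) <= 0.5

    def test_phase_of_zero_phase_cosine(self):
        t = np.arange(200) / 100.0  # 2 Hz -> integer periods in the window
        phi = ft.phase_angle(np.cos(2 * np.pi * 2.0 * t), 100.0)
        assert abs(phi) < 0.1

    def test_constant_series_conventions(self):
        c = np.full(16, 3.3)
        assert ft.fundamental_frequency(c, 100.0) == 0.0
        assert ft.phase_angle(c, 100.0) == 0.0

    def test_spectral_entropy_single_bin_is_zero(self):
        t = np.arange(64) / 64.0
        s = np.sin(2 * np.pi * 8 * t)  # exactly one rfft bin
        assert ft.spectral_entropy(s, 64.0) == pytest.approx(0.0, abs=1e-9)

    def test_spectral_entropy_flat_is_one(self):
        # white spectrum: a unit impulse has equal power in every bin
        s = np.zeros(64)
        s[0] = 1.0
        assert ft.spectral_entropy(s, 64.0) == pytest.approx(1.0, rel=1e-6)

    def test_spectral_entropy_two_of_four_bins(self):
        band = ft.SpectralBand(f1=0.0, f2=4.0, n_band=4)
        t = np.arange(8) / 8.0
        s = np.sin(2 * np.pi * t) + np.sin(2 * np.pi * 2 * t)
        val = ft.spectral_entropy(s, 8.0, band)
        assert val == pytest.approx(math.log(2) / math.log(4), rel=1e-9)

    def test_all_zero_series_entropy_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert ft.spectral_entropy(np.zeros(16), 100.0) == 0.0


class TestEMD:
    def test_monotone_ramp_has_no_imfs(self):
        d = ft.emd(np.linspace(0.0, 1.0, 50))
        assert d.imfs == []
        np.testing.assert_array_equal(d.residue, np.linspace(0.0, 1.0, 50))

    def test_two_tone_separation(self):
        t = np.arange(400) / 100.0
        hi, lo = np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 1 * t)
        d = ft.emd(hi + lo)
        assert len(d.imfs) >= 2
        assert np.corrcoef(d.imfs[0], hi)[0, 1] > 0.9

    def test_reconstruction_invariant(self, rng):
        for _ in range(5):
            s = rng.normal(size=200)
            d = ft.emd(s)
            err = np.linalg.norm(d.reconstruct() - s) / np.linalg.norm(s)
            assert err < 1e-8

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            ft.emd(np.arange(5.0))


class TestHHT:
    def test_ramp_zero_filled(self):
        vals = ft.hht_features(np.linspace(0, 1, 64), 100.0)
        assert vals == [0.0] * 9

    def test_pure_tone_instantaneous_frequency(self):
        t = np.arange(200) / 100.0
        vals = ft.hht_features(np.sin(2 * np.pi * 5 * t), 100.0)
        imf1_energy, _, imf1_freq = vals[0], vals[1], vals[2]
        assert imf1_energy > 0.95
        assert abs(imf1_freq - 5.0) < 0.25


class TestExtractAll:
    def test_vector_length_and_unique_names(self, random_frame):
        fv = ft.extract_all(random_frame)
        assert len(fv) == 74
        assert len(set(fv.names)) == 74
        assert set(fv.groups) == {"time", "frequency", "acoustic"}

    def test_all_zero_frame_gives_zero_vector(self):
        fv = ft.extract_all(make_frame(np.zeros(64)))
        np.testing.assert_array_equal(fv.values, np.zeros(74))

    def test_purity(self, random_frame):
        a = ft.extract_all(random_frame)
        b = ft.extract_all(random_frame)
        np.testing.assert_array_equal(a.values, b.values)

    def test_merge_sensor_vectors_prefixes_names(self, random_frame):
        a = ft.extract_all(random_frame)
        b = ft.extract_all(random_frame)
        merged = ft.merge_sensor_vectors([a, b], placements=["wrist", "chest"])
        assert len(merged) == 148
        assert merged.names[0].startswith("wrist_")
        assert merged.names[74].startswith("chest_")


@pytest.fixture(scope="module")
def frames():
    rng = np.random.default_rng(99)
    return [
        WindowFrame(
            axes=rng.normal(0, 1, size=(128, 3)),
            start_index=0,
            sampling_rate=100.0,
        )
        for _ in range(5)
    ]


class TestBruteForceAgreement:
    """Spot agreement with the naive-loop oracles (the full 100-frame
    sweep lives in the acceptance suite)."""

    def test_scalar_features_match_naive(self, frames):
        for fr in frames:
            for s in (fr.x, fr.y, fr.z):
                sl = list(s)
                assert ft.mean_feature(s) == pytest.approx(oracles.naive_mean(sl), rel=1e-9)
                assert ft.median_feature(s) == pytest.approx(oracles.naive_median(sl), rel=1e-9)
                assert ft.std_feature(s) == pytest.approx(oracles.naive_std(sl), rel=1e-9)
                assert ft.mode_feature(s) == pytest.approx(oracles.naive_mode(sl), rel=1e-9)
                assert ft.peak_features(s) == pytest.approx(oracles.naive_peaks(sl), rel=1e-9)
                centered = s - s.mean()
                assert ft.zero_crossing_rate(centered) == pytest.approx(
                    oracles.naive_zcr(list(centered)), rel=1e-9
                )
                assert ft.signal_energy(s) == pytest.approx(oracles.naive_energy(sl), rel=1e-9)

    def test_spectral_features_match_naive(self, frames):
        for fr in frames[:2]:
            s = fr.x
            assert ft.fundamental_frequency(s, 100.0) == pytest.approx(
                oracles.naive_fundamental(list(s), 100.0), rel=1e-9
            )
            assert ft.phase_angle(s, 100.0) == pytest.approx(
                oracles.naive_phase(list(s), 100.0), rel=1e-6, abs=1e-9
            )
            assert ft.spectral_entropy(s, 100.0) == pytest.approx(
                oracles.naive_spectral_entropy(list(s), 100.0), rel=1e-9
            )

    def test_hht_matches_independent_sifting(self, frames):
        s = frames[0].x
        mine = ft.hht_features(s, 100.0)
        theirs = oracles.naive_hht(list(s), 100.0)
        np.testing.assert_allclose(mine, theirs, rtol=1e-6, atol=1e-6)


class TestEquivariance:
    def test_amplitude_scaling(self, random_frame):
        c = 3.7
        scaled = WindowFrame(
            axes=random_frame.axes * c,
            start_index=0,
            sampling_rate=random_frame.sampling_rate,
        )
        a = ft.extract_all(random_frame)
        b = ft.extract_all(scaled)
        v = dict(zip(a.names, a.values))
        w = dict(zip(b.names, b.values))
        for axis in ("x", "y", "z"):
            for stem in ("mean", "std", "min", "max", "neg_peak", "pos_peak"):
                assert w[f"{axis}_{stem}"] == pytest.approx(c * v[f"{axis}_{stem}"], rel=1e-9)
            assert w[f"{axis}_energy"] == pytest.approx(c**2 * v[f"{axis}_energy"], rel=1e-9)
            for stem in ("zcr", "spec_entropy", "fund_freq"):
                assert w[f"{axis}_{stem}"] == pytest.approx(v[f"{axis}_{stem}"], rel=1e-9)
        assert w["mag_mean"] == pytest.approx(c * v["mag_mean"], rel=1e-9)
        assert w["sma"] == pytest.approx(c * v["sma"], rel=1e-9)
        for pair in ("xy", "yz", "zx"):
            assert w[f"corr_{pair}"] == pytest.approx(v[f"corr_{pair}"], rel=1e-9)

    def test_bounded_features_on_random_suite(self, rng):
        for _ in range(20):
            fr = WindowFrame(
                axes=rng.normal(0, rng.uniform(0.5, 3), size=(64, 3)),
                start_index=0,
                sampling_rate=100.0,
            )
            fv = dict(zip(*[ft.extract_all(fr).names, ft.extract_all(fr).values]))
            for axis in ("x", "y", "z"):
                assert 0.0 <= fv[f"{axis}_zcr"] <= 1.0
                assert 0.0 <= fv[f"{axis}_spec_entropy"] <= 1.0
            for pair in ("xy", "yz", "zx"):
                assert abs(fv[f"corr_{pair}"]) <= 1.0
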