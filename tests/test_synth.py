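"""Pulse, recording and corpus generator tests.

Oracles: a direct-summation DFT for the spectral centroid, recorded onset
times for the Poisson count, closed-form RMS for orthogonal-tone mixing.
"""

import numpy as np
import pytest

from rmamnet.dataset import read_wav
from rmamnet.synth import (
    NOMINAL_PEAK,
    CorpusConfig,
    SpeciesProfile,
    build_corpus,
    default_profiles,
    mix_signals,
    synth_pulse,
    synth_recording,
)

SR = 44_100


def dft_centroid(x: np.ndarray, sr: float) -> float:
    """Spectral centroid from a direct-summation DFT (no FFT)."""
    n = x.size
    k = np.arange(n // 2 + 1)
    basis = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    mag = np.abs(basis @ x)
    freqs = k * sr / n
    return float((freqs * mag).sum() / mag.sum())


class TestSynthPulse:
    def test_zero_amplitude_gives_silence(self, fast_profile, rng):
        x = synth_pulse(fast_profile, SR, 0.0, rng)
        assert x.size > 0
        assert np.all(x == 0.0)

    def test_peak_equals_requested_amplitude(self, fast_profile, rng):
        x = synth_pulse(fast_profile, SR, 0.37, rng)
        assert np.max(np.abs(x)) == pytest.approx(0.37, rel=0.01)

    def test_fast_attack_peak_position(self):
        # Peak must fall in the initial rise, far before the decay tail.
        p = SpeciesProfile(
            name="t", band_center_hz=10_000.0, band_width_hz=2000.0,
            pulse_rate_hz=5.0, attack_ms=1.0, decay_ms=10.0,
        )
        limit = int((p.attack_ms + 0.25 * p.decay_ms) * 1e-3 * SR)
        for seed in range(10):
            x = synth_pulse(p, SR, 1.0, np.random.default_rng(seed))
            assert int(np.argmax(np.abs(x))) < limit

    def test_spectral_centroid_within_band(self):
        p = SpeciesProfile(
            name="t", band_center_hz=10_000.0, band_width_hz=2000.0,
            pulse_rate_hz=5.0, attack_ms=1.0, decay_ms=10.0,
        )
        x = synth_pulse(p, SR, 1.0, np.random.default_rng(3))
        centroid = dft_centroid(x, SR)
        assert abs(centroid - p.band_center_hz) < p.band_width_hz / 2

    def test_band_above_nyquist_rejected(self, rng):
        p = SpeciesProfile(
            name="alias", band_center_hz=9000.0, band_width_hz=1000.0, pulse_rate_hz=1.0
        )
        with pytest.raises(ValueError, match="Nyquist"):
            synth_pulse(p, 16_000, 1.0, rng)

    def test_attack_slower_than_decay_rejected(self, rng):
        p = SpeciesProfile(
            name="slow", band_center_hz=3000.0, band_width_hz=500.0,
            pulse_rate_hz=1.0, attack_ms=20.0, decay_ms=10.0,
        )
        with pytest.raises(ValueError, match="attack"):
            synth_pulse(p, SR, 1.0, rng)


class TestSynthRecording:
    def test_zero_rate_is_pure_background_noise(self, fast_profile):
        from dataclasses import replace

        silent = replace(fast_profile, pulse_rate_hz=0.0)
        cfg = CorpusConfig(snr_db=10.0)
        x = np.asarray(synth_recording(silent, 1.0, cfg, np.random.default_rng(0)))
        expected_std = NOMINAL_PEAK * 10 ** (-cfg.snr_db / 20.0)
        assert x.std() == pytest.approx(expected_std, rel=0.05)

    def test_poisson_pulse_count(self, fast_profile):
        from dataclasses import replace

        p = replace(fast_profile, pulse_rate_hz=2.0)
        cfg = CorpusConfig()
        _, onsets = synth_recording(p, 60.0, cfg, np.random.default_rng(5), return_events=True)
        mean, sd = 120.0, np.sqrt(120.0)
        assert abs(len(onsets) - mean) < 3 * sd

    def test_determinism_under_fixed_seed(self, fast_profile):
        cfg = CorpusConfig()
        x1 = synth_recording(fast_profile, 2.0, cfg, np.random.default_rng(9))
        x2 = synth_recording(fast_profile, 2.0, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(x1, x2)

    def test_output_bounded_and_finite(self, fast_profile):
        x = np.asarray(synth_recording(fast_profile, 3.0, CorpusConfig(), np.random.default_rng(1)))
        assert np.all(np.isfinite(x))
        assert np.max(np.abs(x)) <= 1.0


class TestMixSignals:
    def test_mix_with_zeros_halves(self, rng):
        x = rng.normal(scale=0.1, size=1000)
        np.testing.assert_allclose(mix_signals(x, np.zeros(1000)), x / 2)

    def test_commutative(self, rng):
        a = rng.normal(scale=0.3, size=500)
        b = rng.normal(scale=0.3, size=700)  # also exercises zero-padding
        np.testing.assert_array_equal(mix_signals(a, b), mix_signals(b, a))

    def test_orthogonal_tone_rms(self):
        # Unit tones at bin frequencies are orthogonal over a full period:
        # RMS((a+b)/2) = sqrt(rms_a^2 + rms_b^2)/2 = rms_a / sqrt(2).
        n = 4096
        t = np.arange(n)
        a = np.sin(2 * np.pi * 16 * t / n)
        b = np.sin(2 * np.pi * 48 * t / n)
        mixed = mix_signals(a, b)
        rms_a = np.sqrt(np.mean(a**2))
        assert np.sqrt(np.mean(mixed**2)) == pytest.approx(rms_a / np.sqrt(2), abs=1e-6)

    def test_sample_rate_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mix_signals(np.zeros(10), np.zeros(10), 44_100, 16_000)


class TestBuildCorpus:
    def test_manifest_schema_and_durations(self, tiny_corpus_config, tmp_path):
        manifest = build_corpus(tiny_corpus_config, tmp_path / "c")
        assert list(manifest.columns) == ["path", "label", "day", "position", "duration_s"]
        assert set(manifest["label"]) == {0, 1, 2, 3}
        assert len(manifest) >= 4
        for label in (0, 1, 2):
            total = manifest.loc[manifest["label"] == label, "duration_s"].sum()
            assert total == pytest.approx(tiny_corpus_config.minutes_per_class * 60, abs=5.0)
        # durations in the manifest match the written WAV headers
        for row in manifest.itertuples(index=False):
            samples, rate = read_wav(tmp_path / "c" / row.path)
            assert samples.size / rate == pytest.approx(row.duration_s, abs=1e-3)
            assert rate == tiny_corpus_config.sample_rate_hz

    def test_noise_class_duration_ratio(self, tiny_corpus_config, tmp_path):
        manifest = build_corpus(tiny_corpus_config, tmp_path / "c")
        noise = manifest.loc[manifest["label"] == 3, "duration_s"].sum()
        signal = manifest.loc[manifest["label"] == 0, "duration_s"].sum()
        assert noise / signal == pytest.approx(tiny_corpus_config.noise_to_signal_ratio, rel=0.02)

    def test_same_seed_reproduces_bytes(self, tiny_corpus_config, tmp_path):
        m1 = build_corpus(tiny_corpus_config, tmp_path / "c1")
        m2 = build_corpus(tiny_corpus_config, tmp_path / "c2")
        assert m1.equals(m2)
        f1 = sorted((tmp_path / "c1").rglob("*.wav"))
        f2 = sorted((tmp_path / "c2").rglob("*.wav"))
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()

    def test_refuses_nonempty_dir_without_overwrite(self, tiny_corpus_config, tmp_path):
        out = tmp_path / "c"
        build_corpus(tiny_corpus_config, out)
        with pytest.raises(FileExistsError):
            build_corpus(tiny_corpus_config, out)
        build_corpus(tiny_corpus_config, out, overwrite=True)  # no error


def band_energy_ratio(x: np.ndarray, sr: int, band_a, band_b) -> float:
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / sr)
    ea = spec[(freqs >= band_a[0]) & (freqs < band_a[1])].sum()
    eb = spec[(freqs >= band_b[0]) & (freqs < band_b[1])].sum()
    return float(np.log(ea / eb))


def test_spectral_separability_between_species():
    """Class-0 vs class-1 band-energy statistics differ by > 2 pooled SDs.

    This is the structure the classifier relies on, checked without any
    model: the log ratio of energy in band A to band B, per 5-s segment.
    """
    prof_a, prof_b = default_profiles()
    cfg = CorpusConfig(seed=11)
    band_a = (prof_a.band_center_hz - 600, prof_a.band_center_hz + 600)
    band_b = (prof_b.band_center_hz - 750, prof_b.band_center_hz + 750)
    stats = {}
    for name, prof, seed in (("a", prof_a, 1), ("b", prof_b, 2)):
        x = np.asarray(synth_recording(prof, 60.0, cfg, np.random.default_rng(seed)))
        segs = x[: 12 * 5 * cfg.sample_rate_hz].reshape(12, -1)
        stats[name] = np.array(
            [band_energy_ratio(s, cfg.sample_rate_hz, band_a, band_b) for s in segs]
        )
    pooled_sd = np.sqrt((stats["a"].var(ddof=1) + stats["b"].var(ddof=1)) / 2)
    effect = abs(stats["a"].mean() - stats["b"].mean()) / pooled_sd
    assert effect > 2.0
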