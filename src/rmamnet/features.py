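"""Log-Mel feature extraction for 1-D CNN input.

A 5-s segment is resampled to 16 kHz, randomly (training) or centre
(evaluation) cropped / zero-padded to exactly 3 s, pre-emphasised, framed
with a 512-sample Hanning window at hop 160 with reflect-centred padding,
converted to a power spectrum, pooled through 80 triangular HTK-Mel filters
spanning 0 Hz to Nyquist, and log-compressed.  Under the defaults the
output is an 80 x 301 matrix: 80 Mel bands act as the network's input
channels and 301 frames as its length (T = 1 + floor(48000 / 160)).

An optional DCT along the Mel axis converts the representation to cepstral
coefficients; the default output is the log-Mel spectrogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as sft
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import Segment

__all__ = [
    "FeatureConfig",
    "resample",
    "crop_or_pad",
    "pre_emphasis",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "mel_center_freqs",
    "log_mel",
    "extract_features",
    "LogMelExtractor",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    Defaults reproduce the standard 80 x 301 log-Mel input: 16 kHz target
    rate, 3-s crop, frame 512 / hop 160 with a Hanning window and centred
    (reflect-padded) framing, 80 HTK-Mel filters from 0 Hz to Nyquist, and
    a 1e-10 floor before the natural log.
    """

    target_rate_hz: int = 16_000
    crop_s: float = 3.0
    preemph_coef: float = 0.97
    frame_len: int = 512
    hop: int = 160
    n_mels: int = 80
    fmin_hz: float = 0.0
    fmax_hz: float | None = None
    apply_dct: bool = False
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not 0 <= self.preemph_coef < 1:
            raise ValueError("preemph_coef must be in [0, 1)")
        if self.hop >= self.frame_len:
            raise ValueError("hop must be smaller than frame_len")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if int(round(self.crop_s * self.target_rate_hz)) % self.hop != 0:
            raise ValueError("crop_s * target_rate_hz must be divisible by hop")

    @property
    def crop_len(self) -> int:
        return int(round(self.crop_s * self.target_rate_hz))

    @property
    def n_frames(self) -> int:
        # Centred framing: reflect-pad frame_len//2 on both sides.
        return 1 + self.crop_len // self.hop

    @property
    def fmax(self) -> float:
        return self.fmax_hz if self.fmax_hz is not None else self.target_rate_hz / 2.0


def resample(x: np.ndarray, orig_rate_hz: int, target_rate_hz: int) -> np.ndarray:
    """Polyphase resampling between integer sample rates."""
    if orig_rate_hz == target_rate_hz:
        return np.asarray(x, dtype=np.float64)
    g = math.gcd(int(orig_rate_hz), int(target_rate_hz))
    return sps.resample_poly(np.asarray(x, dtype=np.float64), target_rate_hz // g, orig_rate_hz // g)


def crop_or_pad(
    x: np.ndarray,
    rate_hz: int,
    crop_s: float,
    mode: str = "center",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cut or right-zero-pad a waveform to exactly ``crop_s`` seconds.

    ``mode="random"`` draws the crop offset (training-time augmentation);
    ``mode="center"`` takes the middle window (deterministic evaluation).
    """
    x = np.asarray(x, dtype=np.float64)
    n_out = int(round(crop_s * rate_hz))
    if x.size == n_out:
        return x.copy()
    if x.size < n_out:
        return np.pad(x, (0, n_out - x.size))
    slack = x.size - n_out
    if mode == "random":
        if rng is None:
            raise ValueError("mode='random' requires an rng")
        start = int(rng.integers(0, slack + 1))
    elif mode == "center":
        start = slack // 2
    else:
        raise ValueError(f"unknown crop mode {mode!r}")
    return x[start : start + n_out]


def pre_emphasis(x: np.ndarray, coef: float = 0.97) -> np.ndarray:
    """First-order high-pass: ``y[n] = x[n] - coef * x[n-1]``, ``y[0] = x[0]``."""
    if not 0 <= coef < 1:
        raise ValueError("coef must be in [0, 1)")
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coef * x[:-1]
    return y


def hz_to_mel(f_hz):
    """HTK Mel scale: ``2595 * log10(1 + f / 700)``."""
    return 2595.0 * np.log10(1.0 + np.asarray(f_hz, dtype=np.float64) / 700.0)


def mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel, dtype=np.float64) / 2595.0) - 1.0)


def _mel_edge_freqs(n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    """n_mels + 2 band-edge frequencies equally spaced on the Mel scale."""
    mels = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    return mel_to_hz(mels)


def mel_center_freqs(config: FeatureConfig) -> np.ndarray:
    """Centre frequency (Hz) of each triangular Mel filter."""
    return _mel_edge_freqs(config.n_mels, config.fmin_hz, config.fmax)[1:-1]


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate_hz: int, fmin: float = 0.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular HTK-Mel filterbank, peak height 1, shape (n_mels, n_fft//2 + 1)."""
    if fmax is None:
        fmax = sample_rate_hz / 2.0
    edges = _mel_edge_freqs(n_mels, fmin, fmax)
    fft_freqs = np.arange(n_fft // 2 + 1) * sample_rate_hz / n_fft
    fb = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Centred framing: reflect-pad frame_len//2 each side, then slide."""
    pad = frame_len // 2
    xp = np.pad(x, (pad, pad), mode="reflect")
    n_frames = 1 + (xp.size - frame_len) // hop
    frames = np.lib.stride_tricks.sliding_window_view(xp, frame_len)[::hop]
    return frames[:n_frames]


def log_mel(x: np.ndarray, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Log-Mel spectrogram of an exactly ``crop_s``-long waveform.

    Returns an (n_mels, T) matrix, T = 1 + floor(len(x) / hop); 80 x 301
    under the defaults.  With ``apply_dct`` set, an orthonormal type-II DCT
    along the Mel axis yields cepstral coefficients of the same shape.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size != config.crop_len:
        raise ValueError(
            f"expected {config.crop_len} samples ({config.crop_s} s at "
            f"{config.target_rate_hz} Hz), got {x.size}"
        )
    frames = _frame(x, config.frame_len, config.hop)
    window = sps.get_window("hann", config.frame_len, fftbins=True)
    spectrum = np.fft.rfft(frames * window, axis=1)
    power = np.abs(spectrum) ** 2
    fb = mel_filterbank(
        config.n_mels, config.frame_len, config.target_rate_hz, config.fmin_hz, config.fmax
    )
    mel_power = power @ fb.T  # (T, n_mels)
    feat = np.log(np.maximum(mel_power, config.log_floor)).T
    if config.apply_dct:
        feat = sft.dct(feat, type=2, axis=0, norm="ortho")
    if not np.all(np.isfinite(feat)):
        raise FloatingPointError("non-finite values in log-Mel feature")
    return feat


def segment_to_feature(
    samples: np.ndarray,
    sample_rate_hz: int,
    config: FeatureConfig = FeatureConfig(),
    mode: str = "center",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full per-segment pipeline: resample, crop/pad, pre-emphasis, log-Mel."""
    x = resample(samples, sample_rate_hz, config.target_rate_hz)
    x = crop_or_pad(x, config.target_rate_hz, config.crop_s, mode=mode, rng=rng)
    x = pre_emphasis(x, config.preemph_coef)
    return log_mel(x, config)


def extract_features(
    segments: list[Segment],
    config: FeatureConfig = FeatureConfig(),
    mode: str = "center",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Feature matrix (N, n_mels, T) for a list of segments."""
    if mode == "random" and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    feats = [
        segment_to_feature(s.samples, s.sample_rate_hz, config, mode=mode, rng=rng)
        for s in segments
    ]
    return np.stack(feats).astype(np.float32) if feats else np.empty(
        (0, config.n_mels, config.n_frames), dtype=np.float32
    )


def spectrogram_png(feat: np.ndarray, path, sample_rate_hz: int = 16_000,
                    hop: int = 160) -> None:
    """Render a log-Mel feature matrix as a spectrogram image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    extent = [0, feat.shape[1] * hop / sample_rate_hz, 0, feat.shape[0]]
    im = ax.imshow(feat, origin="lower", aspect="auto", extent=extent, cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Mel band")
    fig.colorbar(im, label="log energy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


class LogMelExtractor(TransformerMixin, BaseEstimator):
    """scikit-learn transformer from waveform segments to log-Mel features.

    ``transform`` accepts either a list of :class:`Segment` or a 2-D array
    of equal-length waveforms already at ``sample_rate_hz``.
    """

    def __init__(
        self,
        sample_rate_hz: int = 44_100,
        config: FeatureConfig = FeatureConfig(),
        mode: str = "center",
        random_state: int | None = None,
    ):
        self.sample_rate_hz = sample_rate_hz
        self.config = config
        self.mode = mode
        self.random_state = random_state

    def fit(self, X, y=None):
        self.n_features_out_ = (self.config.n_mels, self.config.n_frames)
        return self

    def transform(self, X):
        rng = np.random.default_rng(self.random_state) if self.mode == "random" else None
        if len(X) and isinstance(X[0], Segment):
            return extract_features(list(X), self.config, mode=self.mode, rng=rng)
        X = np.asarray(X, dtype=np.float64)
        feats = [
            segment_to_feature(row, self.sample_rate_hz, self.config, mode=self.mode, rng=rng)
            for row in X
        ]
        return np.stack(feats).astype(np.float32)
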