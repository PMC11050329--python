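"""Corpus reading, 5-s segmentation and the temporal train/test split.

Recordings carry a day index and a within-day position (first / middle /
last 30-min third).  Training segments are drawn only from the first and
middle thirds of each day, test segments only from the last third, so the
two splits never share temporally adjacent material; within those pools a
seeded random 5:1 selection is made per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Segment",
    "SegmentSet",
    "read_wav",
    "write_wav",
    "segment_audio",
    "temporal_split",
    "load_manifest",
]

TRAIN_POSITIONS = frozenset({"first", "middle"})
TEST_POSITIONS = frozenset({"last"})
_PCM16_SCALE = 32768.0


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV file, returning float samples in [-1, 1] and the rate."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: missing or empty WAV file")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on chunk padding, not an error
        rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported sample format {data.dtype}")
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{path}: non-finite samples")
    return samples, int(rate)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate_hz: int) -> None:
    """Write float samples in [-1, 1] as mono 16-bit PCM."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise ValueError("only mono waveforms are written")
    pcm = np.clip(np.round(samples * _PCM16_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), int(sample_rate_hz), pcm)


@dataclass
class Recording:
    """A labelled mono recording with temporal-split metadata."""

    samples: np.ndarray
    sample_rate_hz: int
    label: int
    day: int
    position: str
    rec_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2, 3):
            raise ValueError(f"label must be in {{0,1,2,3}}, got {self.label}")
        if self.position not in ("first", "middle", "last"):
            raise ValueError(f"unknown position {self.position!r}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


@dataclass(frozen=True)
class Segment:
    """A fixed-length clip cut from one recording."""

    samples: np.ndarray
    sample_rate_hz: int
    label: int
    source_id: str
    offset_s: float


@dataclass
class SegmentSet:
    segments: list[Segment] = field(default_factory=list)
    split: str = "train"

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=np.int64)

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True) if self.segments else ((), ())
        return {int(l): int(c) for l, c in zip(labels, counts)}

    def keys(self) -> set[tuple[str, float]]:
        """(source recording id, offset) pairs — used for leakage checks."""
        return {(s.source_id, s.offset_s) for s in self.segments}

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_id": [s.source_id for s in self.segments],
                "label": [s.label for s in self.segments],
                "offset_s": [s.offset_s for s in self.segments],
                "duration_s": [s.samples.size / s.sample_rate_hz for s in self.segments],
                "split": self.split,
            }
        )


def segment_audio(recording: Recording, segment_s: float = 5.0) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping ``segment_s`` clips.

    The trailing remainder shorter than one segment is discarded.  A
    recording shorter than one segment yields an empty list with a warning.
    """
    seg_n = int(round(segment_s * recording.sample_rate_hz))
    count = recording.samples.size // seg_n
    if count == 0:
        warnings.warn(
            f"recording {recording.rec_id!r} ({recording.duration_s:.2f} s) is "
            f"shorter than one {segment_s} s segment; returning no segments",
            stacklevel=2,
        )
        return []
    return [
        Segment(
            samples=recording.samples[i * seg_n : (i + 1) * seg_n],
            sample_rate_hz=recording.sample_rate_hz,
            label=recording.label,
            source_id=recording.rec_id,
            offset_s=i * seg_n / recording.sample_rate_hz,
        )
        for i in range(count)
    ]


def temporal_split(
    recordings: list[Recording],
    ratio: tuple[int, int] = (5, 1),
    rng: np.random.Generator | int | None = None,
    segment_s: float = 5.0,
) -> tuple[SegmentSet, SegmentSet]:
    """Segment recordings and draw a seeded per-class train/test selection.

    Candidate training segments come from first/middle-third recordings and
    candidate test segments from last-third recordings only.  Per class,
    ``k = min(len(train_pool) // r_train, len(test_pool) // r_test)`` sets
    the scale and ``r_train*k`` / ``r_test*k`` segments are drawn without
    replacement, so selected counts honour the ratio exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r_train, r_test = ratio
    if r_train < 1 or r_test < 1:
        raise ValueError("ratio parts must be >= 1")

    pools: dict[int, dict[str, list[Segment]]] = {}
    for rec in recordings:
        side = "train" if rec.position in TRAIN_POSITIONS else "test"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segs = segment_audio(rec, segment_s)
        pools.setdefault(rec.label, {"train": [], "test": []})[side].extend(segs)

    train = SegmentSet(split="train")
    test = SegmentSet(split="test")
    for label in sorted(pools):
        tr_pool, te_pool = pools[label]["train"], pools[label]["test"]
        if not te_pool:
            raise ValueError(
                f"class {label}: no last-third material, test pool is empty"
            )
        if not tr_pool:
            raise ValueError(
                f"class {label}: no first/middle-third material, train pool is empty"
            )
        k = min(len(tr_pool) // r_train, len(te_pool) // r_test)
        if k == 0:
            raise ValueError(
                f"class {label}: pools too small for a {r_train}:{r_test} selection "
                f"({len(tr_pool)} train-range, {len(te_pool)} test-range segments)"
            )
        train.segments.extend(
            tr_pool[i] for i in rng.choice(len(tr_pool), size=r_train * k, replace=False)
        )
        test.segments.extend(
            te_pool[i] for i in rng.choice(len(te_pool), size=r_test * k, replace=False)
        )

    leaked = train.keys() & test.keys()
    assert not leaked, f"split leakage: {sorted(leaked)[:5]}"
    return train, test


def load_manifest(manifest_path: str | Path, audio_root: str | Path | None = None) -> list[Recording]:
    """Load every recording listed in a ``path,label,day,position,duration_s`` manifest."""
    manifest_path = Path(manifest_path)
    root = Path(audio_root) if audio_root is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"path", "label", "day", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    recordings = []
    for row in df.itertuples(index=False):
        samples, rate = read_wav(root / row.path)
        recordings.append(
            Recording(
                samples=samples,
                sample_rate_hz=rate,
                label=int(row.label),
                day=int(row.day),
                position=str(row.position),
                rec_id=str(row.path),
            )
        )
    return recordings
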