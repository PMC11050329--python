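"""High-level pipeline helpers shared by the CLI and scripts.

These glue the stages together: synthesise or load a corpus, make the
temporal split, extract features, fit the classifier, evaluate.  The heavy
lifting lives in the stage modules; everything here is thin and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import Recording, SegmentSet, load_manifest, temporal_split
from .estimator import RMAMNetClassifier
from .evaluate import EvalReport, evaluate
from .features import FeatureConfig, extract_features
from .synth import CorpusConfig, synthesize_recordings

__all__ = [
    "SplitArrays",
    "study_corpus_config",
    "synthesize_recordings",
    "split_corpus",
    "featurize_split",
    "run_end_to_end",
]


def study_corpus_config(seed: int = 0) -> CorpusConfig:
    """Synthetic study conditions for end-to-end evaluation.

    18 minutes of audio per signal class yields roughly two hundred
    five-second segments per class (the noise class proportionally more),
    which the 5:1 temporal split turns into ~590 training and ~120 test
    segments — enough for the four-class problem to be learnable while
    keeping a CPU run in the minutes range.
    """
    return CorpusConfig(seed=seed, minutes_per_class=18.0)


@dataclass
class SplitArrays:
    """Feature/label arrays for both splits, plus the segment sets."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_set: SegmentSet
    test_set: SegmentSet


def split_corpus(
    source: CorpusConfig | str | Path | list[Recording],
    ratio: tuple[int, int] = (5, 1),
    segment_s: float = 5.0,
    seed: int | None = 0,
) -> tuple[SegmentSet, SegmentSet]:
    """Temporal 5:1 split from a config (in-memory), manifest path, or recordings."""
    if isinstance(source, CorpusConfig):
        recordings = synthesize_recordings(source)
    elif isinstance(source, (str, Path)):
        recordings = load_manifest(source)
    else:
        recordings = source
    return temporal_split(recordings, ratio=ratio, rng=seed, segment_s=segment_s)


def featurize_split(
    train_set: SegmentSet,
    test_set: SegmentSet,
    feature_config: FeatureConfig = FeatureConfig(),
    seed: int | None = 0,
) -> SplitArrays:
    """Random-crop features for training, centre-crop for evaluation."""
    rng = np.random.default_rng(seed)
    X_train = extract_features(train_set.segments, feature_config, mode="random", rng=rng)
    X_test = extract_features(test_set.segments, feature_config, mode="center")
    return SplitArrays(
        X_train=X_train,
        y_train=train_set.labels,
        X_test=X_test,
        y_test=test_set.labels,
        train_set=train_set,
        test_set=test_set,
    )


def run_end_to_end(
    corpus_config: CorpusConfig,
    feature_config: FeatureConfig = FeatureConfig(),
    epochs: int = 8,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> tuple[RMAMNetClassifier, EvalReport, SplitArrays]:
    """Synthesise, split, featurise, train and evaluate in one seeded call."""
    train_set, test_set = split_corpus(corpus_config, seed=seed)
    arrays = featurize_split(train_set, test_set, feature_config, seed=seed + 1)
    clf = RMAMNetClassifier(
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        random_state=seed + 2,
    )
    clf.fit(arrays.X_train, arrays.y_train)
    report = evaluate(clf, arrays.X_test, arrays.y_test)
    return clf, report, arrays
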