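"""Population decoding of behavior from calcium event rates.

Features: the five consecutive 2-s event-rate bins of each 10-s bout, from
every imaged cell (90 bouts x (n_cells x 5) per session).  Binary freezing
decoding uses an L2-regularized linear SVM on median-split labels; 8-way
cluster decoding uses one-vs-all ECOC built from the same binary SVMs with
highest-margin aggregation.  Accuracy is estimated by repeated 10-fold
cross-validation (random partitions of the 90 bouts into folds of 9), and
significance against a null of circularly shifted label sequences — a
shuffle that preserves label autocorrelation while breaking alignment with
the neural features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .events import EventRateMatrix

log = logging.getLogger(__name__)

BINS_PER_BOUT = 5  # five 2-s bins per 10-s bout


@dataclass
class DecoderDataset:
    """Bouts x (cells x 5 bins) features with per-bout labels."""

    features: np.ndarray
    labels: np.ndarray
    mouse_id: str = "m0"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.size:
            raise ValueError("labels not aligned to feature rows")

    @property
    def n_bouts(self) -> int:
        return self.features.shape[0]


@dataclass
class DecodingResult:
    accuracy_real: float
    null_accuracies: np.ndarray
    p_one_sided: float
    n_repeats: int
    seed: int
    settings: dict = field(default_factory=dict)


def build_decoder_features(rates: EventRateMatrix) -> np.ndarray:
    """Reshape a cells x bins event-rate matrix to bouts x (cells x 5).

    Row i holds bout i's five consecutive bins for every cell, cell-major:
    [cell0 bins 5i..5i+4, cell1 bins 5i..5i+4, ...].  Requires the bin count
    to divide by 5.
    """
    n_cells, n_bins = rates.counts.shape
    if n_bins % BINS_PER_BOUT:
        raise ValueError(f"bin count {n_bins} not divisible by {BINS_PER_BOUT}")
    n_bouts = n_bins // BINS_PER_BOUT
    return (
        rates.counts.reshape(n_cells, n_bouts, BINS_PER_BOUT)
        .transpose(1, 0, 2)
        .reshape(n_bouts, n_cells * BINS_PER_BOUT)
        .astype(float)
    )


def unbuild_decoder_features(features: np.ndarray, n_cells: int) -> np.ndarray:
    """Inverse of :func:`build_decoder_features` (exact round trip)."""
    n_bouts = features.shape[0]
    return (
        features.reshape(n_bouts, n_cells, BINS_PER_BOUT)
        .transpose(1, 0, 2)
        .reshape(n_cells, n_bouts * BINS_PER_BOUT)
    )


def binarize_freezing(per_bout_freezing: np.ndarray) -> np.ndarray:
    """Median-split per-bout freezing into equal-sized binary labels.

    The lower half (by value, ties broken by stable bout order) is 0, the
    upper half 1 — exactly n/2 bouts per class for even n.  A warning is
    emitted when more than half the bouts share one value (the split is then
    mostly tie-break)."""
    fz = np.asarray(per_bout_freezing, dtype=float)
    n = fz.size
    order = np.argsort(fz, kind="stable")
    labels = np.zeros(n, dtype=np.int64)
    labels[order[n // 2 :]] = 1
    vals, counts = np.unique(fz, return_counts=True)
    if counts.max() > n / 2:
        log.warning(
            "a single freezing value covers %d of %d bouts; median split is "
            "dominated by the stable-order tie-break", int(counts.max()), n
        )
    return labels


def _make_model(model: str, seed: int, C: float):
    base = LinearSVC(C=C, random_state=seed)
    if model == "binary_svm_l2":
        return base
    if model == "ecoc_one_vs_all":
        # one-vs-all coding; prediction by the highest decision margin
        return OneVsRestClassifier(base)
    raise ValueError(f"unknown model {model!r}")


def crossval_decode(
    dataset: DecoderDataset,
    model: str = "binary_svm_l2",
    n_repeats: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    n_folds: int = 10,
) -> float:
    """Repeated random 10-fold cross-validated decoding accuracy.

    Each repeat randomly partitions the bouts into ``n_folds`` equal folds
    (9 bouts each for 90 bouts), trains on n_folds-1 folds and tests on the
    held-out fold; features are standardized per fold on training data only.
    Returns the mean test accuracy over folds and repeats.  Folds whose
    training split lacks a class present in the dataset are skipped with a
    log entry.
    """
    X, y = dataset.features, dataset.labels
    n = X.shape[0]
    if np.unique(y).size < 2:
        raise ValueError("labels must contain >= 2 classes")
    if n % n_folds:
        raise ValueError(f"{n} bouts do not split into {n_folds} equal folds")
    fold_size = n // n_folds
    rng = np.random.default_rng(seed)

    accs = []
    n_skipped = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        for f in range(n_folds):
            test = perm[f * fold_size : (f + 1) * fold_size]
            train = np.concatenate([perm[: f * fold_size], perm[(f + 1) * fold_size :]])
            if np.unique(y[train]).size < 2:
                n_skipped += 1
                continue
            scaler = StandardScaler().fit(X[train])
            clf = _make_model(model, seed, C)
            clf.fit(scaler.transform(X[train]), y[train])
            accs.append(np.mean(clf.predict(scaler.transform(X[test])) == y[test]))
    if n_skipped:
        log.info("skipped %d folds with single-class training data", n_skipped)
    if not accs:
        raise ValueError("no usable folds")
    return float(np.mean(accs))


def shuffle_null(
    dataset: DecoderDataset,
    model: str = "binary_svm_l2",
    n_shuffles: int = 1000,
    n_repeats_real: int = 1000,
    n_repeats_per_shuffle: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> DecodingResult:
    """Decoding significance against a circular-shift label null.

    Each shuffle circularly shifts the bout-label sequence by a random
    offset in [1, n_bouts - 1] (preserving label autocorrelation) and re-runs
    cross-validation with ``n_repeats_per_shuffle`` repeats.  One-sided
    p = (1 + #{null >= real}) / (n_shuffles + 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    real = crossval_decode(
        dataset, model=model, n_repeats=n_repeats_real, seed=int(rng.integers(2**31)), C=C
    )
    n = dataset.n_bouts
    null = np.empty(n_shuffles)
    for j in range(n_shuffles):
        offset = int(rng.integers(1, n))
        shifted = DecoderDataset(
            features=dataset.features,
            labels=np.roll(dataset.labels, offset),
            mouse_id=dataset.mouse_id,
        )
        null[j] = crossval_decode(
            shifted, model=model, n_repeats=n_repeats_per_shuffle,
            seed=int(rng.integers(2**31)), C=C,
        )
    p = (1.0 + np.sum(null >= real)) / (n_shuffles + 1.0)
    return DecodingResult(
        accuracy_real=real,
        null_accuracies=null,
        p_one_sided=float(p),
        n_repeats=n_repeats_real,
        seed=seed,
        settings={"model": model, "C": C, "n_shuffles": n_shuffles,
                  "n_repeats_per_shuffle": n_repeats_per_shuffle},
    )


def compare_across_mice(
    real: np.ndarray, null_means: np.ndarray
) -> dict:
    """Paired two-sided t-test of real vs mean-shuffled decoder accuracy
    across mice."""
    real = np.asarray(real, dtype=float)
    null_means = np.asarray(null_means, dtype=float)
    if real.shape != null_means.shape:
        raise ValueError("real and null accuracy vectors must align")
    deltas = real - null_means
    if real.size < 2:
        return {"t": np.nan, "p": None, "deltas": deltas,
                "message": "single mouse: report per-mouse p only"}
    if np.allclose(deltas, 0):
        return {"t": 0.0, "p": 1.0, "deltas": deltas}
    t, p = sps.ttest_rel(real, null_means)
    return {"t": float(t), "p": float(p), "deltas": deltas}
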