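"""Case-resampling cross-validation of the MPLS-DA classifier.

Each run draws a training multiset of 5 fresh and 5 warm-ischemic batches
*with replacement*, capped at 2 occurrences of any one batch within a
training set; every batch never drawn for that run forms the test set.
Offline CV fits one full-trajectory model per run; online CV fits one model
per hour and classifies every test batch at every hour.  Confusion counts
are pooled over runs (and reported per hour for online CV), yielding
sensitivity — WI batches called WI — and specificity — fresh batches called
fresh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FRESH, WI, BatchDataset
from .exceptions import ModelError, ValidationError
from .plsda import fit_hourly_models, fit_mpls, online_predict

# confusion component order used throughout: (wi_as_wi, wi_as_fresh,
# fresh_as_wi, fresh_as_fresh)
_COMPONENTS = ("wi_as_wi", "wi_as_fresh", "fresh_as_wi", "fresh_as_fresh")


@dataclass
class CVSplit:
    """One resampling draw: a 5+5 training multiset and its test set."""

    run_id: int
    train_indices: list[int]      # with multiplicity
    test_indices: list[int]       # batches never drawn into training
    selection_counts: dict[int, int]


def resample_split(dataset: BatchDataset, rng: np.random.Generator,
                   per_class: int = 5, cap: int = 2, run_id: int = 0,
                   replace: bool = True) -> CVSplit:
    """Draw one case-resampling split.

    With ``replace=True`` (default) each class's training draw is with
    replacement but no batch may appear more than ``cap`` times in one
    training set; ``replace=False`` gives plain without-replacement draws.
    """
    train: list[int] = []
    counts: dict[int, int] = {}
    for label in (FRESH, WI):
        members = dataset.label_indices(label)
        limit = len(members) * (cap if replace else 1)
        if limit < per_class:
            raise ValidationError(
                f"cannot draw {per_class} training batches of class {label!r} "
                f"from {len(members)} batches with cap {cap}")
        for _ in range(per_class):
            avail = [int(i) for i in members if counts.get(int(i), 0) < (cap if replace else 1)]
            pick = int(rng.choice(avail))
            counts[pick] = counts.get(pick, 0) + 1
            train.append(pick)
    drawn = set(train)
    test = [i for i in range(dataset.n_batches) if i not in drawn
            and dataset.labels[i] in (FRESH, WI)]
    return CVSplit(run_id, train, test, counts)


@dataclass
class ConfusionCounts:
    """Per-hour and pooled 2x2 confusion counts."""

    per_hour: np.ndarray  # (K, 4) in _COMPONENTS order; offline: (1, 4)

    @property
    def pooled(self) -> np.ndarray:
        return self.per_hour.sum(axis=0)

    @staticmethod
    def _metric(counts: np.ndarray, num: int, den2: int) -> float:
        denom = counts[num] + counts[den2]
        return float(counts[num] / denom) if denom else float("nan")

    def sensitivity(self, hour: int | None = None) -> float:
        c = self.pooled if hour is None else self.per_hour[hour - 1]
        return self._metric(c, 0, 1)  # wi_as_wi / (wi_as_wi + wi_as_fresh)

    def specificity(self, hour: int | None = None) -> float:
        c = self.pooled if hour is None else self.per_hour[hour - 1]
        return self._metric(c, 3, 2)

    def accuracy(self, hour: int | None = None) -> float:
        c = self.pooled if hour is None else self.per_hour[hour - 1]
        total = c.sum()
        return float((c[0] + c[3]) / total) if total else float("nan")


@dataclass
class CVResult:
    """Outcome of a case-resampling CV study."""

    mode: str                    # "offline" | "online"
    runs: int                    # completed runs
    requested_runs: int
    confusion: ConfusionCounts
    splits: list[CVSplit]
    seed: int
    n_time: int
    skipped_runs: list[int] = field(default_factory=list)
    failed_runs: list[tuple[int, str]] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity()

    @property
    def specificity(self) -> float:
        return self.confusion.specificity()

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy()

    def per_hour_frame(self) -> pd.DataFrame:
        hours = range(1, self.confusion.per_hour.shape[0] + 1)
        return pd.DataFrame({
            "time_hr": list(hours),
            "sensitivity": [self.confusion.sensitivity(h) for h in hours],
            "specificity": [self.confusion.specificity(h) for h in hours],
            "accuracy": [self.confusion.accuracy(h) for h in hours],
        })


def run_cv(dataset: BatchDataset, runs: int = 100, R: int = 3,
           mode: str = "offline", seed: int = 0, per_class: int = 5,
           cap: int = 2, strategy: str = "truncated_refit") -> CVResult:
    """Run the case-resampling CV study.  Deterministic given ``seed``.

    Failed fits are recorded per run (without aborting the study); runs with
    an empty test set are skipped with a warning.
    """
    if runs < 1:
        raise ValidationError("runs must be >= 1")
    if mode not in ("offline", "online"):
        raise ValidationError(f"unknown CV mode {mode!r}")
    rng = np.random.default_rng(seed)
    K = dataset.n_time
    n_hours = K if mode == "online" else 1
    counts = np.zeros((n_hours, 4), dtype=int)
    splits: list[CVSplit] = []
    skipped: list[int] = []
    failed: list[tuple[int, str]] = []
    completed = 0

    for run in range(runs):
        split = resample_split(dataset, rng, per_class=per_class, cap=cap, run_id=run)
        splits.append(split)
        if not split.test_indices:
            warnings.warn(f"run {run}: empty test set, skipped")
            skipped.append(run)
            continue
        train = dataset.subset(split.train_indices, allow_duplicates=True)
        try:
            if mode == "offline":
                model = fit_mpls(train, R=R)
                for i in split.test_indices:
                    est = model.predict(dataset.values[i])
                    counts[0] += _confusion_row(dataset.labels[i], est.predicted_class)
            else:
                models = fit_hourly_models(train, R=R)
                for i in split.test_indices:
                    for k in range(1, K + 1):
                        est = online_predict(models, dataset.values[i][:, :k], k,
                                             strategy=strategy)
                        counts[k - 1] += _confusion_row(dataset.labels[i], est.predicted_class)
        except ModelError as exc:
            failed.append((run, str(exc)))
            continue
        completed += 1

    return CVResult(mode, completed, runs, ConfusionCounts(counts), splits,
                    seed, K, skipped, failed)


def _confusion_row(actual: str, predicted: str) -> np.ndarray:
    row = np.zeros(4, dtype=int)
    if actual == WI:
        row[0 if predicted == WI else 1] = 1
    else:
        row[2 if predicted == WI else 3] = 1
    return row


def summarize(result: CVResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy summary tables: a pooled 2x2 confusion table and an
    hour-by-metric table (one row for offline CV)."""
    if result.confusion.per_hour.sum() == 0:
        warnings.warn("empty CV result: no test predictions were made")
        return (pd.DataFrame(columns=["", "WI (actual)", "Fresh (actual)"]),
                pd.DataFrame(columns=["time_hr", "sensitivity", "specificity", "accuracy"]))
    c = result.confusion.pooled
    confusion = pd.DataFrame({
        "": ["Classified as WI", "Classified as Fresh"],
        "WI (actual)": [c[0], c[1]],
        "Fresh (actual)": [c[2], c[3]],
    })
    return confusion, result.per_hour_frame()
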