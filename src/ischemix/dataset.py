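"""In-memory containers for dynamic perfusion-batch data.

A *batch* is one complete perfusion experiment: a (metabolites x hours)
concentration trajectory for one liver.  A :class:`BatchDataset` stacks I
batches into a 3-D array of shape (I, J, K) — batches x metabolites x hourly
time points — together with per-batch class labels (``"fresh"``, ``"wi"`` for
warm-ischemic, or ``"unknown"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .exceptions import ValidationError
from .panel import MetabolitePanel, default_panel

FRESH = "fresh"
WI = "wi"
UNKNOWN = "unknown"
LABELS = (FRESH, WI, UNKNOWN)


@dataclass(frozen=True)
class PerfusionBatch:
    """One perfusion: a (J metabolites x K hours) concentration trajectory."""

    batch_id: str
    label: str
    values: np.ndarray  # (J, K)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError("batch values must be a 2-D (metabolites x hours) array")
        object.__setattr__(self, "values", v)
        if self.label not in LABELS:
            raise ValidationError(f"label {self.label!r} not in {LABELS}")


@dataclass
class BatchDataset:
    """I perfusion batches over a shared metabolite panel and time grid."""

    panel: MetabolitePanel = field(default_factory=default_panel)
    values: np.ndarray = None  # (I, J, K)
    batch_ids: list[str] = None
    labels: list[str] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("dataset values must have shape (batches, metabolites, hours)")
        if self.values.shape[1] != len(self.panel):
            raise ValidationError(
                f"dataset has {self.values.shape[1]} metabolite rows but panel has {len(self.panel)}"
            )
        if self.batch_ids is None:
            self.batch_ids = [f"B{i + 1:02d}" for i in range(self.values.shape[0])]
        self.batch_ids = [str(b) for b in self.batch_ids]
        if self.labels is None:
            self.labels = [UNKNOWN] * self.values.shape[0]
        self.labels = [str(l) for l in self.labels]
        if len(self.batch_ids) != self.values.shape[0] or len(self.labels) != self.values.shape[0]:
            raise ValidationError("batch_ids/labels length must match the batch dimension")
        if len(set(self.batch_ids)) != len(self.batch_ids):
            raise ValidationError("batch_ids must be unique")
        for lab in self.labels:
            if lab not in LABELS:
                raise ValidationError(f"label {lab!r} not in {LABELS}")

    # -- shape -----------------------------------------------------------
    @property
    def n_batches(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(I, J, K): batches x metabolites x hourly time points."""
        return self.values.shape

    # -- access ----------------------------------------------------------
    def batch(self, batch_id: str) -> PerfusionBatch:
        idx = self.batch_ids.index(batch_id)
        return PerfusionBatch(batch_id, self.labels[idx], self.values[idx].copy())

    def iter_batches(self) -> Iterator[PerfusionBatch]:
        for i, bid in enumerate(self.batch_ids):
            yield PerfusionBatch(bid, self.labels[i], self.values[i].copy())

    @property
    def batches(self) -> list[PerfusionBatch]:
        return list(self.iter_batches())

    def label_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == label)

    # -- derivation ------------------------------------------------------
    def copy(self) -> "BatchDataset":
        return BatchDataset(self.panel, self.values.copy(), list(self.batch_ids), list(self.labels))

    def subset(self, indices: Sequence[int], allow_duplicates: bool = False) -> "BatchDataset":
        """Select batches by 0-based index.

        With ``allow_duplicates=True`` a batch may appear more than once
        (case-resampling training multisets); duplicated ids are suffixed
        to stay unique.
        """
        indices = list(indices)
        ids: list[str] = []
        seen: dict[str, int] = {}
        for i in indices:
            bid = self.batch_ids[i]
            if bid in seen:
                if not allow_duplicates:
                    raise ValidationError(f"duplicate batch index {i} in subset")
                seen[bid] += 1
                bid = f"{bid}#{seen[bid]}"
            else:
                seen[bid] = 1
            ids.append(bid)
        return BatchDataset(
            self.panel,
            self.values[indices].copy(),
            ids,
            [self.labels[i] for i in indices],
        )

    def select_label(self, label: str) -> "BatchDataset":
        return self.subset(self.label_indices(label))

    def truncate(self, k: int) -> "BatchDataset":
        """Keep only the first ``k`` hourly time points (online analysis)."""
        if not 1 <= k <= self.n_time:
            raise ValidationError(f"k={k} outside 1..{self.n_time}")
        return BatchDataset(self.panel, self.values[:, :, :k].copy(), list(self.batch_ids), list(self.labels))

    @staticmethod
    def concatenate(datasets: Sequence["BatchDataset"]) -> "BatchDataset":
        if not datasets:
            raise ValidationError("nothing to concatenate")
        panel = datasets[0].panel
        for d in datasets[1:]:
            if d.panel.names != panel.names:
                raise ValidationError("datasets use different panels")
            if d.n_time != datasets[0].n_time:
                raise ValidationError("datasets have different time grids")
        return BatchDataset(
            panel,
            np.concatenate([d.values for d in datasets], axis=0),
            sum((list(d.batch_ids) for d in datasets), []),
            sum((list(d.labels) for d in datasets), []),
        )

    def with_values(self, values: np.ndarray) -> "BatchDataset":
        return BatchDataset(self.panel, values, list(self.batch_ids), list(self.labels))
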