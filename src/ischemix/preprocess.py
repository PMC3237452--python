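"""Preprocessing: invalid-cell repair, column scaling, and array unfolding.

Dynamic batch data live in a 3-D array (I batches x J metabolites x K hours).
Multiway models operate on 2-D *unfoldings* of that array:

* ``batchwise`` (I x JK): each row is one batch, with the J metabolite values
  of hour 1 first, then hour 2, etc.  This is the unfolding used for batch-
  to-batch monitoring; scaling is learned per (metabolite, hour) column.
* ``variablewise`` (IK x J): rows are (batch, hour) pairs in batch-major
  order; useful for assessing batch progress.

Scaling is mean-centring and unit-variance scaling per (metabolite, hour)
column of the batchwise unfolding, learned on training batches only.  Online
(partial-trajectory) data are scaled with the leading columns of the same
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dataset import BatchDataset
from .exceptions import PreprocessError, ValidationError

Direction = Literal["batchwise", "variablewise"]


@dataclass(frozen=True)
class ScalerParams:
    """Per-(metabolite, hour) training mean and sd, each of shape (J, K).

    Columns with zero training variance get sd forced to 1 and are flagged in
    ``degenerate`` so downstream code cannot divide by zero.
    """

    means: np.ndarray
    sds: np.ndarray
    degenerate: np.ndarray  # bool (J, K)

    @property
    def shape(self) -> tuple[int, int]:
        return self.means.shape


def fit_scaler(training: BatchDataset | np.ndarray) -> ScalerParams:
    """Learn per-column mean/sd over the batch dimension (ddof=1)."""
    values = training.values if isinstance(training, BatchDataset) else np.asarray(training, float)
    if values.ndim != 3:
        raise ValidationError("expected a (batches, metabolites, hours) array")
    if values.shape[0] < 2:
        raise PreprocessError("need at least 2 training batches to estimate column sds")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    degenerate = ~(sds > 0)
    sds = np.where(degenerate, 1.0, sds)
    return ScalerParams(means, sds, degenerate)


def apply_scaler(data: BatchDataset | np.ndarray, params: ScalerParams) -> np.ndarray:
    """Scale full or partial (hours 1..k) trajectories: (x - mean) / sd.

    Accepts a dataset, a 3-D (I, J, k) stack, or a single 2-D (J, k) batch
    with k <= K; the leading k columns of the training parameters are used.
    """
    values = data.values if isinstance(data, BatchDataset) else np.asarray(data, float)
    J, K = params.shape
    k = values.shape[-1]
    if values.shape[-2] != J or k > K:
        raise ValidationError(f"data shape {values.shape} incompatible with scaler {params.shape}")
    return (values - params.means[:, :k]) / params.sds[:, :k]


def invert_scaler(scaled: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Undo :func:`apply_scaler`."""
    scaled = np.asarray(scaled, float)
    J, K = params.shape
    k = scaled.shape[-1]
    if scaled.shape[-2] != J or k > K:
        raise ValidationError(f"data shape {scaled.shape} incompatible with scaler {params.shape}")
    return scaled * params.sds[:, :k] + params.means[:, :k]


def replace_invalid(dataset: BatchDataset,
                    training_reference: BatchDataset | np.ndarray) -> tuple[BatchDataset, int]:
    """Replace negative or non-finite cells by the training mean trajectory.

    ``training_reference`` is either a fresh training dataset (its per-column
    mean trajectory is computed with invalid cells masked out) or a (J, K)
    mean-trajectory array.  Returns the repaired copy and the number of cells
    replaced.
    """
    if isinstance(training_reference, BatchDataset):
        ref_values = training_reference.values
        masked = np.where(np.isfinite(ref_values) & (ref_values >= 0), ref_values, np.nan)
        if np.isnan(masked).all(axis=0).any():
            raise PreprocessError("a reference column has no valid (finite, non-negative) values")
        reference = np.nanmean(masked, axis=0)
    else:
        reference = np.asarray(training_reference, float)
        if not np.isfinite(reference).all():
            raise PreprocessError("reference mean trajectory contains non-finite values")
    if reference.shape != dataset.values.shape[1:]:
        raise ValidationError("reference shape does not match dataset (J, K)")
    out = dataset.copy()
    invalid = ~np.isfinite(out.values) | (out.values < 0)
    out.values[invalid] = np.broadcast_to(reference, out.values.shape)[invalid]
    return out, int(invalid.sum())


@dataclass(frozen=True)
class UnfoldedData:
    """A 2-D unfolding of (I, J, K) data with its column/row bookkeeping.

    For the batchwise direction, ``column_index[c]`` gives the (metabolite j,
    hour k) pair (0-based) behind column c; the layout is hour blocks side by
    side with metabolites varying fastest (c = k*J + j).
    """

    matrix: np.ndarray
    direction: Direction
    shape3d: tuple[int, int, int]
    column_index: tuple[tuple[int, int], ...] | None = None

    def refold(self) -> np.ndarray:
        return refold(self.matrix, self.direction, self.shape3d)


def unfold(data: BatchDataset | np.ndarray, direction: Direction = "batchwise") -> UnfoldedData:
    """Unfold a 3-D batch array into 2-D."""
    values = data.values if isinstance(data, BatchDataset) else np.asarray(data, float)
    if values.ndim != 3:
        raise ValidationError("expected a (batches, metabolites, hours) array")
    I, J, K = values.shape
    if direction == "batchwise":
        matrix = values.transpose(0, 2, 1).reshape(I, K * J)
        col_index = tuple((j, k) for k in range(K) for j in range(J))
        return UnfoldedData(matrix, direction, (I, J, K), col_index)
    if direction == "variablewise":
        matrix = values.transpose(0, 2, 1).reshape(I * K, J)
        return UnfoldedData(matrix, direction, (I, J, K))
    raise ValidationError(f"unknown unfolding direction {direction!r}")


def refold(matrix: np.ndarray, direction: Direction, shape3d: tuple[int, int, int]) -> np.ndarray:
    """Invert :func:`unfold` back to a 3-D (I, J, K) array."""
    I, J, K = shape3d
    matrix = np.asarray(matrix, float)
    if direction == "batchwise":
        if matrix.shape != (I, J * K):
            raise ValidationError(f"matrix shape {matrix.shape} incompatible with {shape3d}")
        return matrix.reshape(I, K, J).transpose(0, 2, 1)
    if direction == "variablewise":
        if matrix.shape != (I * K, J):
            raise ValidationError(f"matrix shape {matrix.shape} incompatible with {shape3d}")
        return matrix.reshape(I, K, J).transpose(0, 2, 1)
    raise ValidationError(f"unknown unfolding direction {direction!r}")


def unfold_batch(values: np.ndarray) -> np.ndarray:
    """Unfold a single (J, k) trajectory into a length J*k row vector
    (hour blocks side by side, metabolites fastest)."""
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise ValidationError("expected a (metabolites, hours) array")
    return values.T.reshape(-1)
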