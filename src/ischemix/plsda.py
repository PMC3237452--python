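"""Multiway PLS discriminant analysis (MPLS-DA) of perfusion batches.

PLS regresses the batchwise-unfolded, per-column-scaled trajectory matrix X
(I x JK) onto a dummy-coded class matrix Y (I x G, here G = 2 with class
order fresh, wi): a fresh batch's Y row is [1, 0], a warm-ischemic batch's
[0, 1].  Components are extracted one at a time by NIPALS with X- and
Y-block deflation; the regression coefficients B = W (P'W)^-1 C' give the
direct prediction y_hat = x B + y_mean for a new batch.

Classification: y_hat is normalized to sum to one; its fresh-class entry is
the *quality estimate*.  The predicted class is the argmax of the normalized
vector, equivalently quality > 0.5 for fresh; an exact tie is called
warm-ischemic (an ambiguous organ is treated as injured).

Variable importance in projection (VIP) scores summarise each column's
weight across components, scaled so the mean squared VIP is 1; VIP > 1
marks variables that drive the class separation.

Online use fits one model per hour on the truncated trajectories
("truncated refit", default) or pads the unseen future hours of a scaled
partial batch with zeros under the full-length model ("zero_fill").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import FRESH, WI, BatchDataset, PerfusionBatch
from .exceptions import ConvergenceError, ModelError, ValidationError
from .panel import MetabolitePanel
from .preprocess import ScalerParams, apply_scaler, fit_scaler, unfold, unfold_batch

CLASS_ORDER = (FRESH, WI)
OnlineStrategy = Literal["truncated_refit", "zero_fill"]


@dataclass(frozen=True)
class DummyResponse:
    """Dummy-coded class membership: Y[i, g] = 1 iff batch i is of class g."""

    matrix: np.ndarray  # (I, G) of 0/1
    class_order: tuple[str, ...] = CLASS_ORDER


def encode_classes(labels: Sequence[str],
                   class_order: tuple[str, ...] = CLASS_ORDER) -> DummyResponse:
    """Encode labels as a 0/1 dummy matrix with one column per class."""
    index = {c: g for g, c in enumerate(class_order)}
    Y = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValidationError(f"label {lab!r} not in class order {class_order}")
        Y[i, index[lab]] = 1.0
    return DummyResponse(Y, class_order)


@dataclass
class QualityEstimate:
    """Predicted end-of-perfusion quality of one batch.

    ``quality`` is the normalized fresh-class score: > 0.5 means the batch
    is classified fresh, otherwise warm-ischemic (ties go to wi).
    """

    batch_id: str
    yhat: np.ndarray
    normalized_yhat: np.ndarray
    quality: float
    predicted_class: str
    class_order: tuple[str, ...] = CLASS_ORDER

    def to_row(self, hour: int | None = None) -> dict:
        return {
            "batch_id": self.batch_id,
            "time_hr": hour if hour is not None else pd.NA,
            "quality": self.quality,
            "predicted_class": self.predicted_class,
        }


@dataclass
class VIPVector:
    """VIP scores per unfolded column and aggregated per metabolite (RMS
    over that metabolite's hourly columns)."""

    panel: MetabolitePanel
    per_column: np.ndarray      # (JK,)
    per_metabolite: np.ndarray  # (J,)

    def important(self, threshold: float = 1.0) -> list[str]:
        """Metabolites whose aggregated VIP exceeds ``threshold``."""
        return [self.panel.names[j] for j in np.flatnonzero(self.per_metabolite > threshold)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metabolite": list(self.panel.names),
            "vip": self.per_metabolite,
        })


@dataclass
class MPLSDAModel:
    """Fitted MPLS-DA classifier (NIPALS PLS2 on unfolded batch data)."""

    panel: MetabolitePanel
    scaler: ScalerParams
    y_mean: np.ndarray            # (G,)
    weights: np.ndarray           # W (JK, R), unit-norm columns
    x_loadings: np.ndarray        # P (JK, R)
    y_loadings: np.ndarray        # C (G, R)
    coefficients: np.ndarray      # B (JK, G)
    x_scores: np.ndarray          # T (I, R)
    explained_x: np.ndarray       # (R,) fractions of X sum of squares
    explained_y: np.ndarray       # (R,) fractions of centred Y sum of squares
    class_order: tuple[str, ...] = CLASS_ORDER

    @property
    def R(self) -> int:
        return self.weights.shape[1]

    @property
    def n_time(self) -> int:
        return self.scaler.shape[1]

    def _x_row(self, values: np.ndarray, pad_missing: bool) -> np.ndarray:
        J, K = self.scaler.shape
        if values.shape[0] != J:
            raise ValidationError(f"batch has {values.shape[0]} metabolites, model expects {J}")
        k = values.shape[1]
        if k == K:
            return unfold_batch(apply_scaler(values, self.scaler))
        if k < K and pad_missing:
            x = np.zeros(J * K)
            x[: J * k] = unfold_batch(apply_scaler(values, self.scaler))
            return x
        raise ValidationError(
            f"batch has {k} hours, model expects {K} (use pad_missing for partial data)")

    def predict(self, batch, pad_missing: bool = False) -> QualityEstimate:
        """Quality estimate for a batch: y_hat = x B + y_mean, normalized."""
        if isinstance(batch, PerfusionBatch):
            batch_id, values = batch.batch_id, batch.values
        else:
            batch_id, values = "batch", np.asarray(batch, float)
        x = self._x_row(values, pad_missing)
        yhat = x @ self.coefficients + self.y_mean
        total = yhat.sum()
        if abs(total) < 1e-12:
            normalized = np.full_like(yhat, 1.0 / yhat.size)
        else:
            normalized = yhat / total
        quality = float(normalized[self.class_order.index(FRESH)])
        predicted = FRESH if quality > 0.5 else WI  # tie -> wi (conservative)
        return QualityEstimate(batch_id, yhat, normalized, quality, predicted, self.class_order)


def fit_mpls(dataset: BatchDataset, labels: Sequence[str] | None = None, R: int = 3,
             max_iter: int = 500, tol: float = 1e-10) -> MPLSDAModel:
    """Fit an R-component MPLS-DA model by NIPALS with deflation.

    X is the batchwise unfolding of the per-column scaled trajectories; Y is
    the mean-centred dummy class matrix.  Each component iterates the NIPALS
    outer relations until the weight vector moves by less than ``tol``
    (non-convergence raises, naming the component).  Weight signs are fixed
    (largest-magnitude entry positive) for reproducibility.
    """
    labels = list(dataset.labels) if labels is None else list(labels)
    if len(labels) != dataset.n_batches:
        raise ValidationError("labels length must match dataset")
    present = set(labels)
    if not present.issubset(set(CLASS_ORDER)):
        raise ValidationError(f"labels {present} not drawn from {CLASS_ORDER}")
    if len(present) < 2:
        raise ModelError("MPLS-DA needs batches from both classes")
    for c in CLASS_ORDER:
        if labels.count(c) < 2:
            raise ModelError(f"need at least 2 batches of class {c!r}")
    if R < 1:
        raise ModelError("R must be >= 1")

    scaler = fit_scaler(dataset)
    X0 = unfold(apply_scaler(dataset, scaler)).matrix
    Y = encode_classes(labels).matrix
    y_mean = Y.mean(axis=0)
    Y0 = Y - y_mean

    I, JK = X0.shape
    G = Y0.shape[1]
    ss_x0 = (X0 ** 2).sum()
    ss_y0 = (Y0 ** 2).sum()
    if ss_x0 <= 0:
        raise ModelError("X carries no variance after scaling")

    Xr, Yr = X0.copy(), Y0.copy()
    W = np.zeros((JK, R))
    P = np.zeros((JK, R))
    C = np.zeros((G, R))
    T = np.zeros((I, R))
    expl_x = np.zeros(R)
    expl_y = np.zeros(R)

    for r in range(R):
        ss_yr = (Yr ** 2).sum()
        if ss_yr > 1e-24 * max(ss_y0, 1.0):
            u = Yr[:, int(np.argmax((Yr ** 2).sum(axis=0)))].copy()
            w = np.zeros(JK)
            converged = False
            for _ in range(max_iter):
                w_new = Xr.T @ u / (u @ u)
                norm = np.linalg.norm(w_new)
                if norm <= 0:
                    raise ConvergenceError(
                        f"zero weight vector at component {r + 1}", component=r + 1)
                w_new /= norm
                t = Xr @ w_new
                tt = t @ t
                if tt <= 0:
                    raise ConvergenceError(
                        f"zero score vector at component {r + 1}", component=r + 1)
                c = Yr.T @ t / tt
                cc = c @ c
                if cc > 0:
                    u = Yr @ c / cc
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    converged = True
                    break
                w = w_new
            if not converged:
                raise ConvergenceError(
                    f"NIPALS did not converge within {max_iter} iterations "
                    f"at component {r + 1}", component=r + 1)
        else:
            # Y block fully explained: remaining components span leftover X
            # variance (c ~ 0); take the dominant right singular direction.
            _, _, Vt = np.linalg.svd(Xr, full_matrices=False)
            w = Vt[0]
        # sign convention for reproducibility
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = Xr @ w
        tt = t @ t
        if tt <= 0:
            raise ModelError(f"X deflated to zero before reaching R={R} components")
        p = Xr.T @ t / tt
        c = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, c)
        W[:, r], P[:, r], C[:, r], T[:, r] = w, p, c, t
        expl_x[r] = tt * (p @ p) / ss_x0
        expl_y[r] = tt * (c @ c) / ss_y0 if ss_y0 > 0 else 0.0

    B = W @ np.linalg.solve(P.T @ W, C.T)
    return MPLSDAModel(
        panel=dataset.panel,
        scaler=scaler,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=C,
        coefficients=B,
        x_scores=T,
        explained_x=expl_x,
        explained_y=expl_y,
    )


def predict_quality(model: MPLSDAModel, batch) -> QualityEstimate:
    """Functional alias for :meth:`MPLSDAModel.predict`."""
    return model.predict(batch)


def vip(model: MPLSDAModel) -> VIPVector:
    """Variable importance in projection.

    VIP_col = sqrt( JK * sum_r SS_Y(r) w_col,r^2 / sum_r SS_Y(r) ) with
    SS_Y(r) the Y sum of squares explained by component r and w the
    unit-norm NIPALS weights; mean squared column VIP is 1 by construction.
    Per-metabolite scores are the RMS over that metabolite's hourly columns.
    """
    JK = model.weights.shape[0]
    ss = model.explained_y.copy()
    if ss.sum() <= 0:
        ss = np.ones_like(ss)  # null response: weight components equally
    vip_sq = JK * (model.weights ** 2) @ ss / ss.sum()
    per_column = np.sqrt(vip_sq)
    J, K = model.scaler.shape
    per_metab = np.sqrt(vip_sq.reshape(K, J).T.mean(axis=1))
    return VIPVector(model.panel, per_column, per_metab)


def fit_hourly_models(dataset: BatchDataset, labels: Sequence[str] | None = None,
                      R: int = 3, **kwargs) -> dict[int, MPLSDAModel]:
    """One MPLS-DA model per hour k, fit on the trajectories up to hour k."""
    return {
        k: fit_mpls(dataset.truncate(k), labels, R=R, **kwargs)
        for k in range(1, dataset.n_time + 1)
    }


def online_predict(models_by_hour: Mapping[int, MPLSDAModel] | MPLSDAModel,
                   partial, k: int,
                   strategy: OnlineStrategy = "truncated_refit") -> QualityEstimate:
    """Hour-k quality prediction from a partial trajectory (hours 1..k).

    ``truncated_refit`` (default) uses the model fit on hours 1..k of the
    training data; ``zero_fill`` scales the partial batch with the
    full-length model and treats the unseen hours as zero deviation from
    the training mean.
    """
    if isinstance(partial, PerfusionBatch):
        values = partial.values
        batch = partial
    else:
        values = np.asarray(partial, float)
        batch = values
    if values.shape[1] < k:
        raise ValidationError(f"partial batch lacks hours 1..{k}")
    values = values[:, :k]
    if strategy == "truncated_refit":
        if isinstance(models_by_hour, MPLSDAModel):
            models_by_hour = {models_by_hour.n_time: models_by_hour}
        if k not in models_by_hour:
            raise ModelError(f"no hour-{k} model available for truncated refit")
        model = models_by_hour[k]
        if isinstance(batch, PerfusionBatch):
            return model.predict(PerfusionBatch(batch.batch_id, batch.label, values))
        return model.predict(values)
    if strategy == "zero_fill":
        model = models_by_hour if isinstance(models_by_hour, MPLSDAModel) \
            else models_by_hour[max(models_by_hour)]
        est = model.predict(values, pad_missing=values.shape[1] < model.n_time)
        if isinstance(batch, PerfusionBatch):
            est.batch_id = batch.batch_id
        return est
    raise ValidationError(f"unknown online strategy {strategy!r}")
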