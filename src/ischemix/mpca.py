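"""Multiway PCA monitoring of perfusion batches: the fresh-liver normal-
operation model, SPE control statistics, the log-SPE ischemia index,
contribution diagnostics, and score-space outlier screening.

The model is ordinary PCA on the batchwise-unfolded (I x JK), per-column
scaled training matrix of fresh perfusions: X = T P' + E with orthonormal
loadings P (JK x R).  A new batch is scaled with the *training* scaler,
projected onto P, and judged by its squared prediction error

    SPE = ||e||^2,   e = x (I - P P'),

the squared distance off the model plane.  A large SPE means the batch
carries a correlation structure the fresh model does not explain — for a
perfused liver, evidence of ischemic injury.  Control limits use the
classic scaled-chi-square approximation g*chi2_h matched to the mean and
variance of the training SPE sample; log10(SPE) is reported as a continuous
ischemia index with a heuristic alarm threshold of 1.35.

Online (during perfusion), scores at hour k are the least-squares solution
on the leading J*k loading rows ("missing future data" projection) and
SPE_k is, by default, the residual sum over the J metabolites of hour k
alone, each hour with its own chi-square limit.

Contribution analysis decomposes SPE into per-(metabolite, hour) terms
e_jk^2 (non-negative, summing to SPE) alongside the signed normalized
errors e_jk / s_jk, and flags the metabolites whose contributions leave the
+/-3 sigma band of normal (fresh-liver) contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import BatchDataset, PerfusionBatch
from .exceptions import DegenerateDataError, ModelError, ValidationError
from .panel import MetabolitePanel
from .preprocess import ScalerParams, apply_scaler, fit_scaler, unfold, unfold_batch

OnlineMode = Literal["instantaneous", "cumulative"]

#: Default heuristic alarm threshold on the log10(SPE) ischemia index.
INDEX_THRESHOLD = 1.35
DEFAULT_ALPHAS = (0.05, 0.01)


def spe_limit(spe_sample: np.ndarray, alpha: float) -> float:
    """SPE control limit from a normal-operation SPE sample.

    Uses the scaled-chi-square (Box) approximation ``g * chi2_h`` with
    ``g = v / (2 m)`` and ``h = 2 m^2 / v`` matched to the sample mean ``m``
    and variance ``v``; the limit is the 1-alpha quantile.
    """
    sample = np.asarray(spe_sample, float)
    if sample.size < 3:
        raise DegenerateDataError("need at least 3 SPE values to set a limit")
    m = sample.mean()
    v = sample.var(ddof=1)
    if v <= 0 or m <= 0:
        raise DegenerateDataError("SPE sample has zero mean or variance; limit undefined")
    g = v / (2.0 * m)
    h = 2.0 * m * m / v
    return float(g * stats.chi2.ppf(1.0 - alpha, h))


@dataclass
class SPETrace:
    """SPE statistic(s) for one batch, offline (scalar) or online (per hour).

    ``flags`` marks entries above the stricter stored control limit
    (smallest alpha, i.e. the 99% limit by default); ``index_flag`` marks
    log-index values above the heuristic ischemia threshold.
    """

    batch_id: str
    mode: str  # "offline" | "instantaneous" | "cumulative"
    spe: np.ndarray  # () or (K,)
    limits: dict[float, np.ndarray]
    log_base: float = 10.0
    index_threshold: float = INDEX_THRESHOLD

    def __post_init__(self):
        self.spe = np.asarray(self.spe, float)
        if np.any(self.spe < -1e-12):
            raise ValidationError("SPE values must be non-negative")
        self.spe = np.maximum(self.spe, 0.0)

    @property
    def log_index(self) -> np.ndarray:
        """log(SPE) ischemia index (base ``log_base``; -inf for SPE = 0)."""
        with np.errstate(divide="ignore"):
            return np.log(self.spe) / np.log(self.log_base)

    @property
    def flags(self) -> np.ndarray:
        alpha = min(self.limits)
        return self.spe > self.limits[alpha]

    @property
    def index_flag(self) -> np.ndarray:
        return self.log_index > self.index_threshold

    def to_frame(self) -> pd.DataFrame:
        spe = np.atleast_1d(self.spe)
        offline = self.mode == "offline"
        rows = []
        for i in range(spe.size):
            row = {
                "batch_id": self.batch_id,
                "mode": self.mode,
                "time_hr": pd.NA if offline else i + 1,
                "spe": spe[i],
                "log_index": np.atleast_1d(self.log_index)[i],
                "index_flag": bool(np.atleast_1d(self.index_flag)[i]),
            }
            for alpha, lim in sorted(self.limits.items()):
                row[f"limit_{int(round((1 - alpha) * 100))}"] = np.atleast_1d(lim)[min(i, np.atleast_1d(lim).size - 1)]
            row["above_99"] = bool(np.atleast_1d(self.flags)[i])
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ContributionTable:
    """Per-(metabolite, hour) decomposition of a batch's residual.

    ``squared`` holds the non-negative SPE contributions e_jk^2 (summing to
    the offline SPE); ``normalized`` the signed normalized errors e_jk/s_jk
    (positive: concentration above the fresh model's expectation).
    """

    batch_id: str
    panel: MetabolitePanel
    squared: np.ndarray   # (J, K)
    normalized: np.ndarray  # (J, K)

    def spe(self) -> float:
        return float(self.squared.sum())

    def to_frame(self) -> pd.DataFrame:
        J, K = self.squared.shape
        j, k = np.meshgrid(np.arange(J), np.arange(K), indexing="ij")
        return pd.DataFrame({
            "batch_id": self.batch_id,
            "metabolite": [self.panel.names[x] for x in j.ravel()],
            "time_hr": k.ravel() + 1,
            "squared_contribution": self.squared.ravel(),
            "normalized_error": self.normalized.ravel(),
        })


@dataclass
class ContributorFlags:
    """Outcome of the 3-sigma contributor screen: which metabolites deviate
    from normal (fresh) contributions, per hour."""

    panel: MetabolitePanel
    mask: np.ndarray  # bool (J, K)
    n_sigma: float
    statistic: str

    def by_hour(self) -> dict[int, list[str]]:
        J, K = self.mask.shape
        return {
            k + 1: [self.panel.names[j] for j in np.flatnonzero(self.mask[:, k])]
            for k in range(K)
        }

    def flagged_at(self, hour: int) -> list[str]:
        return self.by_hour()[hour]

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


def flag_contributors(table: ContributionTable,
                      reference: "np.ndarray | Sequence[ContributionTable]",
                      n_sigma: float = 3.0,
                      statistic: Literal["normalized", "squared"] = "normalized",
                      ) -> ContributorFlags:
    """Flag metabolite-hours whose contribution leaves the normal band.

    ``reference`` is a stack (N, J, K) of the corresponding statistic for
    fresh-liver batches (or a sequence of their ContributionTables).  With
    the default signed ``normalized`` statistic a cell is flagged when it
    falls outside mean +/- n_sigma * sd of the fresh reference; with
    ``squared`` when it exceeds mean + n_sigma * sd.
    """
    if not isinstance(reference, np.ndarray):
        tables = list(reference)
        if not tables:
            raise ValidationError("empty fresh reference")
        reference = np.stack([
            t.normalized if statistic == "normalized" else t.squared for t in tables
        ])
    if reference.ndim != 3 or reference.shape[0] < 3:
        raise ValidationError("reference must stack at least 3 fresh batches")
    mu = reference.mean(axis=0)
    sd = reference.std(axis=0, ddof=1)
    if statistic == "normalized":
        mask = np.abs(table.normalized - mu) > n_sigma * sd
    elif statistic == "squared":
        mask = table.squared > mu + n_sigma * sd
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    return ContributorFlags(table.panel, mask, n_sigma, statistic)


@dataclass(frozen=True)
class EllipseSpec:
    """Hotelling confidence ellipse for a pair of score axes (centred at 0)."""

    pc_pair: tuple[int, int]
    score_sds: tuple[float, float]
    crit: dict[float, float]  # alpha -> T^2 critical value

    def semi_axes(self, alpha: float) -> tuple[float, float]:
        c = np.sqrt(self.crit[alpha])
        return (self.score_sds[0] * c, self.score_sds[1] * c)

    def t2(self, point: Sequence[float]) -> float:
        return float((point[0] / self.score_sds[0]) ** 2 + (point[1] / self.score_sds[1]) ** 2)

    def contains(self, point: Sequence[float], alpha: float) -> bool:
        return self.t2(point) <= self.crit[alpha]


@dataclass
class MPCAModel:
    """The fresh-liver ("normal operation") multiway PCA model.

    Holds everything needed to judge a new perfusion: the training scaler,
    orthonormal loadings, training scores, per-component explained variance,
    the training SPE samples (offline and per-hour online, both modes) and
    their chi-square control limits.
    """

    panel: MetabolitePanel
    scaler: ScalerParams
    loadings: np.ndarray           # (JK, R), orthonormal columns
    scores: np.ndarray             # (I_train, R)
    singular_values: np.ndarray
    explained_variance: np.ndarray  # (R,) fractions, non-increasing
    spe_train_offline: np.ndarray   # (I_train,)
    spe_train_online: dict[str, np.ndarray]  # mode -> (I_train, K)
    limits_offline: dict[float, float]
    limits_online: dict[str, dict[float, np.ndarray]]  # mode -> alpha -> (K,)
    training_normalized: np.ndarray  # (I_train, J, K) signed residual reference
    training_squared: np.ndarray     # (I_train, J, K)
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    log_base: float = 10.0
    index_threshold: float = INDEX_THRESHOLD

    @property
    def R(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_time(self) -> int:
        return self.scaler.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.scaler.shape[0]

    # ------------------------------------------------------------------
    def _as_values(self, batch) -> tuple[str, np.ndarray]:
        if isinstance(batch, PerfusionBatch):
            return batch.batch_id, batch.values
        return "batch", np.asarray(batch, float)

    def project(self, batch) -> tuple[np.ndarray, np.ndarray]:
        """Scores and residuals of a full-length batch: t = x P, e = x - t P'."""
        _, values = self._as_values(batch)
        if values.shape != self.scaler.shape:
            raise ValidationError(f"batch shape {values.shape} != model shape {self.scaler.shape}")
        x = unfold_batch(apply_scaler(values, self.scaler))
        t = x @ self.loadings
        e = x - t @ self.loadings.T
        return t, e

    def spe_offline(self, batch) -> SPETrace:
        """End-of-perfusion SPE over all JK entries, with offline limits."""
        batch_id, _ = self._as_values(batch)
        _, e = self.project(batch)
        spe = float(e @ e)
        return SPETrace(batch_id, "offline", np.asarray(spe),
                        {a: np.asarray(l) for a, l in self.limits_offline.items()},
                        self.log_base, self.index_threshold)

    def online_scores(self, partial, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Scores at hour k from the partial trajectory (hours 1..k).

        Least-squares solution on the leading J*k loading rows; returns
        (scores, residuals for hours 1..k).
        """
        _, values = self._as_values(partial)
        J = self.n_metabolites
        if k is None:
            k = values.shape[1]
        if not 1 <= k <= self.n_time:
            raise ValidationError(f"k={k} outside 1..{self.n_time}")
        if values.shape[0] != J or values.shape[1] < k:
            raise ValidationError(f"partial batch shape {values.shape} lacks hours 1..{k}")
        x = unfold_batch(apply_scaler(values[:, :k], self.scaler))
        Pk = self.loadings[: J * k]
        t, *_ = np.linalg.lstsq(Pk, x, rcond=None)
        e = x - Pk @ t
        return t, e

    def spe_online(self, partial, k: int | None = None,
                   mode: OnlineMode = "instantaneous") -> SPETrace:
        """SPE_k at hour k: residual sum over hour k alone (default) or over
        hours 1..k (``cumulative``), with the hour-k chi-square limit."""
        batch_id, values = self._as_values(partial)
        if k is None:
            k = values.shape[1]
        _, e = self.online_scores(values, k)
        J = self.n_metabolites
        ek = e[J * (k - 1): J * k] if mode == "instantaneous" else e
        spe = float(ek @ ek)
        limits = {a: np.asarray(lims[k - 1]) for a, lims in self.limits_online[mode].items()}
        return SPETrace(batch_id, mode, np.asarray(spe), limits,
                        self.log_base, self.index_threshold)

    def online_trace(self, batch, mode: OnlineMode = "instantaneous") -> SPETrace:
        """Full per-hour SPE_k trajectory, each hour using only data to date."""
        batch_id, values = self._as_values(batch)
        K = self.n_time
        spe = np.array([self.spe_online(values[:, :k], k, mode).spe for k in range(1, K + 1)])
        limits = {a: np.asarray(lims) for a, lims in self.limits_online[mode].items()}
        return SPETrace(batch_id, mode, spe, limits, self.log_base, self.index_threshold)

    def contributions(self, batch) -> ContributionTable:
        """Per-(metabolite, hour) SPE contributions and normalized errors."""
        batch_id, _ = self._as_values(batch)
        _, e = self.project(batch)
        J, K = self.scaler.shape
        normalized = e.reshape(K, J).T  # residual of scaled data == e_jk / s_jk
        return ContributionTable(batch_id, self.panel, normalized ** 2, normalized.copy())

    def training_reference(self, statistic: str = "normalized") -> np.ndarray:
        """Stack of fresh-training contribution statistics, shape (I, J, K)."""
        return self.training_normalized if statistic == "normalized" else self.training_squared

    def score_ellipse(self, pc_pair: tuple[int, int] = (0, 1),
                      alphas: Sequence[float] | None = None) -> EllipseSpec:
        """Hotelling confidence ellipse for two score axes (F-based limit)."""
        if self.R < 2:
            raise ModelError("score ellipse needs a model with R >= 2 components")
        a, b = pc_pair
        I = self.scores.shape[0]
        if I < 4:
            raise ModelError("score ellipse needs at least 4 training batches")
        sds = (self.scores[:, a].std(ddof=1), self.scores[:, b].std(ddof=1))
        if min(sds) <= 0:
            raise DegenerateDataError("zero score variance; ellipse undefined")
        alphas = tuple(alphas) if alphas is not None else self.alphas
        crit = {
            alpha: float(2.0 * (I - 1) / (I - 2) * stats.f.ppf(1 - alpha, 2, I - 2))
            for alpha in alphas
        }
        return EllipseSpec((a, b), sds, crit)


def _loo_spe_samples(values: np.ndarray, R: int,
                     J: int, K: int) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Leave-one-out SPE samples over training batches.

    For each batch, the scaler and loadings are refit on the other batches
    and the held-out batch's offline and per-hour online SPE are computed.
    This removes the optimistic bias of in-sample residuals, so chi-square
    limits built from these samples are calibrated for genuinely new
    batches.  If a fold's reduced training set cannot support R components,
    the fold uses its maximal rank.
    """
    I = values.shape[0]
    offline = np.empty(I)
    online = {"instantaneous": np.empty((I, K)), "cumulative": np.empty((I, K))}
    residuals = np.empty((I, J, K))
    idx = np.arange(I)
    for i in range(I):
        rest = values[idx != i]
        means = rest.mean(axis=0)
        sds = rest.std(axis=0, ddof=1)
        sds = np.where(sds > 0, sds, 1.0)
        Xr = ((rest - means) / sds).transpose(0, 2, 1).reshape(I - 1, K * J)
        _, s, Vt = np.linalg.svd(Xr, full_matrices=False)
        tol = max(Xr.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        r_i = min(R, int((s > tol).sum()))
        P_i = Vt[:r_i].T
        x = (((values[i] - means) / sds).T).reshape(-1)
        e = x - P_i @ (P_i.T @ x)
        offline[i] = e @ e
        residuals[i] = e.reshape(K, J).T
        for k in range(1, K + 1):
            Pk = P_i[: J * k]
            xk = x[: J * k]
            t, *_ = np.linalg.lstsq(Pk, xk, rcond=None)
            ek = xk - Pk @ t
            online["instantaneous"][i, k - 1] = ek[J * (k - 1):] @ ek[J * (k - 1):]
            online["cumulative"][i, k - 1] = ek @ ek
    return offline, online, residuals


def fit_mpca(training: BatchDataset, R: int = 3,
             alphas: Sequence[float] = DEFAULT_ALPHAS,
             log_base: float = 10.0,
             index_threshold: float = INDEX_THRESHOLD) -> MPCAModel:
    """Fit the normal-operation MPCA model on training batches.

    Scales per (metabolite, hour) column, unfolds batchwise, and takes the
    top R right singular directions of the scaled matrix.  Loading signs are
    fixed (largest-magnitude entry positive) for reproducibility.  Training
    SPE samples (offline, and online per hour in both modes) and their
    chi-square limits are computed here; limits use leave-one-out SPE
    samples (see :func:`_loo_spe_samples`) and need at least 4 training
    batches — with fewer, limits are infinite and flags never raise.
    """
    if training.n_batches < 2:
        raise ModelError("need at least 2 training batches")
    if R < 1:
        raise ModelError("R must be >= 1")
    scaler = fit_scaler(training)
    X = unfold(apply_scaler(training, scaler)).matrix  # (I, JK)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank == 0:
        raise DegenerateDataError("training batches are identical: no variance to model")
    if R > rank:
        raise ModelError(f"R={R} exceeds the rank ({rank}) of the scaled training matrix")
    P = Vt[:R].T.copy()
    # sign convention: largest-|.| entry of each loading column positive
    for r in range(R):
        if P[np.argmax(np.abs(P[:, r])), r] < 0:
            P[:, r] = -P[:, r]
    T = X @ P
    explained = (s[:R] ** 2) / (s ** 2).sum()

    E = X - T @ P.T
    spe_offline_train = (E ** 2).sum(axis=1)
    I, JK = X.shape
    J, K = scaler.shape

    spe_online_train = {"instantaneous": np.empty((I, K)), "cumulative": np.empty((I, K))}
    for k in range(1, K + 1):
        Pk = P[: J * k]
        Xk = X[:, : J * k]
        Tk, *_ = np.linalg.lstsq(Pk, Xk.T, rcond=None)
        Ek = Xk - Tk.T @ Pk.T
        spe_online_train["instantaneous"][:, k - 1] = (Ek[:, J * (k - 1):] ** 2).sum(axis=1)
        spe_online_train["cumulative"][:, k - 1] = (Ek ** 2).sum(axis=1)

    normalized = np.stack([E[i].reshape(K, J).T for i in range(I)])
    if I >= 4:
        loo_offline, loo_online, loo_resid = _loo_spe_samples(training.values, R, J, K)
        normalized = loo_resid
        limits_offline = {alpha: spe_limit(loo_offline, alpha) for alpha in alphas}
        limits_online = {
            mode: {
                alpha: np.array([spe_limit(sample[:, k], alpha) for k in range(K)])
                for alpha in alphas
            }
            for mode, sample in loo_online.items()
        }
    else:
        limits_offline = {alpha: float("inf") for alpha in alphas}
        limits_online = {
            mode: {alpha: np.full(K, np.inf) for alpha in alphas}
            for mode in spe_online_train
        }

    return MPCAModel(
        panel=training.panel,
        scaler=scaler,
        loadings=P,
        scores=T,
        singular_values=s[:R].copy(),
        explained_variance=explained,
        spe_train_offline=spe_offline_train,
        spe_train_online=spe_online_train,
        limits_offline=limits_offline,
        limits_online=limits_online,
        training_normalized=normalized,
        training_squared=normalized ** 2,
        alphas=tuple(alphas),
        log_base=log_base,
        index_threshold=index_threshold,
    )


def detect_outlier_batches(model: MPCAModel, dataset: BatchDataset,
                           alpha: float = 0.01,
                           pc_pair: tuple[int, int] = (0, 1)) -> list[str]:
    """Batches whose (t_a, t_b) score pair falls outside the Hotelling
    ellipse at ``alpha`` — candidates for exclusion before the final fit.

    Note the masking limit of a non-robust ellipse: a single extreme batch
    saturates at T^2 = (I-1)^2/I, so screens on very small datasets cannot
    flag it; with the study-sized screens (I >= ~16) this is not binding.
    """
    ellipse = model.score_ellipse(pc_pair, alphas=(alpha,))
    out = []
    for b in dataset.iter_batches():
        t, _ = model.project(b)
        if not ellipse.contains((t[pc_pair[0]], t[pc_pair[1]]), alpha):
            out.append(b.batch_id)
    return out
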