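"""Synthetic generator of fresh and warm-ischemic perfusion metabolite trajectories.

The generator emulates the statistical structure that the monitoring and
classification stages assume about normothermic liver perfusion data:

* **fresh livers** follow near-linear mean trajectories over the K hourly
  samples (stable perfusion), with batch-to-batch variation produced by a
  small number of latent metabolic factors shared across all
  (metabolite, hour) columns — this is what makes metabolites auto- and
  cross-correlated in time and gives the data a low-rank covariance;
* **warm-ischemic (WI) livers** are fresh-style batches plus an additive
  injury signature on a handful of metabolites, expressed in units of the
  fresh per-column standard deviation so the class separation is scale-free.

The default injury signature encodes the qualitative injury phenotype of a
liver that spent ~1 h warm-ischemic before perfusion: depressed albumin
synthesis throughout; ornithine below fresh in hour 1 then elevated from
hour 2 on; arginine consumption accelerating after hour 3 with a minimum at
hour 4; tyrosine accumulating towards the end; an early lactate surge from
anaerobic metabolism; and altered glutamate/glutamine handling.

Absolute concentration levels are arbitrary units: every downstream stage
operates on centred/scaled data, so only covariance and perturbation
structure matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dataset import FRESH, WI, BatchDataset
from .exceptions import ConfigError
from .panel import MetabolitePanel, default_panel

#: Default warm-ischemia perturbation on the key injury metabolites, per
#: hour (k = 1..6), in units of the fresh per-column standard deviation.
#: These are continuous deviation profiles; only their largest excursions
#: stand out of the +/-3 sigma normal band in contribution screens.
WI_SIGNATURE: dict[str, tuple[float, ...]] = {
    "Albumin":   (-2.0, -2.5, -3.0, -3.5, -4.0, -3.5),
    "Ornithine": (-3.0,  6.0,  5.0,  4.5,  4.5,  4.0),
    "Arginine":  (-0.5, -0.5, -2.0, -5.0, -3.0, -2.0),
    "Tyrosine":  ( 0.5,  0.5,  1.0,  1.0,  2.5,  4.0),
    "Lactate":   ( 5.0,  1.0,  3.0,  1.0,  0.5,  0.5),
    "Glutamate": ( 0.5,  1.0,  1.5,  3.0,  1.5,  4.0),
    "Glutamine": ( 3.0,  1.0,  0.5,  0.5,  0.5,  0.5),
    "Alanine":   ( 2.5,  0.5,  0.5,  0.5,  0.5,  0.5),
    "Aspartate": ( 2.5,  0.5,  0.5,  0.0,  0.0,  0.0),
}

#: Amplitude (fresh-sd units) of the smooth sub-threshold drift that warm
#: ischemia induces across the rest of the metabolic network: many small
#: correlated differences that never individually clear the 3-sigma band.
WI_BACKGROUND_AMPLITUDE = 1.7


def default_factor_loadings(n_latent: int, n_metabolites: int, n_time: int,
                            scale: float = 0.4) -> np.ndarray:
    """Smooth latent-factor loading surfaces, shape (R, J, K).

    Each factor loads on every (metabolite, hour) column through a smooth
    sinusoidal pattern with factor-specific frequency and phase, so the
    induced covariance couples metabolites with each other and with time.
    Deterministic (no RNG): the loadings are part of the study conditions.
    """
    r = np.arange(n_latent, dtype=float)[:, None, None]
    j = np.arange(n_metabolites, dtype=float)[None, :, None]
    k = np.arange(n_time, dtype=float)[None, None, :]
    phase = 2.0 * np.pi * ((r + 1.0) * j / n_metabolites + (r + 1.0) * k / max(n_time, 1))
    return scale * np.cos(phase + 0.9 * r)


def default_wi_perturbation(panel: MetabolitePanel, n_time: int = 6,
                            background: float = WI_BACKGROUND_AMPLITUDE) -> np.ndarray:
    """Default WI injury signature as a (J, K) array in fresh-column-sd units.

    Metabolites named in :data:`WI_SIGNATURE` carry the tabulated profiles;
    every other metabolite gets a smooth deterministic drift of amplitude
    ``background`` — the network-wide shadow of the injury, individually
    sub-threshold but collectively informative.
    """
    J = len(panel)
    delta = np.zeros((J, n_time))
    j_idx = np.arange(J, dtype=float)[:, None]
    k_idx = np.arange(n_time, dtype=float)[None, :]
    delta[:] = background * np.sin(2.0 * np.pi * 3.0 * j_idx / J + 0.7 * k_idx + 1.0)
    for name, profile in WI_SIGNATURE.items():
        if name not in panel:
            continue
        j = panel.index_of(name)
        take = min(n_time, len(profile))
        delta[j, :take] = profile[:take]
        delta[j, take:] = 0.0
    return delta


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic perfusion generator.

    Defaults mirror the study design after outlier removal: 10 fresh and
    6 warm-ischemic livers, 6 hourly samples of a 25-metabolite panel,
    3 latent metabolic factors.
    """

    panel: MetabolitePanel = field(default_factory=default_panel)
    n_fresh: int = 10
    n_wi: int = 6
    n_time: int = 6
    n_latent: int = 3
    baseline_intercepts: np.ndarray | None = None  # (J,), arbitrary conc. units
    baseline_slopes: np.ndarray | None = None      # (J,), drift per hour
    factor_loadings: np.ndarray | None = None      # (R, J, K)
    noise_sd: float = 0.30                         # per-column residual scale
    wi_perturbation: np.ndarray | None = None      # (J, K), fresh-sd units
    seed: int = 0

    def __post_init__(self):
        J, K, R = len(self.panel), self.n_time, self.n_latent
        if self.n_time < 1:
            raise ConfigError("n_time must be >= 1")
        if not 0 <= R <= J * K:
            raise ConfigError(f"n_latent must be in 0..{J * K}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        j = np.arange(J, dtype=float)
        if self.baseline_intercepts is None:
            # levels sit well clear of zero so that negative values are
            # genuinely impossible read-outs, not ordinary noise
            self.baseline_intercepts = 5.0 + 1.5 * np.sin(2 * np.pi * j / J + 0.5)
        if self.baseline_slopes is None:
            self.baseline_slopes = 0.3 * np.cos(2 * np.pi * j / J + 1.2)
        if self.factor_loadings is None:
            self.factor_loadings = default_factor_loadings(R, J, K)
        if self.wi_perturbation is None:
            self.wi_perturbation = default_wi_perturbation(self.panel, K)
        self.baseline_intercepts = np.asarray(self.baseline_intercepts, dtype=float)
        self.baseline_slopes = np.asarray(self.baseline_slopes, dtype=float)
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        self.wi_perturbation = np.asarray(self.wi_perturbation, dtype=float)
        if self.baseline_intercepts.shape != (J,):
            raise ConfigError(f"baseline_intercepts must have shape ({J},)")
        if self.baseline_slopes.shape != (J,):
            raise ConfigError(f"baseline_slopes must have shape ({J},)")
        if self.factor_loadings.shape != (R, J, K):
            raise ConfigError(f"factor_loadings must have shape ({R}, {J}, {K})")
        if self.wi_perturbation.shape != (J, K):
            raise ConfigError(f"wi_perturbation must have shape ({J}, {K})")

    def mean_surface(self) -> np.ndarray:
        """Fresh-liver mean trajectory surface, shape (J, K): linear in time."""
        hours = np.arange(1, self.n_time + 1, dtype=float)
        return self.baseline_intercepts[:, None] + self.baseline_slopes[:, None] * hours[None, :]

    def column_sd(self) -> np.ndarray:
        """Theoretical fresh per-(metabolite, hour) sd, shape (J, K)."""
        factor_var = (self.factor_loadings ** 2).sum(axis=0) if self.n_latent else 0.0
        return np.sqrt(factor_var + self.noise_sd ** 2)

    def with_(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)


def _draw_batches(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """n fresh-style batches: linear mean + latent factors + iid noise."""
    J, K, R = len(config.panel), config.n_time, config.n_latent
    values = np.broadcast_to(config.mean_surface(), (n, J, K)).copy()
    if R:
        scores = rng.standard_normal((n, R))
        values += np.einsum("ir,rjk->ijk", scores, config.factor_loadings)
    if config.noise_sd > 0:
        values += config.noise_sd * rng.standard_normal((n, J, K))
    return values


def generate_fresh(config: GeneratorConfig, n: int | None = None,
                   id_prefix: str = "F") -> BatchDataset:
    """Generate fresh-liver batches.  Deterministic given ``config.seed``."""
    n = config.n_fresh if n is None else n
    if n < 1:
        raise ConfigError("need at least one batch")
    rng = np.random.default_rng(config.seed)
    values = _draw_batches(config, n, rng)
    ids = [f"{id_prefix}{i + 1:02d}" for i in range(n)]
    return BatchDataset(config.panel, values, ids, [FRESH] * n)


def generate_wi(config: GeneratorConfig, n: int | None = None,
                id_prefix: str = "WI") -> BatchDataset:
    """Generate warm-ischemic batches: fresh-style draws plus the additive
    injury signature, scaled by the fresh per-column sd.

    Uses the same RNG stream as :func:`generate_fresh` for the same seed, so
    a zero perturbation reproduces fresh batches exactly; use different seeds
    (or :func:`generate_study`) when combining the two classes.
    """
    n = config.n_wi if n is None else n
    if n < 1:
        raise ConfigError("need at least one batch")
    rng = np.random.default_rng(config.seed)
    values = _draw_batches(config, n, rng)
    values += config.wi_perturbation * config.column_sd()
    ids = [f"{id_prefix}{i + 1:02d}" for i in range(n)]
    return BatchDataset(config.panel, values, ids, [WI] * n)


def generate_study(config: GeneratorConfig) -> BatchDataset:
    """A combined study dataset: ``n_fresh`` fresh then ``n_wi`` WI batches.

    The two classes use decorrelated RNG streams derived from ``config.seed``.
    """
    fresh = generate_fresh(config)
    wi = generate_wi(config.with_(seed=config.seed + 1_000_003))
    return BatchDataset.concatenate([fresh, wi])


@dataclass(frozen=True)
class AnomalySpec:
    """Controlled corruptions for robustness testing.

    ``negative_cells``: (batch_index, metabolite_index, hour_index) cells
    (0-based) overwritten with ``negative_value`` — the classic impossible
    assay read-out.  ``batch_shifts``: whole-batch additive offsets, in units
    of the dataset's per-column sd, emulating an outlier perfusion.
    """

    negative_cells: tuple[tuple[int, int, int], ...] = ()
    batch_shifts: Mapping[int, float] = field(default_factory=dict)
    negative_value: float = -1.0


def inject_anomalies(dataset: BatchDataset, spec: AnomalySpec) -> BatchDataset:
    """Return a corrupted copy of ``dataset``; the original is untouched."""
    out = dataset.copy()
    I, J, K = out.shape
    if spec.batch_shifts:
        col_sd = out.values.std(axis=0, ddof=1) if I > 1 else np.ones((J, K))
        for i, mult in spec.batch_shifts.items():
            if not 0 <= i < I:
                raise IndexError(f"batch index {i} outside 0..{I - 1}")
            out.values[i] += float(mult) * col_sd
    for (i, j, k) in spec.negative_cells:
        if not (0 <= i < I and 0 <= j < J and 0 <= k < K):
            raise IndexError(f"cell ({i}, {j}, {k}) outside dataset shape {dataset.shape}")
        out.values[i, j, k] = spec.negative_value
    return out
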