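"""Hierarchical SECR model: augmented population, activity centres and the
effort-corrected cloglog detection equation.

Detection hazard for individual *i*, trap pixel *j*, occasion *k*::

    eta_ijk = log(lambda0) + beta_eff * log(effort_jk) + beta_sex * male_i
              - (d_ij^2 / (2 sigma_sex^2))^theta
    pi_ijk  = 1 - exp(-exp(eta_ijk))

with ``theta`` fixed at 1 (half-normal decline with distance).  Cells with
zero driven effort are undetectable (``pi = 0``); opportunistic-sighting
pixels are given a small configurable effort floor so that observed
detections there keep positive likelihood.

Five candidate model structures are supported: sex-specific basal rate
and/or spatial scale (models 1-4) and a nonspatial, effort-only variant
(model 5) in which the distance term is dropped and the covariate is total
effort per occasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from secrsearch.ingest import CaptureHistory, EffortMatrix, StateSpace

__all__ = [
    "ModelSpec", "DetectionParams", "AugmentedState", "Priors",
    "distance_kernel", "detection_prob", "log_likelihood",
    "apply_effort_floor", "ModelError",
]

LOG_ZERO = -1e300   # sentinel for impossible configurations


class ModelError(ValueError):
    """Invalid model specification or parameters."""


@dataclass(frozen=True)
class ModelSpec:
    """Which detection-model structure to fit (candidate models 1-5)."""

    model_id: int
    lambda0_sex_specific: bool
    sigma_sex_specific: bool
    spatial: bool = True
    theta: float = 1.0

    _TABLE = {
        1: (True, True, True),
        2: (False, True, True),
        3: (False, False, True),
        4: (True, False, True),
        5: (False, False, False),
    }

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        if model_id not in cls._TABLE:
            raise ModelError(f"model_id must be 1..5, got {model_id}")
        l0, sig, sp = cls._TABLE[model_id]
        return cls(model_id=model_id, lambda0_sex_specific=l0,
                   sigma_sex_specific=sig, spatial=sp)

    def __post_init__(self):
        if self.model_id in self._TABLE and \
                self._TABLE[self.model_id] != (self.lambda0_sex_specific,
                                               self.sigma_sex_specific, self.spatial):
            raise ModelError(f"flags inconsistent with candidate model {self.model_id}")


@dataclass
class DetectionParams:
    lambda0: float
    beta_eff: float = 0.0
    beta_sex: float = 0.0
    sigma_f: float = 1.0
    sigma_m: float = 1.0
    theta: float = 1.0

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ModelError("lambda0 must be positive")
        if self.sigma_f <= 0 or self.sigma_m <= 0:
            raise ModelError("sigma must be positive")

    def sigma_of(self, male) -> np.ndarray:
        """Per-individual sigma given a 0/1 male indicator."""
        return np.where(np.asarray(male) == 1, self.sigma_m, self.sigma_f)


@dataclass
class AugmentedState:
    """Latent state of the augmented population of size M."""

    M: int
    z: np.ndarray          # (M,) 0/1 inclusion
    sex: np.ndarray        # (M,) 0 female / 1 male
    s: np.ndarray          # (M,) state-space pixel row indices
    psi: float
    psi_sex: float

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.s = np.asarray(self.s, dtype=int)
        if not (0 < self.psi < 1 and 0 < self.psi_sex < 1):
            raise ModelError("psi and psi_sex must lie in (0, 1)")

    @property
    def n_super(self) -> int:
        return int(self.z.sum())


@dataclass
class Priors:
    """Vague proper priors for all top-level parameters.

    psi, psi_sex ~ Beta(1, 1); log(lambda0), beta_eff, beta_sex ~
    Normal(0, sd); sigma_f, sigma_m ~ Uniform(0, sigma_max) with sigma_max
    defaulting to the state-space diameter.
    """

    normal_sd: float = 10.0
    sigma_max: float = 50.0

    def _lp_normal(self, x: float) -> float:
        sd = self.normal_sd
        return -0.5 * (x / sd) ** 2 - 0.5 * np.log(2.0 * np.pi * sd * sd)

    def lp_log_lambda0(self, log_l0: float) -> float:
        return self._lp_normal(log_l0)

    def lp_beta(self, b: float) -> float:
        return self._lp_normal(b)

    def lp_sigma(self, sigma: float) -> float:
        return 0.0 - np.log(self.sigma_max) if 0 < sigma < self.sigma_max else LOG_ZERO

    @classmethod
    def for_space(cls, space: StateSpace, normal_sd: float = 10.0) -> "Priors":
        lo = space.centroids.min(axis=0)
        hi = space.centroids.max(axis=0)
        return cls(normal_sd=normal_sd, sigma_max=float(np.hypot(*(hi - lo))))


def distance_kernel(d, sigma, theta: float = 1.0):
    """Distance term of the hazard: ``(d^2 / (2 sigma^2))^theta``.

    With theta = 1 this is the half-normal exponent.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ModelError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    base = d * d / (2.0 * np.asarray(sigma, dtype=float) ** 2)
    if theta == 1.0:
        return base
    return base ** theta


def detection_prob(params: DetectionParams, d, effort_km, male=0):
    """Per-cell detection probability under the cloglog model.

    Zero-effort cells return exactly 0 (detection there is impossible).
    """
    d = np.asarray(d, dtype=float)
    e = np.asarray(effort_km, dtype=float)
    male = np.asarray(male)
    if np.any(e < 0):
        raise ModelError("effort must be nonnegative")
    sigma = params.sigma_of(male)
    with np.errstate(divide="ignore"):
        eta = (np.log(params.lambda0)
               + params.beta_eff * np.log(np.where(e > 0, e, 1.0))
               + params.beta_sex * male
               - distance_kernel(d, sigma, params.theta))
    pi = -np.expm1(-np.exp(eta))
    pi = np.where(e > 0, pi, 0.0)
    if pi.ndim == 0:
        return float(pi)
    return pi


def apply_effort_floor(effort: EffortMatrix, ch: CaptureHistory,
                       floor_km: float = 0.1) -> EffortMatrix:
    """Give opportunistic-sighting cells (detection but zero effort) a small
    positive effort so their detections have positive likelihood."""
    values = effort.values.copy()
    seen = ch.y.max(axis=0) > 0        # (J, K)
    mask = seen & (values == 0)
    values[mask] = floor_km
    return EffortMatrix(values=values, trap_ids=effort.trap_ids,
                        trap_xy=effort.trap_xy, occasion_dates=effort.occasion_dates)


def _hazards(ch: CaptureHistory, effort: EffortMatrix, state: AugmentedState,
             params: DetectionParams, spec: ModelSpec, space: StateSpace | None):
    """(M, J, K) detection hazards h = exp(eta); h = 0 where effort = 0."""
    male = state.sex.astype(float)
    if spec.spatial:
        if space is None:
            raise ModelError("spatial models need the state space")
        centres = space.centroids[state.s]                      # (M, 2)
        d2 = ((centres[:, None, :] - ch.trap_xy[None, :, :]) ** 2).sum(-1)
        sigma = params.sigma_of(state.sex)[:, None]
        if spec.theta == 1.0:
            f = d2 / (2.0 * sigma ** 2)
        else:
            f = (d2 / (2.0 * sigma ** 2)) ** spec.theta
        eff = effort.values                                     # (J, K)
    else:
        # nonspatial: one pseudo-trap, per-occasion total effort
        f = np.zeros((state.M, 1))
        eff = effort.values.sum(axis=0, keepdims=True)          # (1, K)
    pos = eff > 0
    with np.errstate(divide="ignore"):
        logeff = np.where(pos, np.log(np.where(pos, eff, 1.0)), 0.0)
    eta = (np.log(params.lambda0)
           + params.beta_eff * logeff[None, :, :]
           + params.beta_sex * male[:, None, None]
           - f[:, :, None])
    h = np.exp(eta)
    h[:, ~pos] = 0.0
    return h, pos


def log_likelihood(ch: CaptureHistory, effort: EffortMatrix, state: AugmentedState,
                   params: DetectionParams, spec: ModelSpec,
                   space: StateSpace | None = None) -> float:
    """Complete-data log likelihood of the augmented model.

    Bernoulli mass of the (implicitly zero-padded) capture tensor with cell
    probability ``z_i * pi_ijk``, plus the inclusion mass ``z | psi`` and the
    sex mass of included individuals given ``psi_sex``.  Observed detections
    with ``z_i = 0`` or ``pi = 0`` make the result the log-zero sentinel.
    """
    n = ch.n_individuals
    if state.M < n:
        raise ModelError("augmented size M smaller than number detected")
    if np.any(state.z[:n] != 1):
        raise ModelError("detected individuals must have z = 1")

    h, pos = _hazards(ch, effort, state, params, spec, space)
    if spec.spatial:
        y = np.zeros_like(h, dtype=np.int8)
        y[:n] = ch.y
    else:
        y = np.zeros_like(h, dtype=np.int8)
        y[:n, 0, :] = ch.y.max(axis=1)

    z = state.z.astype(bool)
    # z=0 rows: Bernoulli(0) on zeros -> contribute 0; any y=1 -> impossible
    if y[~z].any():
        return LOG_ZERO
    hz = h[z]
    yz = y[z].astype(bool)
    if np.any(yz & (hz <= 0)):
        return LOG_ZERO
    with np.errstate(divide="ignore"):
        ll = float(np.log(-np.expm1(-hz[yz])).sum() - hz[~yz].sum())

    nz = state.n_super
    ll += nz * np.log(state.psi) + (state.M - nz) * np.log1p(-state.psi)
    male_in = int(state.sex[z].sum())
    ll += male_in * np.log(state.psi_sex) + (nz - male_in) * np.log1p(-state.psi_sex)
    return ll
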