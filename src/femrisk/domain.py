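"""Core domain types: model constants, stochastic parameter specs and subjects.

The fall model treats each fall as an inverted-pendulum rotation of the whole
body about a hinge at the foot, with the body mass concentrated at the centre
of mass (COM) whose standing elevation is ``c*H``.  All stochastic fall
parameters are normal distributions truncated symmetrically at +/- 3 SD, so a
pair of truncation limits ``(a, b)`` fully specifies each distribution: the
untruncated mean is ``(a+b)/2`` and the untruncated SD is ``(b-a)/6``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
from scipy.stats import norm

__all__ = [
    "FixedConstants",
    "TruncatedNormalSpec",
    "GeneralTruncNormSpec",
    "UniformSpec",
    "FallStochasticModel",
    "Subject",
    "compute_bmi",
    "truncated_moments",
    "TRUNC_VAR_RATIO",
]

# Variance of a standard normal truncated at +/-3 sigma, relative to sigma^2:
# 1 - 2*3*phi(3) / (Phi(3) - Phi(-3)).
TRUNC_VAR_RATIO: float = float(1.0 - 6.0 * norm.pdf(3.0) / (norm.cdf(3.0) - norm.cdf(-3.0)))


@dataclass(frozen=True)
class FixedConstants:
    """Deterministic model constants shared by all subjects and falls.

    Attributes
    ----------
    c : float
        Ratio of standing COM elevation to body height (dimensionless).
    dt : float
        Duration of the hip impact in seconds; the impact force is a
        triangular pulse peaking at ``dt/2``.
    n_fall : float
        Annual fall rate in falls per person per year, fixed across subjects.
    g : float
        Gravitational acceleration, m s^-2.
    k : float
        Proportionality factor of the peak-force relation ``F* = k*2*m*u/dt``;
        impact experiments on synthetic pelves suggest ``k ~ 0.5``, which
        collapses the relation to ``F* = m*u/dt``.
    """

    c: float = 0.554
    dt: float = 0.09
    n_fall: float = 0.65
    g: float = 9.81
    k: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"constant {f.name!r} must be strictly positive, got {v}")
        if self.c >= 1:
            raise ValueError(f"COM-height ratio c must be < 1, got {self.c}")


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Normal distribution truncated symmetrically at +/-3 SD.

    ``a`` and ``b`` are the truncation limits in native units; the implied
    untruncated mean and SD are ``(a+b)/2`` and ``(b-a)/6``.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a < self.b):
            raise ValueError(f"require a < b, got a={self.a}, b={self.b}")

    @property
    def mu(self) -> float:
        return 0.5 * (self.a + self.b)

    @property
    def sigma(self) -> float:
        return (self.b - self.a) / 6.0

    def ppf(self, q):
        """Inverse CDF of the truncated distribution (vectorised)."""
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0.0) or np.any(q >= 1.0):
            raise ValueError("quantile q must lie strictly in (0, 1)")
        lo, hi = norm.cdf(-3.0), norm.cdf(3.0)
        out = self.mu + self.sigma * norm.ppf(lo + q * (hi - lo))
        return np.clip(out, self.a, self.b)


@dataclass(frozen=True)
class GeneralTruncNormSpec:
    """Truncated normal with explicit (possibly asymmetric) limits.

    Used for the surrogate mean-strength distribution, whose truncation
    window is not symmetric about the mean.
    """

    mu: float
    sigma: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a < self.b):
            raise ValueError(f"require a < b, got a={self.a}, b={self.b}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0.0) or np.any(q >= 1.0):
            raise ValueError("quantile q must lie strictly in (0, 1)")
        lo = norm.cdf((self.a - self.mu) / self.sigma)
        hi = norm.cdf((self.b - self.mu) / self.sigma)
        out = self.mu + self.sigma * norm.ppf(lo + q * (hi - lo))
        return np.clip(out, self.a, self.b)


@dataclass(frozen=True)
class UniformSpec:
    """Uniform distribution on [a, b] (used by the sensitivity analyses)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a < self.b):
            raise ValueError(f"require a < b, got a={self.a}, b={self.b}")

    @property
    def mu(self) -> float:
        return 0.5 * (self.a + self.b)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0.0) or np.any(q >= 1.0):
            raise ValueError("quantile q must lie strictly in (0, 1)")
        return self.a + q * (self.b - self.a)


# Order matters: this is the canonical column order of a fall sample.
FALL_PARAM_NAMES = ("theta_i", "theta_f", "v_i", "a_i", "eta_P", "eta_I")


@dataclass(frozen=True)
class FallStochasticModel:
    """Truncated-normal specs of the six stochastic fall parameters.

    Angles are in degrees.  The initial angular velocity and acceleration are
    represented as the linear quantities ``c*H*theta_dot_i`` (``v_i``, m/s)
    and ``c*H*theta_ddot_i`` (``a_i``, m/s^2), whose bounds are
    subject-independent.
    """

    theta_i: TruncatedNormalSpec = field(default_factory=lambda: TruncatedNormalSpec(0.0, 30.0))
    theta_f: TruncatedNormalSpec = field(default_factory=lambda: TruncatedNormalSpec(60.0, 120.0))
    v_i: TruncatedNormalSpec = field(default_factory=lambda: TruncatedNormalSpec(0.0, 1.40))
    a_i: TruncatedNormalSpec = field(default_factory=lambda: TruncatedNormalSpec(0.0, 5.10))
    eta_P: TruncatedNormalSpec = field(default_factory=lambda: TruncatedNormalSpec(0.500, 0.800))
    eta_I: TruncatedNormalSpec = field(default_factory=lambda: TruncatedNormalSpec(-2.55, 0.914))

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_P.a and self.eta_P.b <= 1.0):
            raise ValueError("eta_P bounds must lie within [0, 1]")

    def specs(self) -> dict[str, TruncatedNormalSpec]:
        """Ordered parameter-name -> spec mapping."""
        return {name: getattr(self, name) for name in FALL_PARAM_NAMES}

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {name: {"a": s.a, "b": s.b} for name, s in self.specs().items()}

    @classmethod
    def from_dict(cls, d: dict) -> "FallStochasticModel":
        unknown = set(d) - set(FALL_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fall parameters: {sorted(unknown)}")
        kwargs = {k: TruncatedNormalSpec(float(v["a"]), float(v["b"])) for k, v in d.items()}
        return cls(**kwargs)


@dataclass
class Subject:
    """One subject's anthropometrics and (optional) clinical metadata."""

    subject_id: str
    m: float  # body mass, kg
    H: float  # standing height, m
    age: Optional[float] = None
    group: Optional[str] = None  # "fracture" | "non-fracture"
    fracture_label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.m <= 0 or self.H <= 0:
            raise ValueError(f"mass and height must be positive (subject {self.subject_id})")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.m, self.H)


def compute_bmi(m, H):
    """Body mass index m/H^2 in kg m^-2 (vectorised)."""
    m = np.asarray(m, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(m <= 0) or np.any(H <= 0):
        raise ValueError("mass and height must be strictly positive")
    out = m / H**2
    return float(out) if out.ndim == 0 else out


def truncated_moments(spec: TruncatedNormalSpec) -> tuple[float, float, float, float]:
    """Moments implied by a +/-3 SD truncated-normal spec.

    Returns ``(mu, sigma, mu_trunc, var_trunc)`` where ``mu`` and ``sigma``
    describe the untruncated parent and ``mu_trunc``/``var_trunc`` are the
    mean and variance after truncation.  By symmetry ``mu_trunc == mu``; the
    truncated variance is ``sigma^2`` shrunk by a universal factor
    (:data:`TRUNC_VAR_RATIO`, about 0.97334).
    """
    mu, sigma = spec.mu, spec.sigma
    return mu, sigma, mu, sigma**2 * TRUNC_VAR_RATIO
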