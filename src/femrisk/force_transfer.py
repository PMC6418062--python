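"""Ground-skeleton force-transfer model.

Only part of the peak impact force reaches the greater trochanter: the
combined attenuation of flooring, hip protectors and active muscle (eta_I,
sampled per fall; negative values mean active-muscle amplification) and the
passive trochanteric soft-tissue attenuation (eta_ST, fixed per subject via
a BMI regression) act multiplicatively:

    F = (1 - eta_I) * (1 - eta_ST) * F*

The soft-tissue chain is: STT(cm) = 0.23415*BMI - 3.3444 (floored at 0),
the impact-test regression F(kN) = 7.2 - 0.71*STT implying
eta_ST = 0.0986*STT, hence eta_ST = 0.0231*BMI - 0.330 (reset to 0 when
negative).  The intermediate F-STT regression is kept only as a documented
derivation check; the runtime path maps BMI directly to eta_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttenuationSet",
    "stt_from_bmi",
    "eta_st_from_bmi",
    "compose_eta_I",
    "attenuated_force",
]

# Regression coefficients (soft-tissue thickness and attenuation vs BMI).
_STT_SLOPE, _STT_INTERCEPT = 0.23415, -3.3444
_ETA_ST_SLOPE, _ETA_ST_INTERCEPT = 0.0231, -0.330
ETA_ST_PER_STT = 0.0986  # eta_ST per cm of soft-tissue thickness (derivation check)


@dataclass(frozen=True)
class AttenuationSet:
    """Component and combined force attenuations for one impact scenario."""

    eta_floor: float
    eta_ext: float
    eta_act: float
    eta_ST: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_ST < 1.0):
            raise ValueError("eta_ST must lie in [0, 1)")

    @property
    def eta_I(self) -> float:
        return compose_eta_I(self.eta_floor, self.eta_ext, self.eta_act)


def stt_from_bmi(bmi):
    """Trochanteric soft-tissue thickness (cm) from BMI, floored at zero."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    out = np.maximum(_STT_SLOPE * bmi + _STT_INTERCEPT, 0.0)
    return float(out) if out.ndim == 0 else out


def eta_st_from_bmi(bmi):
    """Passive soft-tissue attenuation coefficient from BMI, reset to 0 if negative."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    out = np.maximum(_ETA_ST_SLOPE * bmi + _ETA_ST_INTERCEPT, 0.0)
    return float(out) if out.ndim == 0 else out


def compose_eta_I(eta_floor, eta_ext, eta_act):
    """Combine component attenuations: ``1 - prod(1 - eta_component)``."""
    comps = [np.asarray(x, dtype=float) for x in (eta_floor, eta_ext, eta_act)]
    for c in comps:
        if np.any(c >= 1):
            raise ValueError("attenuation components must be < 1")
    out = 1.0 - (1.0 - comps[0]) * (1.0 - comps[1]) * (1.0 - comps[2])
    return float(out) if np.ndim(out) == 0 else out


def attenuated_force(F_star, eta_I, eta_ST):
    """Peak force on the greater trochanter: ``(1-eta_I)*(1-eta_ST)*F*`` (N)."""
    F_star = np.asarray(F_star, dtype=float)
    eta_I = np.asarray(eta_I, dtype=float)
    eta_ST = np.asarray(eta_ST, dtype=float)
    if np.any(eta_I >= 1):
        raise ValueError("eta_I must be < 1")
    if np.any((eta_ST < 0) | (eta_ST >= 1)):
        raise ValueError("eta_ST must lie in [0, 1)")
    out = (1.0 - eta_I) * (1.0 - eta_ST) * F_star
    return float(out) if np.ndim(out) == 0 else out
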