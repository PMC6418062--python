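"""Body-floor impact model: inverted-pendulum fall energetics and peak force.

A fall is a rotation of the body about a hinge at the foot from inclination
``theta_i`` to ``theta_f`` (measured from the vertical).  The kinetic energy
per unit mass available at impact combines the work done by the initial
angular acceleration, the initial kinetic energy and the gravitational drop
of the COM; postural reflexes attenuate a fraction ``eta_P`` of it.  The
peak impact force follows from a triangular force-time pulse of duration
``dt``.

All functions are pure and vectorised over their numeric arguments; angles
enter in degrees and are converted to radians internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .domain import FixedConstants

__all__ = ["FallKinematics", "kinetic_energy", "impact_velocity", "peak_impact_force"]

log = logging.getLogger(__name__)


@dataclass
class FallKinematics:
    """Derived quantities of one (or a batch of) realised fall(s)."""

    e: np.ndarray  # kinetic energy per unit mass, J/kg
    u: np.ndarray  # hip impact velocity, m/s
    F_star: np.ndarray  # unattenuated peak impact force, N


def kinetic_energy(H, theta_i, theta_f, v_i, a_i, constants: FixedConstants = FixedConstants()):
    """Kinetic energy per unit body mass at the end of the fall (J/kg).

    ``e = cH * a_i * (theta_f - theta_i) + v_i^2/2 + g*cH*(cos th_i - cos th_f)``

    where ``v_i = cH*theta_dot_i`` and ``a_i = cH*theta_ddot_i`` are the
    linear COM velocity/acceleration at fall initiation (the first term is
    algebraically ``c^2 H^2 theta_ddot_i (theta_f - theta_i)``).  Angles in
    degrees.  A pathological parameter combination yielding negative energy
    is clamped to zero (cannot occur within the default parameter ranges).
    """
    H = np.asarray(H, dtype=float)
    theta_i = np.asarray(theta_i, dtype=float)
    theta_f = np.asarray(theta_f, dtype=float)
    if np.any(H <= 0):
        raise ValueError("height must be positive")
    if np.any(theta_f <= theta_i):
        raise ValueError("fall must progress: theta_f > theta_i")
    ch = constants.c * H
    dtheta = np.deg2rad(theta_f - theta_i)
    ti = np.deg2rad(theta_i)
    tf = np.deg2rad(theta_f)
    e = ch * np.asarray(a_i, float) * dtheta
    e = e + 0.5 * np.asarray(v_i, float) ** 2
    e = e + constants.g * ch * (np.cos(ti) - np.cos(tf))
    if np.any(e < 0):
        log.warning("negative kinetic energy clamped to zero for %d fall(s)", int(np.sum(e < 0)))
        e = np.maximum(e, 0.0)
    return float(e) if np.ndim(e) == 0 else e


def impact_velocity(e, eta_P):
    """Hip impact velocity ``u = sqrt(2*(1-eta_P)*e)`` in m/s.

    ``eta_P`` is the postural reflex attenuation coefficient in [0, 1].
    """
    e = np.asarray(e, dtype=float)
    eta_P = np.asarray(eta_P, dtype=float)
    if np.any(e < 0):
        raise ValueError("kinetic energy must be non-negative")
    if np.any((eta_P < 0) | (eta_P > 1)):
        raise ValueError("eta_P must lie in [0, 1]")
    u = np.sqrt(2.0 * (1.0 - eta_P) * e)
    return float(u) if np.ndim(u) == 0 else u


def peak_impact_force(m, u, constants: FixedConstants = FixedConstants()):
    """Unattenuated peak impact force ``F* = k * 2*m*u/dt`` in N.

    With the default ``k = 0.5`` this is ``F* = m*u/dt``.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    if np.any(u < 0):
        raise ValueError("impact velocity must be non-negative")
    F = constants.k * 2.0 * m * u / constants.dt
    return float(F) if np.ndim(F) == 0 else F
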