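"""Variance-based global sensitivity analysis and uncertainty bands.

First-order Sobol indices S_x = Var[E(Y|x)]/Var(Y) quantify the fraction of
output variance attributable to each input alone.  For independent inputs
they are estimated with the Saltelli radial scheme ((d+2)*N model runs); for
rank-correlated inputs an Iman-Conover correlated sample is combined with a
binned conditional-expectation estimator.  The inputs whose descending
indices sum to just over a threshold (default 80%) are "sensitive"; a
location-independent uncertainty band for the output is then obtained from
the extreme bin-mean outputs over a regular grid in the sensitive-input
space:

    s~ = sqrt(sum s_X^2) * (<Y>_max - <Y>_min) / |X_max - X_min|

where s_X are the measurement uncertainties of the sensitive inputs.
Angle-valued inputs are converted to radians before the distance and the
s_X norm; this convention is load-bearing for mixed-unit inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .domain import FixedConstants, FallStochasticModel, UniformSpec
from .sampling import LHSample, iman_conover, lh_sample

__all__ = [
    "SensitivityResult",
    "UncertaintyBand",
    "saltelli_first_order",
    "correlated_first_order",
    "select_sensitive",
    "eq12_band",
    "uncertainty_band",
    "impact_force_specs",
    "unattenuated_force_model",
    "skeletal_force_model",
]

log = logging.getLogger(__name__)


@dataclass
class SensitivityResult:
    """First-order sensitivity indices per input parameter."""

    indices: dict[str, float]
    N: int
    method: str


@dataclass
class UncertaintyBand:
    """Location-independent propagated output uncertainty."""

    s_tilde: float
    y_max: float
    y_min: float
    x_max: np.ndarray  # bin-centre location of the maximum (native units)
    x_min: np.ndarray
    input_uncertainties: dict[str, float] = field(default_factory=dict)


def impact_force_specs(
    fall_model: FallStochasticModel | None = None,
    include_eta_I: bool = False,
) -> dict[str, UniformSpec]:
    """Uniform input ranges of the impact-force sensitivity analyses.

    Anthropometrics span the validation-population ranges (m 31.0-101 kg,
    H 1.45-1.73 m); fall parameters span their truncation ranges.
    """
    fall_model = fall_model or FallStochasticModel()
    fm = fall_model.to_dict()
    specs = {"m": UniformSpec(31.0, 101.0), "H": UniformSpec(1.45, 1.73)}
    names = ["theta_i", "theta_f", "v_i", "a_i", "eta_P"] + (["eta_I"] if include_eta_I else [])
    specs.update({k: UniformSpec(fm[k]["a"], fm[k]["b"]) for k in names})
    return specs


def unattenuated_force_model(constants: FixedConstants = FixedConstants()) -> Callable:
    """F* as a function of (m, H, theta_i, theta_f, v_i, a_i, eta_P) rows."""
    from .fall_mechanics import impact_velocity, kinetic_energy, peak_impact_force

    def model(X: np.ndarray) -> np.ndarray:
        m, H, theta_i, theta_f, v_i, a_i, eta_P = np.atleast_2d(X).T
        e = kinetic_energy(H, theta_i, theta_f, v_i, a_i, constants)
        return peak_impact_force(m, impact_velocity(e, eta_P), constants)

    return model


def skeletal_force_model(
    constants: FixedConstants = FixedConstants(),
    eta_ST: float = 0.26,
) -> Callable:
    """F as a function of (m, H, theta_i, theta_f, v_i, a_i, eta_P, eta_I) rows.

    The passive soft-tissue attenuation is held at a fixed reference value
    (population-typical by default): it is a deterministic per-subject
    regression, not a measured stochastic input of this analysis, and a
    constant multiplier leaves sensitivity indices unchanged.
    """
    from .fall_mechanics import impact_velocity, kinetic_energy, peak_impact_force
    from .force_transfer import attenuated_force

    def model(X: np.ndarray) -> np.ndarray:
        m, H, theta_i, theta_f, v_i, a_i, eta_P, eta_I = np.atleast_2d(X).T
        e = kinetic_energy(H, theta_i, theta_f, v_i, a_i, constants)
        F_star = peak_impact_force(m, impact_velocity(e, eta_P), constants)
        return attenuated_force(F_star, eta_I, eta_ST)

    return model


def _evaluate(model: Callable, X: np.ndarray) -> np.ndarray:
    Y = np.asarray(model(X), dtype=float)
    if Y.shape != (X.shape[0],):
        raise ValueError("model must map an (n, d) array to an (n,) array")
    if np.any(~np.isfinite(Y)):
        bad = X[~np.isfinite(Y)][0]
        raise ValueError(f"non-finite model output, first offending input vector: {bad}")
    return Y


def saltelli_first_order(
    model: Callable[[np.ndarray], np.ndarray],
    specs: Mapping[str, object],
    N: int,
    seed: int,
) -> SensitivityResult:
    """Saltelli radial estimator of first-order indices for independent inputs.

    Two independent LH base samples A and B of size N are drawn; for each
    input i the radial matrix AB_i equals A with column i taken from B.  The
    estimator ``S_i = mean(B*(AB_i - A)) / Var([A; B])`` uses (d+2)*N model
    evaluations in total.  A zero-variance model returns all-zero indices.
    """
    if N < 1000:
        raise ValueError("Saltelli estimation needs N >= 1000 for usable accuracy")
    names = list(specs)
    spec_list = [specs[k] for k in names]
    A = lh_sample(N, spec_list, seed=seed, names=names).matrix
    B = lh_sample(N, spec_list, seed=seed + 1, names=names).matrix
    fA = _evaluate(model, A)
    fB = _evaluate(model, B)
    V = np.var(np.concatenate([fA, fB]))
    indices: dict[str, float] = {}
    for i, name in enumerate(names):
        if V == 0.0:
            indices[name] = 0.0
            continue
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = _evaluate(model, ABi)
        indices[name] = float(np.mean(fB * (fABi - fA)) / V)
    return SensitivityResult(indices=indices, N=N, method="saltelli")


def _binned_first_order(Y: np.ndarray, x: np.ndarray, n_bins: int) -> float:
    """Var[E(Y|x)]/Var(Y) via equal-count bins of x."""
    V = np.var(Y)
    if V == 0.0:
        return 0.0
    order = np.argsort(x, kind="stable")
    splits = np.array_split(Y[order], n_bins)
    counts = np.array([len(s) for s in splits])
    means = np.array([s.mean() for s in splits])
    cond_var = np.sum(counts * (means - Y.mean()) ** 2) / len(Y)
    return float(cond_var / V)


def correlated_first_order(
    model: Callable[[np.ndarray], np.ndarray],
    specs: Mapping[str, object],
    rank_corr: np.ndarray,
    N: int,
    seed: int,
    n_bins: int = 50,
) -> SensitivityResult:
    """First-order indices under rank-correlated inputs.

    An LH sample is given the target Spearman structure by Iman-Conover,
    the model is evaluated once, and each index is the binned
    conditional-expectation estimate Var[E(Y|X_i)]/Var(Y).  With the
    identity correlation this agrees with the Saltelli estimator up to
    estimator noise.  Under correlation, variance "leaks": an input
    correlated with a driving input obtains a positive index even if the
    model ignores it.
    """
    names = list(specs)
    base = lh_sample(N, [specs[k] for k in names], seed=seed, names=names)
    sample: LHSample = iman_conover(base, np.asarray(rank_corr, float), seed=seed + 1)
    Y = _evaluate(model, sample.matrix)
    indices = {name: _binned_first_order(Y, sample.matrix[:, i], n_bins) for i, name in enumerate(names)}
    return SensitivityResult(indices=indices, N=N, method="correlated")


def select_sensitive(result: SensitivityResult | Mapping[str, float], threshold: float = 0.8) -> list[str]:
    """Smallest prefix of descending-sorted indices whose sum reaches the threshold.

    Ties are broken deterministically by parameter name.
    """
    indices = result.indices if isinstance(result, SensitivityResult) else dict(result)
    if all(v <= 0 for v in indices.values()):
        raise ValueError("no positive sensitivity index; nothing to select")
    ranked = sorted(indices.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen: list[str] = []
    total = 0.0
    for name, s in ranked:
        chosen.append(name)
        total += s
        if total >= threshold:
            break
    return chosen


def eq12_band(
    s_X: Sequence[float],
    y_max: float,
    y_min: float,
    x_max: Sequence[float],
    x_min: Sequence[float],
    angular: Sequence[bool] | None = None,
) -> float:
    """Location-independent uncertainty from extreme bin means.

    ``s~ = sqrt(sum s_X^2) * |y_max - y_min| / |x_max - x_min|``; coordinates
    flagged ``angular`` (degrees) are converted to radians in both the s_X
    norm and the Euclidean distance.  Symmetric in which extremum is called
    max.
    """
    s_X = np.asarray(s_X, dtype=float)
    x_max = np.asarray(x_max, dtype=float)
    x_min = np.asarray(x_min, dtype=float)
    if angular is not None:
        ang = np.asarray(angular, dtype=bool)
        s_X = np.where(ang, np.deg2rad(s_X), s_X)
        x_max = np.where(ang, np.deg2rad(x_max), x_max)
        x_min = np.where(ang, np.deg2rad(x_min), x_min)
    dist = float(np.linalg.norm(x_max - x_min))
    if dist == 0.0:
        raise ValueError("extremum locations coincide; band undefined")
    return float(np.sqrt(np.sum(s_X**2)) * abs(y_max - y_min) / dist)


def uncertainty_band(
    sample_Y: np.ndarray,
    sample_X: np.ndarray,
    s_X: Mapping[str, float] | Sequence[float],
    bins: int = 10,
    angular: Sequence[bool] | None = None,
) -> UncertaintyBand:
    """Bin the output over a regular grid in sensitive-input space (Eq-12 band).

    ``sample_X`` has one column per sensitive input; the grid is ``bins``
    equal-width intervals per dimension over the sample range.  Empty bins
    are excluded from the extrema (with a warning).  Extremum locations are
    reported as bin centres.
    """
    Y = np.asarray(sample_Y, dtype=float)
    X = np.atleast_2d(np.asarray(sample_X, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("sample_X and sample_Y must have matching lengths")
    if bins < 2:
        raise ValueError("need at least 2 bins per dimension")
    k = X.shape[1]
    s_vals = np.asarray([s_X[name] for name in s_X] if isinstance(s_X, Mapping) else s_X, dtype=float)
    if s_vals.shape != (k,):
        raise ValueError("one input uncertainty per sensitive input required")

    lo, hi = X.min(axis=0), X.max(axis=0)
    width = (hi - lo) / bins
    idx = np.clip(((X - lo) / width).astype(int), 0, bins - 1)
    flat = np.ravel_multi_index(idx.T, (bins,) * k)
    sums = np.bincount(flat, weights=Y, minlength=bins**k)
    counts = np.bincount(flat, minlength=bins**k)
    occupied = counts > 0
    if not np.all(occupied):
        log.warning("%d of %d bins are empty and excluded from extrema", int(np.sum(~occupied)), bins**k)
    means = np.full(bins**k, np.nan)
    means[occupied] = sums[occupied] / counts[occupied]

    i_max = int(np.nanargmax(means))
    i_min = int(np.nanargmin(means))
    centres = [lo + (np.array(np.unravel_index(i, (bins,) * k)) + 0.5) * width for i in (i_max, i_min)]
    y_max, y_min = float(means[i_max]), float(means[i_min])
    s_tilde = eq12_band(s_vals, y_max, y_min, centres[0], centres[1], angular)
    names = list(s_X) if isinstance(s_X, Mapping) else [f"x{i}" for i in range(k)]
    return UncertaintyBand(
        s_tilde=s_tilde,
        y_max=y_max,
        y_min=y_min,
        x_max=centres[0],
        x_min=centres[1],
        input_uncertainties=dict(zip(names, s_vals.tolist())),
    )
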