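"""Verification protocol for the stochastic numerics.

Three steps: (1) errors of Latin-hypercube sample moments against the
theoretical truncated-normal moments, (2) refinement of the orientation
quadrature in M against a fine reference grid, and (3) Monte-Carlo
convergence of ARF0 in the fall sample size N against a large-N reference
run.  All reports are bit-reproducible under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .domain import FixedConstants, FallStochasticModel, Subject, TruncatedNormalSpec, truncated_moments
from .sampling import lh_sample
from .strength import AnisotropyShape, StrengthSurface, build_orientation_grid
from .risk import arf0_from_p, fall_fracture_probability

__all__ = ["ConvergenceReport", "lh_moment_errors", "quadrature_convergence", "mc_convergence"]


@dataclass
class ConvergenceReport:
    """Errors of a numerical setting against a reference solution."""

    settings: list  # the refined quantity (sample sizes N or point counts M)
    errors: list  # per-setting error; percentage points for ARF0 errors
    reference: str
    extra: dict = field(default_factory=dict)


def lh_moment_errors(spec: TruncatedNormalSpec, N: int, seed: int) -> tuple[float, float]:
    """Normalised LH moment errors (eps_mu, eps_sigma) for one parameter.

    eps_mu = |mu* - mu| / sqrt(sigma^2) and eps_sigma = |sigma*^2 - sigma^2|
    / sigma^2, where mu and sigma^2 are the theoretical mean and variance of
    the truncated distribution and starred quantities are sample estimates.
    """
    _, _, mu_t, var_t = truncated_moments(spec)
    x = lh_sample(N, [spec], seed=seed).matrix[:, 0]
    eps_mu = abs(x.mean() - mu_t) / np.sqrt(var_t)
    eps_sigma = abs(x.var(ddof=1) - var_t) / var_t
    return float(eps_mu), float(eps_sigma)


def quadrature_convergence(
    subject: Subject,
    fall_model: FallStochasticModel,
    shape: AnisotropyShape,
    mean_strength: float,
    M_list: Sequence[int],
    N: int,
    seed: int,
    ref_M: int = 231,
    constants: FixedConstants = FixedConstants(),
) -> ConvergenceReport:
    """ARF0 change (pp) as the orientation grid is refined towards ``ref_M``.

    The strength surface is an analytic anisotropy shape evaluated on each
    grid (times a fixed orientation-averaged strength), so refinement probes
    only the quadrature error.  The same N Latin-hypercube falls (same seed)
    are shared by every grid.
    """

    def _arf0(M: int) -> float:
        grid = build_orientation_grid(M)
        f = shape.evaluate(grid.points[:, 0], grid.points[:, 1])
        surface = StrengthSurface(subject.subject_id, grid, mean_strength * f)
        P = fall_fracture_probability(subject, fall_model, surface, N, seed, constants)
        return arf0_from_p(P, constants.n_fall)

    ref = _arf0(ref_M)
    errors = [abs(_arf0(M) - ref) for M in M_list]
    return ConvergenceReport(
        settings=list(M_list),
        errors=errors,
        reference=f"M={ref_M} grid, common N={N} falls",
        extra={"arf0_ref": ref},
    )


def mc_convergence(
    subjects: Sequence[Subject],
    surfaces: Mapping[str, StrengthSurface],
    fall_model: FallStochasticModel,
    N_list: Sequence[int],
    ref_N: int,
    seed: int,
    constants: FixedConstants = FixedConstants(),
) -> ConvergenceReport:
    """Median and maximum ARF0 error (pp) over a cohort versus a large-N run.

    The reference for each subject is an independently seeded run at
    ``ref_N``; eps_ARF0(i, N) = |ARF0(i, N) - ARF0(i, ref_N)|.
    """
    if ref_N <= max(N_list):
        raise ValueError("reference sample size must exceed every tested N")
    root = np.random.SeedSequence(seed)
    subject_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(len(subjects))]

    def _arf0_all(N: int, offset: int) -> np.ndarray:
        out = []
        for subject, s in zip(subjects, subject_seeds):
            P = fall_fracture_probability(
                subject, fall_model, surfaces[subject.subject_id], N, s + offset, constants
            )
            out.append(arf0_from_p(P, constants.n_fall))
        return np.asarray(out)

    ref = _arf0_all(ref_N, offset=0)
    medians, maxima = [], []
    for i, N in enumerate(N_list, start=1):
        err = np.abs(_arf0_all(N, offset=i) - ref)
        medians.append(float(np.median(err)))
        maxima.append(float(err.max()))
    return ConvergenceReport(
        settings=list(N_list),
        errors=medians,
        reference=f"independent run at N={ref_N}",
        extra={"max_errors": maxima, "arf0_ref": ref.tolist()},
    )
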