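"""Side-fall femoral strength surfaces over impact orientation.

Femoral strength ``S(alpha', beta')`` is the smallest impact-force magnitude
that fractures the proximal femur when the force is applied at the femoral
head centre in the direction given by the orientation angles
``(alpha', beta')``, which range over [-30, +30] x [0, +30] degrees and are
uniformly distributed across falls.  Strength maps are represented on a
discrete rectangular lattice of M orientation points with a deterministic
triangulation used for linear interpolation and quadrature.

Real strength maps come from CT-based finite-element models; this module
also provides a synthetic surrogate generator: a subject's surface is a
drawn mean strength times a smooth positive anisotropy field shared across
the population up to per-subject perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import LinearTriInterpolator, Triangulation

from .domain import GeneralTruncNormSpec, Subject

__all__ = [
    "OrientationGrid",
    "StrengthSurface",
    "SurfaceGenParams",
    "AnisotropyShape",
    "build_orientation_grid",
    "integrate_field",
    "interpolate_field",
    "surface_stats",
    "synthesize_shape",
    "synthesize_surface",
]

ALPHA_RANGE = (-30.0, 30.0)
BETA_RANGE = (0.0, 30.0)
DOMAIN_AREA = (ALPHA_RANGE[1] - ALPHA_RANGE[0]) * (BETA_RANGE[1] - BETA_RANGE[0])  # 1800 deg^2

# Rectangular lattice layouts (n_alpha, n_beta) for each supported point count.
_LAYOUTS = {4: (2, 2), 15: (5, 3), 33: (11, 3), 66: (11, 6), 231: (21, 11)}


@dataclass(frozen=True)
class OrientationGrid:
    """M orientation points (degrees) with a triangulation covering the domain."""

    points: np.ndarray  # (M, 2) columns alpha', beta'
    triangles: np.ndarray  # (T, 3) int vertex indices

    @property
    def M(self) -> int:
        return self.points.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])


def build_orientation_grid(M: int) -> OrientationGrid:
    """Rectangular lattice of ``M`` nominally uniformly spaced angle pairs.

    Supported counts and layouts (alpha x beta): 4 -> 2x2, 15 -> 5x3,
    33 -> 11x3, 66 -> 11x6, 231 -> 21x11.  Cells are split along the
    lower-left to upper-right diagonal, so the triangulation is
    deterministic and covers the rectangle exactly.
    """
    if M not in _LAYOUTS:
        raise ValueError(f"unsupported orientation count M={M}; supported: {sorted(_LAYOUTS)}")
    na, nb = _LAYOUTS[M]
    alpha = np.linspace(*ALPHA_RANGE, na)
    beta = np.linspace(*BETA_RANGE, nb)
    aa, bb = np.meshgrid(alpha, beta)  # beta-major rows, alpha varying fastest
    points = np.column_stack([aa.ravel(), bb.ravel()])
    tris = []
    for ib in range(nb - 1):
        for ia in range(na - 1):
            v00 = ib * na + ia
            v10 = v00 + 1
            v01 = v00 + na
            v11 = v01 + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return OrientationGrid(points=points, triangles=np.asarray(tris, dtype=int))


def integrate_field(values, grid: OrientationGrid) -> float:
    """Integrate a nodal field against the uniform orientation density.

    The field is linearly interpolated on the triangulation; the integral of
    the interpolant over each triangle is area times the vertex-value mean,
    and the uniform density divides by the total domain area.  Exact for
    piecewise-linear fields; a constant field integrates to itself.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.M,):
        raise ValueError(f"field must have length M={grid.M}, got {values.shape}")
    areas = grid.triangle_areas()
    tri_means = values[grid.triangles].mean(axis=1)
    return float(np.sum(areas * tri_means) / np.sum(areas))


def quadrature_weights(grid: OrientationGrid) -> np.ndarray:
    """Nodal weights w with ``integrate_field(v, grid) == w @ v`` (sum to 1)."""
    areas = grid.triangle_areas()
    w = np.zeros(grid.M)
    np.add.at(w, grid.triangles, (areas / 3.0)[:, None])
    return w / areas.sum()


def interpolate_field(values, grid: OrientationGrid, alpha, beta):
    """Piecewise-linear interpolation of a nodal field at query orientations."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.M,):
        raise ValueError(f"field must have length M={grid.M}")
    tri = Triangulation(grid.points[:, 0], grid.points[:, 1], grid.triangles)
    out = LinearTriInterpolator(tri, values)(np.asarray(alpha, float), np.asarray(beta, float))
    return np.ma.filled(out, np.nan)


@dataclass
class StrengthSurface:
    """Per-subject femoral strength (N) at each orientation point."""

    subject_id: str
    grid: OrientationGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.M,):
            raise ValueError("values length must equal grid point count")
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError(f"strength values must be finite and positive (subject {self.subject_id})")


def surface_stats(surface: StrengthSurface) -> tuple[float, float, float]:
    """(min, max, mean) strength over the orientation points."""
    v = surface.values
    return float(v.min()), float(v.max()), float(v.mean())


# --- synthetic surrogate generator ------------------------------------------

# Population-mean anisotropy coefficients for (x, y, x^2-1/3, x*y, y^2-1/3)
# with x = alpha'/30 and y = (beta'-15)/15, both in [-1, 1].  Chosen so the
# shared orientation structure dominates per-subject perturbations, giving
# most subjects a surface at least moderately correlated with the
# population-mean surface.
_DEFAULT_SHARED_COEFFS = (0.08, -0.15, -0.10, 0.03, 0.06)


@dataclass(frozen=True)
class SurfaceGenParams:
    """Calibration of the surrogate strength-surface generator.

    ``mean_strength_spec`` is the population distribution of
    orientation-averaged strength; ``shared_coeffs`` fix the population-mean
    anisotropy and ``coeff_sd`` the SD of per-subject coefficient
    perturbations.
    """

    mean_strength_spec: GeneralTruncNormSpec = field(
        default_factory=lambda: GeneralTruncNormSpec(2800.0, 1000.0, 390.0, 6330.0)
    )
    shared_coeffs: tuple = _DEFAULT_SHARED_COEFFS
    coeff_sd: float = 0.05
    M: int = 33


@dataclass(frozen=True)
class AnisotropyShape:
    """A smooth positive orientation field with unit mean over the domain."""

    coeffs: tuple

    def evaluate(self, alpha, beta) -> np.ndarray:
        x = np.asarray(alpha, float) / 30.0
        y = (np.asarray(beta, float) - 15.0) / 15.0
        c = self.coeffs
        # Basis terms are centred over the continuous rectangle, so the
        # continuous mean of f is exactly 1.
        f = 1.0 + c[0] * x + c[1] * y + c[2] * (x**2 - 1.0 / 3.0) + c[3] * x * y + c[4] * (y**2 - 1.0 / 3.0)
        return f


def synthesize_shape(params: SurfaceGenParams, rng: np.random.Generator) -> AnisotropyShape:
    """Draw a per-subject anisotropy shape around the population mean."""
    dev = rng.normal(0.0, params.coeff_sd, size=len(params.shared_coeffs))
    return AnisotropyShape(tuple(np.asarray(params.shared_coeffs) + dev))


def synthesize_surface(
    subject: Subject,
    params: SurfaceGenParams,
    rng: np.random.Generator,
    mean_strength: float | None = None,
    grid: OrientationGrid | None = None,
) -> StrengthSurface:
    """Generate a synthetic strength surface for one subject.

    ``S(alpha', beta') = <S> * f(alpha', beta')`` with ``f`` rescaled to unit
    grid-mean, so the surface's orientation-averaged strength equals ``<S>``
    exactly.  ``<S>`` is drawn from ``params.mean_strength_spec`` unless
    supplied (the cohort generator supplies it so rank correlations with
    mass and height can be induced beforehand).
    """
    if grid is None:
        grid = build_orientation_grid(params.M)
    if mean_strength is None:
        mean_strength = float(params.mean_strength_spec.ppf(rng.uniform(1e-12, 1.0)))
    if mean_strength <= 0:
        raise ValueError("mean strength must be positive")
    shape = synthesize_shape(params, rng)
    f = shape.evaluate(grid.points[:, 0], grid.points[:, 1])
    if np.any(f <= 0):
        raise ValueError("anisotropy field is non-positive; reduce coefficient amplitudes")
    values = mean_strength * f / f.mean()
    return StrengthSurface(subject_id=subject.subject_id, grid=grid, values=values)
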