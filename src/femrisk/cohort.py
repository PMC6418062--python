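"""Synthetic validation-cohort generator and cohort/strength-map I/O.

Generates case-control cohorts with the statistical structure of a
postmenopausal secondary-care referral population: group-wise
anthropometrics drawn from +/-3 SD truncated normals, weak rank
correlations between mass, height and orientation-averaged femoral strength
induced by Iman-Conover, surrogate strength surfaces, and fracture labels
drawn Bernoulli in each subject's ARF0 and then balanced to exactly half
cases.  The label mechanism is synthetic by construction (real labels are
clinical); it provides a tunable, imperfect signal for exercising the
validation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import FixedConstants, FallStochasticModel, Subject, TruncatedNormalSpec
from .risk import run_cohort
from .sampling import iman_conover, lh_sample
from .strength import (
    OrientationGrid,
    StrengthSurface,
    SurfaceGenParams,
    build_orientation_grid,
    synthesize_surface,
)

__all__ = [
    "GroupStats",
    "CohortGeneratorConfig",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "read_strengths",
]

COHORT_COLUMNS = ["subject_id", "group", "fracture_label", "mass_kg", "height_m", "age_yr"]
STRENGTH_COLUMNS = ["subject_id", "alpha_deg", "beta_deg", "strength_N"]


@dataclass(frozen=True)
class GroupStats:
    """Mean and SD of one anthropometric variable within one group."""

    mean: float
    sd: float

    def spec(self) -> TruncatedNormalSpec:
        if self.sd <= 0:
            raise ValueError("SD must be positive")
        return TruncatedNormalSpec(self.mean - 3 * self.sd, self.mean + 3 * self.sd)


@dataclass
class CohortGeneratorConfig:
    """Study conditions of the synthetic validation cohort.

    Defaults reproduce the printed cohort summary: 98 subjects, half per
    group, pair-matched anthropometrics, and weak rank correlations
    r(m,H)=0.429, r(m,<S>)=0.264, r(H,<S>)=0.294.
    """

    n_subjects: int = 98
    m_stats: dict = field(default_factory=lambda: {"fracture": GroupStats(62.6, 14.3), "non-fracture": GroupStats(64.9, 12.1)})
    H_stats: dict = field(default_factory=lambda: {"fracture": GroupStats(1.58, 0.0653), "non-fracture": GroupStats(1.58, 0.0592)})
    age_stats: dict = field(default_factory=lambda: {"fracture": GroupStats(75.4, 9.44), "non-fracture": GroupStats(74.7, 8.86)})
    r_mH: float = 0.429
    r_mS: float = 0.264
    r_HS: float = 0.294
    strength_params: SurfaceGenParams = field(default_factory=SurfaceGenParams)
    label_N: int = 2000  # falls per subject when computing label probabilities


def _rank_corr_matrix(cfg: CohortGeneratorConfig) -> np.ndarray:
    # order: m, H, age, <S>; age independent of everything
    C = np.eye(4)
    C[0, 1] = C[1, 0] = cfg.r_mH
    C[0, 3] = C[3, 0] = cfg.r_mS
    C[1, 3] = C[3, 1] = cfg.r_HS
    return C


def generate_cohort(
    config: CohortGeneratorConfig,
    seed: int,
    fall_model: FallStochasticModel | None = None,
    constants: FixedConstants = FixedConstants(),
) -> tuple[list[Subject], dict[str, StrengthSurface], np.ndarray]:
    """Generate subjects, strength surfaces and balanced fracture labels.

    Returns ``(subjects, surfaces, labels)``; each subject's ``group`` and
    ``fracture_label`` fields reflect the final balanced labels.
    """
    if config.n_subjects % 2 != 0:
        raise ValueError("cohort size must be even (half cases, half controls)")
    fall_model = fall_model or FallStochasticModel()
    root = np.random.SeedSequence(seed)
    ss_groups, ss_surface, ss_labels = root.spawn(3)

    rows = []
    half = config.n_subjects // 2
    corr = _rank_corr_matrix(config)
    for group, ss in zip(("fracture", "non-fracture"), ss_groups.spawn(2)):
        gseed = int(ss.generate_state(1)[0] % (2**31))
        specs = [
            config.m_stats[group].spec(),
            config.H_stats[group].spec(),
            config.age_stats[group].spec(),
            config.strength_params.mean_strength_spec,
        ]
        base = lh_sample(half, specs, seed=gseed, names=["m", "H", "age", "S"])
        sample = iman_conover(base, corr, seed=gseed + 1)
        for m, H, age, S in sample.matrix:
            rows.append({"draw_group": group, "m": m, "H": H, "age": age, "S": S})

    rng_surface = np.random.default_rng(ss_surface)
    grid = build_orientation_grid(config.strength_params.M)
    subjects: list[Subject] = []
    surfaces: dict[str, StrengthSurface] = {}
    for i, row in enumerate(rows):
        sid = f"S{i + 1:03d}"
        subject = Subject(subject_id=sid, m=row["m"], H=row["H"], age=row["age"])
        subjects.append(subject)
        surfaces[sid] = synthesize_surface(
            subject, config.strength_params, rng_surface, mean_strength=row["S"], grid=grid
        )

    # Labels: Bernoulli in each subject's ARF0, then balanced to exactly half cases.
    label_seed = int(ss_labels.generate_state(1)[0] % (2**31))
    results = run_cohort(subjects, surfaces, fall_model, N=config.label_N, seed=label_seed, constants=constants)
    p = np.array([r.ARF0 / 100.0 for r in results])
    rng_labels = np.random.default_rng(ss_labels)
    labels = (rng_labels.random(config.n_subjects) < p).astype(int)
    labels = _balance_labels(labels, p, half, rng_labels)

    for subject, lab in zip(subjects, labels):
        subject.fracture_label = int(lab)
        subject.group = "fracture" if lab else "non-fracture"
    return subjects, surfaces, labels


def _balance_labels(labels: np.ndarray, p: np.ndarray, target_cases: int, rng: np.random.Generator) -> np.ndarray:
    """Resample labels until exactly ``target_cases`` cases remain.

    Excess cases are demoted uniformly at random; missing cases are promoted
    from the controls with probability weights proportional to risk.
    """
    labels = labels.copy()
    cases = np.flatnonzero(labels == 1)
    if len(cases) > target_cases:
        demote = rng.choice(cases, size=len(cases) - target_cases, replace=False)
        labels[demote] = 0
    elif len(cases) < target_cases:
        controls = np.flatnonzero(labels == 0)
        w = p[controls]
        w = w / w.sum() if w.sum() > 0 else np.full(len(controls), 1.0 / len(controls))
        promote = rng.choice(controls, size=target_cases - len(cases), replace=False, p=w)
        labels[promote] = 1
    return labels


def write_cohort(
    subjects: Sequence[Subject],
    surfaces: Mapping[str, StrengthSurface],
    cohort_path,
    strength_path,
) -> None:
    """Write the cohort table and the long-format strength map as CSV."""
    cohort = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "fracture_label": s.fracture_label,
                "mass_kg": s.m,
                "height_m": s.H,
                "age_yr": s.age,
            }
            for s in subjects
        ],
        columns=COHORT_COLUMNS,
    )
    cohort.to_csv(cohort_path, index=False)

    recs = []
    for s in subjects:
        surface = surfaces[s.subject_id]
        for (a, b), v in zip(surface.grid.points, surface.values):
            recs.append({"subject_id": s.subject_id, "alpha_deg": a, "beta_deg": b, "strength_N": v})
    pd.DataFrame(recs, columns=STRENGTH_COLUMNS).to_csv(strength_path, index=False)


def read_cohort(cohort_path) -> list[Subject]:
    """Read a cohort CSV back into Subject records."""
    df = pd.read_csv(cohort_path, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {cohort_path} lacks columns: {sorted(missing)}")
    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            Subject(
                subject_id=str(row["subject_id"]),
                m=float(row["mass_kg"]),
                H=float(row["height_m"]),
                age=None if pd.isna(row["age_yr"]) else float(row["age_yr"]),
                group=None if pd.isna(row["group"]) else str(row["group"]),
                fracture_label=None if pd.isna(row["fracture_label"]) else int(row["fracture_label"]),
            )
        )
    return subjects


def read_strengths(strength_path) -> dict[str, StrengthSurface]:
    """Read a long-format strength CSV, validating grid completeness per subject."""
    df = pd.read_csv(strength_path, float_precision="round_trip")
    missing = set(STRENGTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"strength file {strength_path} lacks columns: {sorted(missing)}")
    surfaces: dict[str, StrengthSurface] = {}
    grids: dict[int, OrientationGrid] = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        M = len(sub)
        if M not in grids:
            try:
                grids[M] = build_orientation_grid(M)
            except ValueError as exc:
                raise ValueError(f"subject {sid}: {M} orientation rows match no supported grid") from exc
        grid = grids[M]
        key = {(round(a, 6), round(b, 6)): v for a, b, v in zip(sub["alpha_deg"], sub["beta_deg"], sub["strength_N"])}
        values = np.empty(M)
        for i, (a, b) in enumerate(grid.points):
            k = (round(a, 6), round(b, 6))
            if k not in key:
                raise ValueError(f"subject {sid}: missing strength at orientation (alpha={a}, beta={b})")
            values[i] = key[k]
        surfaces[str(sid)] = StrengthSurface(subject_id=str(sid), grid=grid, values=values)
    return surfaces
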