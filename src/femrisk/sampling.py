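"""Seeded random-variate machinery.

Provides the truncated-normal inverse CDF, inverse-transformed Latin
hypercube (LH) sampling and Iman-Conover rank-correlation induction.  All
randomness flows from a single integer root seed through
``numpy.random.SeedSequence`` spawns, so that adding or removing columns
never reshuffles unrelated columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .domain import TruncatedNormalSpec

__all__ = ["LHSample", "truncnorm_ppf", "lh_sample", "iman_conover"]


@dataclass
class LHSample:
    """A Latin-hypercube sample: N rows by d columns in native units.

    Each column is marginally stratified: exactly one draw falls in each
    probability stratum of width 1/N of its marginal distribution.
    """

    matrix: np.ndarray
    seed: int
    specs: Sequence
    names: Sequence[str] | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


def truncnorm_ppf(q, spec: TruncatedNormalSpec):
    """Inverse CDF of a +/-3 SD truncated normal, in native units.

    ``value = mu + sigma * Phi^-1(Phi(-3) + q*(Phi(3) - Phi(-3)))``.
    """
    return spec.ppf(q)


def _column_uniforms(n: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified uniforms: one jittered draw per stratum, randomly permuted."""
    perm = rng.permutation(n)
    jitter = rng.random(n)
    return (perm + jitter) / n


def lh_sample(n: int, specs: Sequence, seed: int, names: Sequence[str] | None = None) -> LHSample:
    """Draw an inverse-transformed Latin-hypercube sample.

    Parameters
    ----------
    n : int
        Sample size (>= 2).
    specs : sequence
        Per-column distribution specs; anything with a ``.ppf`` method
        (``TruncatedNormalSpec``, ``UniformSpec``, ...).
    seed : int
        Root seed; per-column substreams are spawned from it.
    """
    if n < 2:
        raise ValueError("LH sample size must be at least 2")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs))
    cols = []
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        u = _column_uniforms(n, rng)
        cols.append(np.asarray(spec.ppf(u), dtype=float))
    return LHSample(np.column_stack(cols), seed=seed, specs=list(specs), names=names)


def iman_conover(sample: LHSample, target_rank_corr: np.ndarray, seed: int | None = None) -> LHSample:
    """Induce a target Spearman rank-correlation structure on a sample.

    Classic Iman-Conover: van der Waerden scores are given the target
    correlation by a Cholesky adjustment, and each data column is reordered
    to match the ranks of the adjusted scores.  Marginal multisets are
    untouched (the operation is a within-column permutation).

    The target is interpreted as Spearman correlation; it is converted to
    the equivalent Pearson correlation of the underlying normal scores via
    ``2*sin(pi*r_s/6)`` before the adjustment.
    """
    C = np.asarray(target_rank_corr, dtype=float)
    d = sample.d
    if C.shape != (d, d):
        raise ValueError(f"target matrix must be {d}x{d}")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("target matrix must be symmetric with unit diagonal")
    # Spearman -> Pearson-on-normal-scores conversion.
    Cp = 2.0 * np.sin(np.pi * C / 6.0)
    np.fill_diagonal(Cp, 1.0)
    try:
        P = np.linalg.cholesky(Cp)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target rank-correlation matrix is not positive definite") from exc

    n = sample.n
    rng = np.random.default_rng(
        np.random.SeedSequence(sample.seed if seed is None else seed).spawn(1)[0].entropy % (2**32)
    )
    scores = norm.ppf(np.arange(1, n + 1) / (n + 1.0))
    M = np.column_stack([rng.permutation(scores) for _ in range(d)])
    E = np.corrcoef(M, rowvar=False)
    # the empirical score correlation can be singular for tiny n; shrink
    # toward the identity just enough to factorise
    jitter = 0.0
    while True:
        try:
            Q = np.linalg.cholesky((1 - jitter) * E + jitter * np.eye(d))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0.0 else jitter * 10
            if jitter > 0.1:
                raise
    # M* has correlation ~Cp while keeping each column a permutation of scores' ranks.
    M_star = M @ np.linalg.inv(Q).T @ P.T

    out = np.empty_like(sample.matrix)
    for j in range(d):
        order = rankdata(M_star[:, j], method="ordinal").astype(int) - 1
        col_sorted = np.sort(sample.matrix[:, j])
        out[:, j] = col_sorted[order]
    return LHSample(out, seed=sample.seed, specs=sample.specs, names=sample.names)
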