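"""Statistical validation of ARF0 against fracture labels.

Group comparison (Mann-Whitney), calibration of a univariate logistic model
(Hosmer-Lemeshow) and classification performance (empirical ROC, trapezoid
AUC with a stratified-bootstrap CI, Youden-optimal threshold, Wilson CIs for
sensitivity and specificity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ClassificationReport",
    "mann_whitney",
    "roc_analysis",
    "hosmer_lemeshow",
    "validate_arf0",
    "roc_curve_table",
]


@dataclass
class ClassificationReport:
    """Classification of fracture status by a continuous risk score."""

    auc: float
    auc_ci: tuple[float, float]
    threshold: float  # score units (ARF0 %, when scoring with ARF0)
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    mw_p: float | None = None
    hl_p: float | None = None
    extra: dict = field(default_factory=dict)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float], alternative: str = "two-sided"):
    """Mann-Whitney U test; exact for small tie-free groups, else tie-corrected normal.

    Returns (U, p) with U the statistic of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = a.size <= 10 and b.size <= 10
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus outer sentinels."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ClassificationReport:
    """Empirical ROC analysis; higher scores indicate the positive class.

    AUC by the trapezoid rule (equivalently the tie-adjusted rank statistic);
    its CI by a stratified bootstrap.  The operating threshold maximises the
    Youden index over midpoints between adjacent observed scores, ties broken
    toward higher specificity (higher threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have matching shapes")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")

    auc = float(roc_auc_score(y, s))

    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    boots = []
    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        boots.append(roc_auc_score(y[idx], s[idx]))
    alpha = 1.0 - ci_level
    auc_ci = tuple(np.quantile(boots, [alpha / 2, 1 - alpha / 2]))

    best = None  # (J, threshold, sens, spec); prefer higher threshold on J ties
    for t in _candidate_thresholds(s):
        pred = s >= t
        sens = np.mean(pred[pos])
        spec = np.mean(~pred[neg])
        J = sens + spec - 1.0
        if best is None or J > best[0] + 1e-12 or (abs(J - best[0]) <= 1e-12 and t > best[1]):
            best = (J, t, sens, spec)
    _, thr, sens, spec = best

    sens_ci = proportion_confint(int(round(sens * len(pos))), len(pos), alpha=alpha, method="wilson")
    spec_ci = proportion_confint(int(round(spec * len(neg))), len(neg), alpha=alpha, method="wilson")
    return ClassificationReport(
        auc=auc,
        auc_ci=(float(auc_ci[0]), float(auc_ci[1])),
        threshold=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        sens_ci=(float(sens_ci[0]), float(sens_ci[1])),
        spec_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )


def roc_curve_table(scores: Sequence[float], labels: Sequence[int]):
    """(threshold, sensitivity, specificity) rows over all candidate thresholds."""
    import pandas as pd

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = y == 1, y == 0
    rows = []
    for t in _candidate_thresholds(s):
        pred = s >= t
        rows.append({"threshold": t, "sensitivity": np.mean(pred[pos]), "specificity": np.mean(~pred[neg])})
    return pd.DataFrame(rows)


def hosmer_lemeshow(probabilities: Sequence[float], labels: Sequence[int], g: int = 10):
    """Hosmer-Lemeshow decile-of-risk goodness-of-fit test.

    Groups the fitted probabilities into ``g`` quantile bins (degenerate bins
    are merged), and compares observed and expected event counts with a
    chi-square statistic on ``groups - 2`` degrees of freedom.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have matching shapes")
    if g > p.size:
        raise ValueError("more groups than observations")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)))
    if len(edges) - 1 < g:
        import warnings

        warnings.warn(f"degenerate probability groups merged: {g} -> {len(edges) - 1}", stacklevel=2)
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    chi2 = 0.0
    n_groups = 0
    for b in np.unique(bins):
        mask = bins == b
        n = int(mask.sum())
        o1 = int(y[mask].sum())
        e1 = float(p[mask].sum())
        e0 = n - e1
        n_groups += 1
        if e1 > 0:
            chi2 += (o1 - e1) ** 2 / e1
        if e0 > 0:
            chi2 += ((n - o1) - e0) ** 2 / e0
    df = max(n_groups - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df))


def validate_arf0(arf0: Sequence[float], labels: Sequence[int], seed: int = 0, g: int = 10) -> ClassificationReport:
    """Full validation battery for ARF0 scores against binary fracture labels.

    Fits a univariate logistic regression of label on ARF0 (maximum
    likelihood) for the calibration test, and fills the Mann-Whitney and
    Hosmer-Lemeshow p-values into the classification report.
    """
    s = np.asarray(arf0, dtype=float)
    y = np.asarray(labels, dtype=int)
    report = roc_analysis(s, y, seed=seed)
    _, report.mw_p = mann_whitney(s[y == 1], s[y == 0])
    X = sm.add_constant(s)
    fit = sm.Logit(y, X).fit(disp=0)
    probs = fit.predict(X)
    _, report.hl_p = hosmer_lemeshow(probs, y, g=g)
    report.extra["logit_params"] = fit.params.tolist()
    report.extra["group_means"] = {"fracture": float(s[y == 1].mean()), "non-fracture": float(s[y == 0].mean())}
    return report
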