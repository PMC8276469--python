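"""Validation statistics for dental-age predictors.

Error convention throughout: ``error = chronological age - estimated age``
(negative = overestimation).  The headline summaries are the mean error (ME,
bias direction), mean absolute error (MAE, magnitude) and root mean square
error (RMSE, variance-weighted magnitude), the latter with a subject-level
percentile-bootstrap 95% confidence interval.  Paired method comparisons and
the Wilcoxon signed-rank test follow the same convention; observer agreement
on the ordinal stage scale uses weighted kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, SEXES
from .scoring import CoefficientTable, PredictionOutcome, predict_cohort
from .stages import STAGES, StageCode


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float  # W+ = sum of ranks of positive differences
    n_used: int  # pairs remaining after zero-differences are dropped
    n_zeros: int
    method: str  # "exact" | "normal_approx" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


#: sample size at or below which the exact signed-rank distribution is used
EXACT_N_MAX = 25


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p via the signed-rank sum distribution.

    Enumerates the null distribution of W+ (each rank positive or negative
    with probability 1/2) by dynamic programming over doubled ranks, which are
    integers even with midranks from ties.
    """
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = (dist + shifted) / 2.0
    w2 = int(round(w_plus * 2))
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Optional[Sequence[float]] = None
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Zero differences are dropped (classic convention; the count is reported).
    Ties receive midranks.  Exact enumeration for <= 25 non-zero pairs,
    otherwise a normal approximation with continuity and tie correction.
    If every difference is zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    nz = d[d != 0]
    n_zeros = int(d.size - nz.size)
    if nz.size == 0:
        return WilcoxonResult(1.0, 0.0, 0, n_zeros, "degenerate")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    n = nz.size
    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(p, w_plus, n, n_zeros, "exact")
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(np.abs(nz), return_counts=True)
    tie_corr = float(((counts**3 - counts).sum()) / 48.0)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(min(1.0, p), w_plus, n, n_zeros, "normal_approx")


# ---------------------------------------------------------------------------
# error summaries


@dataclass(frozen=True)
class ValidationSummary:
    """ME / MAE / RMSE for one group of prediction outcomes."""

    group: str
    n: int
    me: float
    me_sd: float
    mae: float
    mae_sd: float
    rmse: float
    rmse_ci: tuple[float, float]
    wilcoxon_p: float
    flags: tuple[str, ...] = ()


def _rmse_bootstrap_ci(
    errors: np.ndarray, ci_reps: int, rng: np.random.Generator, level: float = 0.95
) -> tuple[float, float]:
    n = errors.size
    idx = rng.integers(0, n, size=(ci_reps, n))
    boot = np.sqrt(np.mean(errors[idx] ** 2, axis=1))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def error_summary(
    outcomes: Sequence[PredictionOutcome],
    group: str = "M+F",
    ci_reps: int = 2000,
    seed: Optional[int] = None,
) -> ValidationSummary:
    """Summarise signed and absolute prediction errors for one group.

    ME/MAE are sample means, their SDs use n-1; RMSE = sqrt(mean(error^2))
    with a subject-level percentile bootstrap 95% CI; the Wilcoxon p compares
    chronological with estimated ages (i.e. tests the errors against zero).
    """
    if len(outcomes) == 0:
        raise ValueError("no outcomes to summarise")
    errors = np.array([o.error for o in outcomes], dtype=float)
    n = errors.size
    flags = []
    me = float(errors.mean())
    mae = float(np.abs(errors).mean())
    rmse = float(np.sqrt(np.mean(errors**2)))
    if n > 1:
        me_sd = float(errors.std(ddof=1))
        mae_sd = float(np.abs(errors).std(ddof=1))
        rng = np.random.default_rng(seed)
        ci = _rmse_bootstrap_ci(errors, ci_reps, rng)
    else:
        me_sd = mae_sd = float("nan")
        ci = (float("nan"), float("nan"))
        flags.append("single_subject")
    wres = wilcoxon_signed_rank(errors)
    if wres.degenerate:
        flags.append("wilcoxon_degenerate")
    return ValidationSummary(
        group=group,
        n=n,
        me=me,
        me_sd=me_sd,
        mae=mae,
        mae_sd=mae_sd,
        rmse=rmse,
        rmse_ci=ci,
        wilcoxon_p=wres.p_value,
        flags=tuple(flags),
    )


def summarize_by_sex(
    cohort: Cohort,
    table: CoefficientTable,
    ci_reps: int = 2000,
    seed: Optional[int] = None,
) -> list[ValidationSummary]:
    """Validation summaries overall and per sex (rows M+F, M, F)."""
    outcomes = predict_cohort(table, cohort)
    by_sex = {s: [] for s in SEXES}
    for o, r in zip(outcomes, cohort):
        by_sex[r.sex].append(o)
    rows = [error_summary(outcomes, "M+F", ci_reps, seed)]
    for s in SEXES:
        if by_sex[s]:
            rows.append(error_summary(by_sex[s], s, ci_reps, seed))
    return rows


# ---------------------------------------------------------------------------
# paired method comparison


@dataclass(frozen=True)
class GroupComparison:
    group: str
    n: int
    me_a: float
    me_b: float
    me_diff: float
    me_diff_sd: float
    p_me: float
    mae_a: float
    mae_b: float
    mae_diff: float
    mae_diff_sd: float
    p_mae: float
    rmse_a: float
    rmse_a_ci: tuple[float, float]
    rmse_b: float
    rmse_b_ci: tuple[float, float]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class MethodComparison:
    """Per-group paired comparison of two coefficient tables (A vs B)."""

    table_a: str
    table_b: str
    groups: dict[str, GroupComparison]


def _compare_group(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    group: str,
    ci_reps: int,
    rng: np.random.Generator,
) -> GroupComparison:
    flags = []
    d_signed = errors_a - errors_b
    d_abs = np.abs(errors_a) - np.abs(errors_b)
    p_me = wilcoxon_signed_rank(d_signed)
    p_mae = wilcoxon_signed_rank(d_abs)
    if p_me.degenerate or p_mae.degenerate:
        flags.append("wilcoxon_degenerate")
    n = errors_a.size
    sd = lambda v: float(np.std(v, ddof=1)) if n > 1 else float("nan")
    return GroupComparison(
        group=group,
        n=n,
        me_a=float(errors_a.mean()),
        me_b=float(errors_b.mean()),
        me_diff=float(d_signed.mean()),
        me_diff_sd=sd(d_signed),
        p_me=p_me.p_value,
        mae_a=float(np.abs(errors_a).mean()),
        mae_b=float(np.abs(errors_b).mean()),
        mae_diff=float(d_abs.mean()),
        mae_diff_sd=sd(d_abs),
        p_mae=p_mae.p_value,
        rmse_a=float(np.sqrt(np.mean(errors_a**2))),
        rmse_a_ci=_rmse_bootstrap_ci(errors_a, ci_reps, rng),
        rmse_b=float(np.sqrt(np.mean(errors_b**2))),
        rmse_b_ci=_rmse_bootstrap_ci(errors_b, ci_reps, rng),
        flags=tuple(flags),
    )


def compare_methods(
    cohort: Cohort,
    table_a: CoefficientTable,
    table_b: CoefficientTable,
    ci_reps: int = 2000,
    seed: Optional[int] = None,
) -> MethodComparison:
    """Paired per-subject comparison of two score tables on one cohort.

    Differences are A - B computed per subject then averaged; Wilcoxon
    signed-rank p-values test the signed-error pairs (``p_me``) and the
    absolute-error pairs (``p_mae``).  Groups: M+F, M, F.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out_a = predict_cohort(table_a, cohort)
    out_b = predict_cohort(table_b, cohort)
    ea = np.array([o.error for o in out_a])
    eb = np.array([o.error for o in out_b])
    sexes = np.array([r.sex for r in cohort])
    rng = np.random.default_rng(seed)
    groups = {"M+F": _compare_group(ea, eb, "M+F", ci_reps, rng)}
    for s in SEXES:
        m = sexes == s
        if m.any():
            groups[s] = _compare_group(ea[m], eb[m], s, ci_reps, rng)
    return MethodComparison(
        table_a=table_a.name or "A", table_b=table_b.name or "B", groups=groups
    )


# ---------------------------------------------------------------------------
# calibration


def calibration_slope(
    chron: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float]:
    """OLS line of predicted age on chronological age: (slope, intercept).

    Slope 1 / intercept 0 indicates perfect calibration.
    """
    x = np.asarray(chron, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("chronological ages have zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def plot_calibration(chron, predicted, ax=None, **scatter_kw):
    """Scatter of predicted vs chronological age with the calibration line.

    Requires matplotlib (``pip install dentage[plot]``).
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    slope, intercept = calibration_slope(chron, predicted)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(chron, predicted, s=8, alpha=0.5, **scatter_kw)
    xs = np.array([min(chron), max(chron)])
    ax.plot(xs, slope * xs + intercept, label=f"slope {slope:.3f}")
    ax.plot(xs, xs, linestyle=":", label="identity")
    ax.set_xlabel("chronological age (y)")
    ax.set_ylabel("predicted age (y)")
    ax.legend()
    return ax


# ---------------------------------------------------------------------------
# observer agreement


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weighting: str
    n_items: int
    flags: tuple[str, ...] = ()


def weighted_kappa(
    r1: Sequence[StageCode],
    r2: Sequence[StageCode],
    weighting: str = "linear",
) -> KappaResult:
    """Weighted Cohen's kappa on the 9-level ordinal stage scale (0, A-H).

    kappa = 1 - sum(w * O) / sum(w * E) with disagreement weights
    w_ij = |i - j| / (k - 1) (linear) or its square (quadratic); E is the
    product of the two raters' marginals.  If either rater shows no variation
    kappa is undefined (NaN, flagged).
    """
    if weighting not in ("linear", "quadratic"):
        raise ValueError("weighting must be 'linear' or 'quadratic'")
    a = np.array([s.rank for s in r1])
    b = np.array([s.rank for s in r2])
    if a.size != b.size:
        raise ValueError("rating vectors must have equal length")
    if a.size == 0:
        raise ValueError("empty rating vectors")
    k = len(STAGES)
    observed = np.zeros((k, k))
    np.add.at(observed, (a, b), 1.0)
    n = a.size
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    ij = np.arange(k)
    w = np.abs(ij[:, None] - ij[None, :]) / (k - 1)
    if weighting == "quadratic":
        w = w**2
    denom = float((w * expected).sum())
    if denom == 0.0:
        return KappaResult(float("nan"), weighting, n, ("no_variation",))
    kappa = 1.0 - float((w * observed).sum()) / denom
    return KappaResult(kappa, weighting, n, ())
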