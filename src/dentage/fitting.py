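"""Fit country-specific Willems coefficient tables by weighted ANOVA.

The model regresses chronological age on the seven teeth's stage indicators:

    age_i = b0 + sum_t beta[t, stage_i(t)] + eps_i,

one categorical block per tooth, reference level = the lowest stage observed
for that tooth (coefficient 0).  After fitting, the intercept is *folded* into
tooth 31's coefficients so that a prediction is a pure seven-term table sum —
the form in which Willems-style tables are published.  Folding is
prediction-invariant; it merely moves b0 into every tooth-31 entry.

Weighting.  The original methodology is described only as "weighted analysis
of variance"; two reproducible schemes are built in:

* ``uniform`` — ordinary least squares (all weights 1);
* ``inv_var_ageband`` (default) — two-pass feasible WLS: an OLS first pass,
  residual variance per 1-year chronological-age band, then weights equal to
  the inverse band variance.  Bands with fewer than 2 records (or zero
  variance) fall back to the pooled residual variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort, DentitionRecord, SEXES, TEETH
from .scoring import CoefficientTable
from .stages import StageCode

WEIGHTING_SCHEMES = ("uniform", "inv_var_ageband")


class FitError(ValueError):
    """The training design cannot be fitted (empty, rank-deficient...)."""


class SmallStratumWarning(UserWarning):
    """A stratum of size 1 cannot be split; its record goes to training."""


class PartialFitWarning(UserWarning):
    """Only one sex present in training; the returned table is partial."""


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split parameters.

    Strata are (sex x age band); each stratum contributes round-half-up
    ``n * test_fraction`` records to the test set, the remainder to training.
    """

    test_fraction: float
    seed: int
    age_band_width: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.age_band_width <= 0:
            raise ValueError("age_band_width must be positive")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Partition a cohort into (train, test), stratified by sex and age band.

    Deterministic given the seed; records keep their cohort order within each
    part.  A stratum of size 1 raises :class:`SmallStratumWarning` and sends
    its record to training.
    """
    if len(cohort) == 0:
        raise FitError("cannot split an empty cohort")
    strata: dict[tuple[str, int], list[int]] = {}
    for i, r in enumerate(cohort):
        band = int(math.floor(r.chron_age / spec.age_band_width))
        strata.setdefault((r.sex, band), []).append(i)

    rng = np.random.default_rng(spec.seed)
    test_idx: set[int] = set()
    for key in sorted(strata):
        idx = strata[key]
        if len(idx) == 1:
            warnings.warn(
                f"stratum {key} has a single record; assigned to training",
                SmallStratumWarning,
                stacklevel=2,
            )
            continue
        n_test = min(_round_half_up(len(idx) * spec.test_fraction), len(idx))
        chosen = rng.permutation(len(idx))[:n_test]
        test_idx.update(idx[j] for j in chosen)

    records = list(cohort)
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return (
        Cohort(train, provenance=f"{cohort.provenance} [train]"),
        Cohort(test, provenance=f"{cohort.provenance} [test]"),
    )


@dataclass
class FitResult:
    """A fitted coefficient table plus fit diagnostics."""

    table: CoefficientTable
    fitted_on: str
    weighting: str
    weights_used: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _stage_groups(
    records: Sequence[DentitionRecord], min_cell: int
) -> dict[int, list[list[StageCode]]]:
    """Group each tooth's observed stages, merging sparse cells downward.

    A non-lowest stage observed fewer than ``min_cell`` times joins the group
    of the adjacent lower observed stage (they share a coefficient).  With
    ``min_cell=1`` every observed stage forms its own group.
    """
    groups: dict[int, list[list[StageCode]]] = {}
    for t in TEETH:
        counts: dict[StageCode, int] = {}
        for r in records:
            counts[r.stages[t]] = counts.get(r.stages[t], 0) + 1
        levels = sorted(counts, key=lambda s: s.rank)
        tooth_groups: list[list[StageCode]] = [[levels[0]]]
        for s in levels[1:]:
            if counts[s] < min_cell:
                tooth_groups[-1].append(s)
            else:
                tooth_groups.append([s])
        groups[t] = tooth_groups
    return groups


def _group_label(tooth: int, group: Sequence[StageCode]) -> str:
    return f"t{tooth}:" + "+".join(s.value for s in group)


def _design(
    records: Sequence[DentitionRecord],
    groups: dict[int, list[list[StageCode]]],
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, tuple[StageCode, ...]]]]:
    """Dummy-coded design matrix with intercept first.

    Returns (X, y, column labels [(tooth, stage-group)...]).
    The first (lowest) group of each tooth is the reference (no column).
    """
    columns: list[tuple[int, tuple[StageCode, ...]]] = [
        (t, tuple(g)) for t in TEETH for g in groups[t][1:]
    ]
    col_of: dict[tuple[int, StageCode], int] = {}
    for j, (t, g) in enumerate(columns):
        for s in g:
            col_of[(t, s)] = j
    n, p = len(records), len(columns)
    X = np.zeros((n, 1 + p))
    X[:, 0] = 1.0
    y = np.empty(n)
    for i, r in enumerate(records):
        y[i] = r.chron_age
        for t in TEETH:
            j = col_of.get((t, r.stages[t]))
            if j is not None:
                X[i, 1 + j] = 1.0
    return X, y, columns


def _aliased_columns(X: np.ndarray, labels: list) -> list:
    """Columns whose removal does not reduce rank (members of a collinear set)."""
    full_rank = np.linalg.matrix_rank(X)
    aliased = []
    for j in range(1, X.shape[1]):  # never blame the intercept
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == full_rank:
            aliased.append(labels[j - 1])
    return aliased


def _ageband_weights(
    y: np.ndarray, resid: np.ndarray, band_width: float
) -> np.ndarray:
    bands = np.floor(y / band_width).astype(int)
    pooled = float(np.var(resid, ddof=1)) if len(resid) > 1 else 1.0
    if pooled <= 0:
        pooled = 1.0
    var = np.full(len(y), pooled)
    for b in np.unique(bands):
        m = bands == b
        if m.sum() >= 2:
            v = float(np.var(resid[m], ddof=1))
            if v > 0:
                var[m] = v
    return 1.0 / var


def fit_coefficients(
    train: Cohort,
    sex: str,
    weighting: str = "inv_var_ageband",
    age_band_width: float = 1.0,
    min_cell: int = 1,
    on_deficiency: str = "error",
) -> FitResult:
    """Fit one sex's coefficient table by (weighted) least squares.

    The returned table stores an entry for every (tooth, stage) observed in
    training: tooth 31 carries the folded intercept (its reference stage's
    entry *is* the intercept), teeth 32-37 store their reference stage as an
    explicit 0.  Predictions with the table reproduce the regression's fitted
    values exactly.

    ``min_cell > 1`` merges a stage observed fewer than ``min_cell`` times
    into the adjacent lower stage (the two share a score) — sparse cells from
    boundary ages otherwise produce exactly collinear indicator columns.

    ``on_deficiency`` controls what happens when the design is still rank
    deficient: ``"error"`` (default) raises a :class:`FitError` naming the
    aliased stage levels; ``"coarsen"`` deterministically merges the sparsest
    aliased stage group into the stage group below it within the same tooth,
    repeating until the design is identifiable (merges are recorded in the
    diagnostics).
    """
    if weighting not in WEIGHTING_SCHEMES:
        raise ValueError(f"weighting must be one of {WEIGHTING_SCHEMES}")
    if on_deficiency not in ("error", "coarsen"):
        raise ValueError("on_deficiency must be 'error' or 'coarsen'")
    records = [r for r in train if r.sex == sex]
    if not records:
        raise FitError(f"no {sex} records in training cohort")
    if any(r.has_missing() for r in records):
        raise FitError("training cohort contains records with MISSING stages")

    groups = _stage_groups(records, min_cell)
    if all(len(groups[t]) == 1 for t in TEETH):
        raise FitError(
            "no stage variation in training cohort; stage coefficients are "
            "unidentifiable"
        )
    while True:
        X, y, columns = _design(records, groups)
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        aliased = _aliased_columns(X, columns)
        if on_deficiency == "error" or not aliased:
            names = ", ".join(_group_label(t, g) for t, g in aliased) or "unidentified"
            raise FitError(
                f"design matrix is rank deficient; aliased stage levels: {names}"
            )
        # merge the sparsest aliased group into the group below it
        col_counts = {c: int(X[:, 1 + j].sum()) for j, c in enumerate(columns)}
        t, g = min(aliased, key=lambda c: (col_counts[c], c[0], c[1][0].rank))
        gi = groups[t].index(list(g))
        groups[t][gi - 1].extend(groups[t].pop(gi))

    w = np.ones(len(y))
    if weighting == "inv_var_ageband":
        ols = sm.WLS(y, X, weights=w).fit()
        w = _ageband_weights(y, np.asarray(ols.resid), age_band_width)
    res = sm.WLS(y, X, weights=w).fit()
    intercept = float(res.params[0])
    coefs = {c: float(b) for c, b in zip(columns, res.params[1:])}

    entries: dict[tuple[str, int, StageCode], float] = {}
    for t in TEETH:
        fold = intercept if t == 31 else 0.0
        for s in groups[t][0]:  # reference group
            entries[(sex, t, s)] = fold
        for (tt, g), b in coefs.items():
            if tt == t:
                for s in g:
                    entries[(sex, t, s)] = b + fold

    resid = y - X @ res.params
    bands = np.floor(y / age_band_width).astype(int)
    merged = [
        _group_label(t, g)
        for t in TEETH
        for g in groups[t]
        if len(g) > 1
    ]
    diagnostics = {
        "residual_sd": float(np.std(resid, ddof=1)) if len(y) > 1 else float("nan"),
        "n": len(y),
        "per_band_counts": {int(b): int((bands == b).sum()) for b in np.unique(bands)},
        "reference_stages": {t: groups[t][0][0].value for t in TEETH},
        "merged_stage_groups": merged,
    }
    table = CoefficientTable(
        entries,
        name=f"fit_{sex}",
        provenance=f"weighted-ANOVA fit ({weighting}) on {train.provenance or 'cohort'}",
    )
    return FitResult(
        table=table,
        fitted_on=train.provenance,
        weighting=weighting,
        weights_used={sex: w},
        diagnostics={sex: diagnostics},
    )


def fit_both_sexes(
    train: Cohort,
    weighting: str = "inv_var_ageband",
    age_band_width: float = 1.0,
    min_cell: int = 1,
    on_deficiency: str = "error",
) -> FitResult:
    """Independent per-sex fits concatenated into one table.

    If one sex is absent the result is a partial table and a
    :class:`PartialFitWarning` is raised.
    """
    entries: dict = {}
    weights: dict = {}
    diagnostics: dict = {}
    present = [s for s in SEXES if any(r.sex == s for r in train)]
    if not present:
        raise FitError("empty training cohort")
    if len(present) < len(SEXES):
        missing = [s for s in SEXES if s not in present]
        warnings.warn(
            f"sex {missing[0]} absent from training; returning a partial table",
            PartialFitWarning,
            stacklevel=2,
        )
    for s in present:
        fr = fit_coefficients(
            train, s, weighting=weighting, age_band_width=age_band_width,
            min_cell=min_cell, on_deficiency=on_deficiency,
        )
        entries.update(fr.table.entries)
        weights.update(fr.weights_used)
        diagnostics.update(fr.diagnostics)
    table = CoefficientTable(
        entries,
        name="fit_MF",
        provenance=f"weighted-ANOVA fit ({weighting}) on {train.provenance or 'cohort'}",
    )
    return FitResult(
        table=table,
        fitted_on=train.provenance,
        weighting=weighting,
        weights_used=weights,
        diagnostics=diagnostics,
    )
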