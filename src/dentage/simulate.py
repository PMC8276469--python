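"""Synthetic staged cohorts with the structure seven-tooth age methods assume.

Latent maturation model.  Each child i has a chronological age ``a_i`` and a
maturation tempo offset ``delta_i ~ N(0, sigma_child)`` shared by all teeth
(children are systematically early or late maturers); each tooth t adds an
independent timing wobble ``eps_it ~ N(0, sigma_tooth)``.  A tooth's observed
stage is the highest stage s whose mean attainment age ``mu[sex, t, s]`` lies
at or below the child's effective maturation age ``a_i + delta_i + eps_it``;
below stage A's attainment age the tooth is at stage 0.  Stages are therefore
ordinal, monotone in age, correlated across teeth within a child, and
sex-specific — the features fitting and validation rely on.

``default_params_like_study`` calibrates the attainment ages so that, for ages
uniform on the study range (4-16 y), the marginal stage frequencies match a
packaged per-(sex, tooth) reference frequency table from a Saudi Arabian
sample of 1146 children.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, DentitionRecord, SEXES, TEETH
from .scoring import CoefficientTable, estimate_age
from .stages import STAGES, StageCode

#: stages with attainment-age parameters (A..H; stage 0 is "before A")
ATTAINABLE: tuple[StageCode, ...] = STAGES[1:]

#: floor applied to non-positive synthetic ages (years)
AGE_FLOOR = 0.1


@dataclass
class MaturationParams:
    """Per-tooth stage-attainment timelines for the latent maturation model.

    ``mu[(sex, tooth)]`` is a length-8 array of mean attainment ages (years)
    for stages A..H, strictly increasing.
    """

    mu: Mapping[tuple[str, int], np.ndarray]
    sigma_child: float = 0.7
    sigma_tooth: float = 0.9
    age_range: tuple[float, float] = (4.0, 16.0)
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu = {k: np.asarray(v, dtype=float) for k, v in self.mu.items()}
        for (sex, tooth), m in self.mu.items():
            if sex not in SEXES or tooth not in TEETH:
                raise ValueError(f"bad mu key ({sex}, {tooth})")
            if m.shape != (len(ATTAINABLE),):
                raise ValueError(f"mu[{sex},{tooth}] must have {len(ATTAINABLE)} entries")
            if not np.all(np.diff(m) > 0):
                raise ValueError(f"mu[{sex},{tooth}] must be strictly increasing")
        missing = [(s, t) for s in SEXES for t in TEETH if (s, t) not in self.mu]
        if missing:
            raise ValueError(f"mu missing keys: {missing}")
        if self.sigma_child < 0 or self.sigma_tooth < 0:
            raise ValueError("sigmas must be non-negative")
        lo, hi = self.age_range
        if not lo < hi or lo <= 0:
            raise ValueError("age_range must satisfy 0 < min < max")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")


def stage_from_maturation(mu_t: np.ndarray, effective_age: float) -> StageCode:
    """Highest stage attained at an effective maturation age (stage 0 if none)."""
    idx = int(np.searchsorted(mu_t, effective_age, side="right"))
    return STAGES[idx]  # idx 0 -> stage 0, idx 8 -> H


def generate_cohort(
    params: MaturationParams,
    n: int,
    age_band_counts: Optional[Mapping[int, int]] = None,
    seed: Optional[int] = None,
) -> Cohort:
    """Draw a synthetic staged cohort of ``n`` children.

    Ages are uniform on ``params.age_range`` unless ``age_band_counts`` maps
    1-year band start -> count (then ``n`` must equal the total).  Determinism:
    the same params/seed give the same cohort; ``seed`` overrides
    ``params.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.age_range
    if age_band_counts is None:
        ages = rng.uniform(lo, hi, size=n)
    else:
        if sum(age_band_counts.values()) != n:
            raise ValueError("age_band_counts must sum to n")
        ages = np.concatenate(
            [rng.uniform(b, b + 1.0, size=c) for b, c in sorted(age_band_counts.items())]
        )
    sexes = np.where(rng.random(n) < params.sex_ratio, "M", "F")
    delta = rng.normal(0.0, params.sigma_child, size=n)
    eps = rng.normal(0.0, params.sigma_tooth, size=(n, len(TEETH)))

    width = len(str(n))
    records = []
    for i in range(n):
        stages = {}
        for j, t in enumerate(TEETH):
            mu_t = params.mu[(str(sexes[i]), t)]
            stages[t] = stage_from_maturation(mu_t, ages[i] + delta[i] + eps[i, j])
        records.append(
            DentitionRecord(
                subject_id=f"s{i + 1:0{width}d}",
                sex=str(sexes[i]),
                chron_age=float(ages[i]),
                stages=stages,
            )
        )
    return Cohort(records, provenance="synthetic")


# ---------------------------------------------------------------------------
# stage-frequency summaries


@dataclass(frozen=True)
class StageDistribution:
    """Per-(sex, tooth) percentage of records at each stage (0, A-H)."""

    percents: Mapping[tuple[str, int], np.ndarray]

    def percent(self, sex: str, tooth: int) -> np.ndarray:
        return np.asarray(self.percents[(sex, tooth)])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": s, "tooth": t, "stage": stage.value, "percent": float(p)}
            for (s, t), vec in sorted(self.percents.items())
            for stage, p in zip(STAGES, vec)
        ]
        return pd.DataFrame(rows, columns=["sex", "tooth", "stage", "percent"])


def stage_distribution(cohort: Cohort) -> StageDistribution:
    """Empirical stage percentages per sex and tooth (columns sum to 100)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out: dict[tuple[str, int], np.ndarray] = {}
    for sex in SEXES:
        recs = [r for r in cohort if r.sex == sex]
        if not recs:
            continue
        for t in TEETH:
            counts = np.zeros(len(STAGES))
            for r in recs:
                s = r.stages[t]
                if s is not StageCode.MISSING:
                    counts[s.rank] += 1
            total = counts.sum()
            out[(sex, t)] = 100.0 * counts / total if total else counts
    return StageDistribution(out)


def load_reference_stage_distribution() -> StageDistribution:
    """Packaged per-(sex, tooth) stage percentages from the Saudi sample.

    Stages A-H as published; the stage-0 share is 0 (the study sample had no
    pre-calcification teeth among eligible children).
    """
    with resources.as_file(
        resources.files("dentage.data").joinpath("stage_frequencies_sa.csv")
    ) as p:
        df = pd.read_csv(p)
    out: dict[tuple[str, int], np.ndarray] = {}
    for (sex, tooth), grp in df.groupby(["sex", "tooth"]):
        vec = np.zeros(len(STAGES))
        for _, row in grp.iterrows():
            vec[StageCode(row["stage"]).rank] = float(row["percent"])
        out[(str(sex), int(tooth))] = vec
    return StageDistribution(out)


# ---------------------------------------------------------------------------
# calibration to a reference distribution


def default_params_like_study(
    reference: Optional[StageDistribution] = None,
    age_range: tuple[float, float] = (4.0, 16.0),
    sigma_child: float = 0.7,
    sigma_tooth: float = 0.9,
    sex_ratio: float = 0.5,
    seed: int = 0,
    min_gap: float = 0.05,
) -> MaturationParams:
    """Attainment ages matched to a reference marginal stage distribution.

    For ages uniform on ``age_range`` and small latent noise, the share of
    children at stage >= s is approximately (age_max - mu_s) / range, so the
    calibration inverts the reference's top-cumulative frequencies:
    ``mu_s = age_max - P(stage >= s) * range``.  Ties (stages with zero
    reference mass) are broken by pushing earlier stages down by ``min_gap``
    to keep mu strictly increasing; the construction is deterministic.
    """
    if reference is None:
        reference = load_reference_stage_distribution()
    lo, hi = age_range
    span = hi - lo
    mu: dict[tuple[str, int], np.ndarray] = {}
    for (sex, tooth), vec in reference.percents.items():
        p = np.asarray(vec, dtype=float)
        total = p.sum()
        if total <= 0:
            raise ValueError(f"reference for ({sex},{tooth}) has no mass")
        p = p / total
        # cumulative share at or beyond each attainable stage (A..H)
        tail = np.cumsum(p[::-1])[::-1]
        f = tail[1:] if p.shape == (len(STAGES),) else tail  # drop stage 0 row
        m = hi - f * span
        for s in range(len(m) - 2, -1, -1):  # enforce strict increase downward
            m[s] = min(m[s], m[s + 1] - min_gap)
        mu[(sex, tooth)] = m
    return MaturationParams(
        mu=mu,
        sigma_child=sigma_child,
        sigma_tooth=sigma_tooth,
        age_range=age_range,
        sex_ratio=sex_ratio,
        seed=seed,
    )


def implied_stage_distribution(
    params: MaturationParams, n: int = 10000, seed: Optional[int] = None
) -> StageDistribution:
    """Model-implied marginal stage frequencies, by simulation."""
    return stage_distribution(generate_cohort(params, n, seed=seed))


def calibration_deviation(
    params: MaturationParams,
    reference: StageDistribution,
    n: int = 10000,
    seed: Optional[int] = None,
) -> float:
    """Max abs deviation (percentage points, stages A-H) from the reference."""
    sim = implied_stage_distribution(params, n=n, seed=seed)
    worst = 0.0
    for key, ref_vec in reference.percents.items():
        sim_vec = sim.percents[key]
        worst = max(worst, float(np.max(np.abs(sim_vec[1:] - np.asarray(ref_vec)[1:]))))
    return worst


# ---------------------------------------------------------------------------
# parameter-recovery harness


def attach_additive_ages(
    cohort: Cohort,
    truth: CoefficientTable,
    noise_sd: float,
    seed: Optional[int] = None,
) -> Cohort:
    """Replace chronological ages with a known additive model's predictions.

    Each record's age becomes ``estimate_age(truth, record) + N(0, noise_sd)``,
    so the cohort's true generating model is the supplied table — the harness
    for parameter-recovery checks.  Every stage present must be covered by the
    table (an explicit entry), else an error names the uncovered key.
    Non-positive resulting ages are floored at 0.1 y; a warning reports the
    count.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for r in cohort:
        for t in TEETH:
            s = r.stages[t]
            if s is StageCode.MISSING:
                raise ValueError(f"record {r.subject_id!r}: tooth {t} is MISSING")
            if (r.sex, t, s) not in truth.entries:
                raise ValueError(
                    f"truth table has no entry for (sex={r.sex}, tooth={t}, "
                    f"stage={s}); cannot attach additive ages"
                )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(cohort)) if noise_sd > 0 else np.zeros(len(cohort))
    n_clipped = 0
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-positive estimates handled here
        for r, eta in zip(cohort, noise):
            age = estimate_age(truth, r) + float(eta)
            if age <= 0:
                age = AGE_FLOOR
                n_clipped += 1
            records.append(
                DentitionRecord(r.subject_id, r.sex, age, dict(r.stages),
                                r.observer_id, r.session)
            )
    if n_clipped:
        warnings.warn(
            f"{n_clipped} synthetic age(s) were non-positive and floored at "
            f"{AGE_FLOOR} y",
            UserWarning,
            stacklevel=2,
        )
    return Cohort(
        records,
        provenance=f"additive-truth ages (noise_sd={noise_sd}, clipped={n_clipped})",
    )
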