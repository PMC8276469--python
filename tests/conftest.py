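import numpy as np
import pytest

from dentage import Cohort, CoefficientTable, DentitionRecord, TEETH, load_sa_table
from dentage.stages import STAGES, StageCode


def make_record(
    subject_id="s1",
    sex="M",
    chron_age=10.0,
    stages="DDEEEGD",
    observer_id=None,
    session=None,
):
    """Record builder; ``stages`` is a 7-char string for teeth 31..37."""
    smap = {t: StageCode(c) if c != "N" else StageCode.MISSING
            for t, c in zip(TEETH, stages)}
    return DentitionRecord(subject_id, sex, chron_age, smap, observer_id, session)


def make_cohort(*records, provenance="test"):
    return Cohort(list(records), provenance=provenance)


def balanced_stage_cohort(n, seed, sexes=("M", "F")):
    """Stage vectors drawn independently and uniformly over all nine stages.

    The maximally informative design for coefficient recovery: teeth are
    uncorrelated, every (tooth, stage) cell has expected share n/9.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        sex = sexes[i % len(sexes)]
        stages = {t: STAGES[int(rng.integers(0, len(STAGES)))] for t in TEETH}
        records.append(DentitionRecord(f"s{i:05d}", sex, 10.0, stages))
    return Cohort(records, provenance="balanced-design")


def identifiable_truth_table(seed=123, base=3.0):
    """Random truth table in the fit's identifiable parameterisation.

    Teeth 32-37 score 0 at stage 0 (the reference); tooth 31 carries a
    baseline so the all-reference prediction is positive.  Scores increase
    with stage, step sizes ~ |N(0.8, 0.3)|, covering realistic child ages.
    """
    rng = np.random.default_rng(seed)
    entries = {}
    for sex in ("M", "F"):
        for t in TEETH:
            steps = np.abs(rng.normal(0.8, 0.3, size=len(STAGES)))
            vals = np.cumsum(steps) - steps[0]
            for s, v in zip(STAGES, vals):
                entries[(sex, t, s)] = float(v + (base if t == 31 else 0.0))
    return CoefficientTable(entries, name="truth")


@pytest.fixture(scope="session")
def sa_table():
    return load_sa_table()
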