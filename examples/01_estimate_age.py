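"""Estimate a child's dental age from staged teeth with the packaged table.

A dental age is the sum of seven per-tooth scores (in years) looked up by
(sex, FDI tooth 31-37, Demirjian stage A-H).  The error convention is
chronological age minus estimated age: negative = overestimation.
"""

from dentage import DentitionRecord, TEETH, estimate_age, load_sa_table
from dentage.stages import StageCode

table = load_sa_table()

# a 10.5-year-old boy, staged on a panoramic radiograph
stages = {
    31: StageCode.G, 32: StageCode.G, 33: StageCode.F, 34: StageCode.F,
    35: StageCode.E, 36: StageCode.G, 37: StageCode.E,
}
boy = DentitionRecord("example-boy", "M", chron_age=10.5, stages=stages)

estimate = estimate_age(table, boy)
print(f"chronological age : {boy.chron_age:.2f} y")
print(f"estimated age     : {estimate:.3f} y")
print(f"error (CA - DA)   : {boy.chron_age - estimate:+.3f} y")
print()
print("per-tooth contributions (years):")
for t in TEETH:
    from dentage import lookup_score

    print(f"  t{t} stage {boy.stages[t]}: {lookup_score(table, 'M', t, boy.stages[t]):+7.3f}")
# The seven contributions sum to the estimate; a negative error means the
# table over-predicted this child's age.
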