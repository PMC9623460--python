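"""Worked example: distinct flagged drugs in the 90 days before a hospital stay.

One hand-built stay (admitted 2021-03-10, discharged 2021-03-15) with three
drug dispensings, two of them on the flagged (potentially-inappropriate)
list.  The pipeline builds the stay track, derives the 90-day pre-admission
window, masks the flagged exposures by it, unions the per-drug results and
counts the distinct drugs — printing the intermediate track after every step.
"""

from trackfeat import generate_worked_sc6_fixture, sc6_worked_steps

bundle, _expected = generate_worked_sc6_fixture()
steps = sc6_worked_steps(bundle)

for name in sorted(steps):
    value = steps[name]
    print(f"\n{name}")
    if name == "step8_count_distinct":
        print(f"  feature value = {value}")
    else:
        for r in value.sorted_records():
            print(f"  [{r.start:%Y-%m-%d}, {r.end:%Y-%m-%d})  value={r.value}")

# The final value, 2, is the analysis-ready feature: this stay's patient was
# exposed to 2 distinct flagged drugs in the 90 days before admission.  The
# third dispensing is ignored (not on the list) and an old flagged exposure
# falls outside the window.
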