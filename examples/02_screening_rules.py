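"""Apply all ten screening rules to one illustrative participant.

The person reads 138/88 on the first measurement and 150/95 on the
second and third.  The standard rule (mean of readings 2-3) diagnoses
hypertension, while rules that never look past a non-elevated first
reading miss it — the cost of conditionally triggered shortcuts.
"""

import pandas as pd

import bpscreen as b

person = pd.DataFrame([{
    "person_id": 0, "country": "C1", "region": "R1",
    "sbp1": 138, "sbp2": 150, "sbp3": 150,
    "dbp1": 88, "dbp2": 95, "dbp3": 95,
}])

print(f"{'approach':28s} {'effective BP':>14s} {'readings':>9s} {'result':>14s}")
for approach_id in b.ALL_IDS:
    d = b.diagnose(person, approach_id).iloc[0]
    label = "hypertensive" if d.hypertensive else "normal"
    print(f"{approach_id:28s} {d.effective_sbp:6.1f}/{d.effective_dbp:5.1f} "
          f"{d.readings_used:>9d} {label:>14s}")

print("\nThe >=140/90-triggered rule never takes a second reading here"
      "\n(first reading 138/88 is below its trigger), so it returns the"
      "\nfirst reading and misses the sustained 150/95 elevation.")
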