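"""Recommend a care-plan action by rules, then emulate the rules with the
pre-pruned Gini decision tree.

The rule engine is the staff-authored ground truth; the depth-3 tree with
at least 6 samples per leaf is trained on rule-labelled synthetic patient
states and reported with its hold-out agreement.
"""

import numpy as np

from gericare.careplan import demo_ruleset, fit_tree, recommend, state_features
from gericare.core import PATIENT_SCHEMA, PatientState
from gericare.synthetic import generate_patient_states

ruleset = demo_ruleset()
print(f"shipped illustrative ruleset: {len(ruleset)} rules")

# A patient who is stable except for low oxygen saturation.
values = {var: vals[0] for var, vals in PATIENT_SCHEMA.items()}
values["Sat"] = "<94%"
state = PatientState(values=values, height=1.68)

rec = recommend(state, ruleset=ruleset)
print(f"rules say: {rec.action.value} (matched: {list(rec.trace)})")

# Train the tree emulator on 5000 rule-labelled states.
records = generate_patient_states(5000, ruleset, seed=2)
tree = fit_tree(records[:4000], max_depth=3, min_samples=6)
agree = np.mean(
    [tree.predict_one(state_features(s)) == a.value for s, a in records[4000:]]
)
print(f"tree vs rules on 1000 held-out states: {100 * agree:.1f}% agreement")

rec_tree = recommend(state, tree=tree)
print(f"tree says: {rec_tree.action.value}")
print("decision path: " + " AND ".join(rec_tree.trace))
print("\nThe tree is the statistical stand-in that can later be refit from "
      "accumulated staff decisions; the trace shows why it decided.")
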