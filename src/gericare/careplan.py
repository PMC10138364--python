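"""Care-plan decision support: IF-THEN rules and the Gini-tree emulator.

Two interchangeable recommenders map a 21-variable patient state to one of
four plan actions (continue current treatment, monitor, adjust, extra
situation):

* an ordered **rule engine** — conjunctive IF-THEN rules written by care
  staff, evaluated most-severe-action first (then priority, then id) with
  "continue current treatment" as the default when nothing matches;
* a **decision tree** trained on rule-labelled states with Gini impurity
  and pre-pruning (maximum depth 3, at least 6 samples per leaf), the
  statistical stand-in that can later be refit from accumulated decisions.

Categorical variables are one-hot binarized (variable == value) for the
tree, keeping every split readable at depth 3.

The production ruleset of a real facility is site-specific; the package
ships an illustrative ~16-rule set (``data/demo_rules.yaml``).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

from .core import (
    ACTION_SEVERITY,
    PATIENT_SCHEMA,
    PatientState,
    PlanAction,
    SchemaError,
)
from .tree import DecisionTree, gini

__all__ = [
    "Rule",
    "RuleSet",
    "evaluate_rules",
    "fit_tree",
    "recommend",
    "gini",
    "load_ruleset",
    "demo_ruleset",
    "state_features",
    "FEATURE_NAMES",
]

_OPS = {
    "eq": lambda actual, target: actual == target,
    "in": lambda actual, target: actual in target,
    "ge": lambda actual, target: actual >= target,
    "le": lambda actual, target: actual <= target,
}


@dataclasses.dataclass(frozen=True)
class Condition:
    var: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if self.var not in PATIENT_SCHEMA:
            raise SchemaError(f"rule condition references unknown variable {self.var!r}")
        if self.op not in _OPS:
            raise SchemaError(f"unknown operator {self.op!r}")
        allowed = PATIENT_SCHEMA[self.var]
        values = self.value if self.op == "in" else (self.value,)
        bad = [v for v in values if v not in allowed]
        if bad:
            raise SchemaError(f"rule value(s) {bad} not in value set of {self.var!r}")

    def matches(self, state: PatientState) -> bool:
        return _OPS[self.op](state[self.var], self.value)


@dataclasses.dataclass(frozen=True)
class Rule:
    """Conjunction of conditions mapping to one plan action."""

    id: str
    conditions: tuple[Condition, ...]
    action: PlanAction
    priority: int = 0

    def matches(self, state: PatientState) -> bool:
        return all(c.matches(state) for c in self.conditions)


class RuleSet:
    """Ordered rules with a default action.

    Evaluation order: severity of the action (descending), then priority
    (descending), then id (ascending) — an emergency rule can never be
    shadowed by a blander one.
    """

    def __init__(
        self,
        rules: Iterable[Rule],
        default_action: PlanAction = PlanAction.CONTINUE,
    ):
        rules = list(rules)
        ids = [r.id for r in rules]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate rule ids: {dupes}")
        self.rules = sorted(
            rules, key=lambda r: (-ACTION_SEVERITY[r.action], -r.priority, r.id)
        )
        self.default_action = default_action

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def evaluate_rules(state: PatientState, ruleset: RuleSet) -> tuple[PlanAction, list[str]]:
    """Action of the first matching rule in evaluation order.

    Returns (action, matched rule ids); no match gives the default action
    with an empty id list.
    """
    for rule in ruleset:
        if rule.matches(state):
            return rule.action, [rule.id]
    return ruleset.default_action, []


# ---------------------------------------------------------------------------
# YAML ruleset I/O
# ---------------------------------------------------------------------------

def load_ruleset(source: Union[str, Path]) -> RuleSet:
    """Load a YAML ruleset: list of {id, if: [{var, op, value}], then, priority}."""
    text = Path(source).read_text()
    return parse_ruleset(text)


def parse_ruleset(text: str) -> RuleSet:
    doc = yaml.safe_load(text)
    entries = doc["rules"] if isinstance(doc, dict) else doc
    rules = []
    for e in entries:
        conds = tuple(
            Condition(c["var"], c.get("op", "eq"), c["value"]) for c in e["if"]
        )
        rules.append(
            Rule(
                id=str(e["id"]),
                conditions=conds,
                action=PlanAction(e["then"]),
                priority=int(e.get("priority", 0)),
            )
        )
    default = PlanAction.CONTINUE
    if isinstance(doc, dict) and "default" in doc:
        default = PlanAction(doc["default"])
    return RuleSet(rules, default_action=default)


def demo_ruleset() -> RuleSet:
    """The illustrative ruleset shipped with the package."""
    text = (
        importlib.resources.files("gericare").joinpath("data/demo_rules.yaml").read_text()
    )
    return parse_ruleset(text)


# ---------------------------------------------------------------------------
# Tree emulator
# ---------------------------------------------------------------------------

#: One-hot feature names, fixed by the schema: "<var>=<value>".
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{var}={value}" for var, values in PATIENT_SCHEMA.items() for value in values
)

#: Class order most-severe-first so leaf ties resolve toward urgency.
_CLASS_ORDER = [
    PlanAction.EXTRA.value,
    PlanAction.ADJUST.value,
    PlanAction.MONITOR.value,
    PlanAction.CONTINUE.value,
]


def state_features(state: PatientState) -> np.ndarray:
    """One-hot encode a patient state over the full schema."""
    vec = np.zeros(len(FEATURE_NAMES))
    i = 0
    for var, values in PATIENT_SCHEMA.items():
        vec[i + values.index(state[var])] = 1.0
        i += len(values)
    return vec


def fit_tree(
    records: Sequence[tuple[PatientState, PlanAction]],
    max_depth: int = 3,
    min_samples: int = 6,
    seed: int = 0,
) -> DecisionTree:
    """Fit the pre-pruned Gini tree on (state, action) pairs.

    All-one-class data yields a valid single-leaf tree.  The fit is
    deterministic given the data order.
    """
    if len(records) < min_samples:
        raise ValueError(f"need at least {min_samples} records, got {len(records)}")
    X = np.array([state_features(s) for s, _ in records])
    y = [PlanAction(a).value for _, a in records]
    tree = DecisionTree(
        max_depth=max_depth,
        min_samples_leaf=min_samples,
        classes=_CLASS_ORDER,
        feature_names=list(FEATURE_NAMES),
        seed=seed,
    )
    return tree.fit(X, y)


# ---------------------------------------------------------------------------
# Unified recommendation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Recommendation:
    action: PlanAction
    trace: tuple[str, ...]  # matched rule ids, or the root-to-leaf path
    recommender: str  # "rules" or "tree"


def recommend(
    state: PatientState,
    ruleset: Optional[RuleSet] = None,
    tree: Optional[DecisionTree] = None,
    move_habit: Optional[str] = None,
) -> Recommendation:
    """Recommend a plan action with an explanation trace.

    Exactly one of ``ruleset`` / ``tree`` must be given.  ``move_habit``
    (a value from the MoveH value set, e.g. the verdict of the habit-change
    detector) overrides the state's MoveH field before evaluation.
    """
    if (ruleset is None) == (tree is None):
        raise ValueError("supply exactly one of ruleset or tree")
    if move_habit is not None:
        values = dict(state.values)
        values["MoveH"] = move_habit
        state = dataclasses.replace(state, values=values)
    if ruleset is not None:
        action, ids = evaluate_rules(state, ruleset)
        return Recommendation(action=action, trace=tuple(ids), recommender="rules")
    x = state_features(state)
    action = PlanAction(tree.predict_one(x))
    return Recommendation(
        action=action, trace=tuple(tree.decision_path(x)), recommender="tree"
    )
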