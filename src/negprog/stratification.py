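"""Sequential Bayesian risk stratification.

Clinical information arrives sequentially in practice: a cheap clinical
assessment first, an MRI-derived biomarker second.  Starting from the
pretest probability (base rate) of the bad outcome, each test result updates
the outcome probability by Bayes' rule through the test's sensitivity (SE)
and specificity (SP):

* positive result:  ``p' = p*SE / (p*SE + (1-p)*(1-SP))``
* negative result:  ``p' = p*(1-SE) / (p*(1-SE) + (1-p)*SP)``

Enumerating all result paths yields a binary tree of posttest probabilities;
each leaf carries the probability mass of its path (law of total
probability), a risk category (high > 80%, medium 40-64%, low < 20%, gaps
mapped to "indeterminate"), and the number needed to treat for an
intervention with risk ratio RR: ``NNT = 1 / (p * (1 - RR))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESULTS = ("+", "-")

HIGH_RISK_MIN = 0.80       # exclusive
MEDIUM_RISK = (0.40, 0.64)  # inclusive band
LOW_RISK_MAX = 0.20        # exclusive


@dataclass(frozen=True)
class DiagnosticTest:
    """A binary test summarized by its sensitivity and specificity."""

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for attr in ("sensitivity", "specificity"):
            v = getattr(self, attr)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{attr} of test {self.name!r} must lie in (0, 1), got {v!r}")

    @property
    def informative(self) -> bool:
        return not np.isclose(self.sensitivity + self.specificity, 1.0)

    def positive_rate(self, p: float) -> float:
        """Marginal probability of a positive result at pretest probability p."""
        return p * self.sensitivity + (1.0 - p) * (1.0 - self.specificity)


def posttest_probability(p: float, test: DiagnosticTest, result: str) -> float:
    """Bayes update of the outcome probability after one test result."""
    if result not in RESULTS:
        raise ValueError(f"result must be '+' or '-', got {result!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    if p in (0.0, 1.0):
        warnings.warn(
            "degenerate pretest probability; returned unchanged", RuntimeWarning, stacklevel=2
        )
        return p
    se, sp = test.sensitivity, test.specificity
    if result == "+":
        return p * se / (p * se + (1.0 - p) * (1.0 - sp))
    return p * (1.0 - se) / (p * (1.0 - se) + (1.0 - p) * sp)


def assign_risk_category(p: float) -> str:
    """Risk band of a posttest probability; band gaps are 'indeterminate'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    if p > HIGH_RISK_MIN:
        return "high"
    if MEDIUM_RISK[0] <= p <= MEDIUM_RISK[1]:
        return "medium"
    if p < LOW_RISK_MAX:
        return "low"
    return "indeterminate"


def nnt(posttest_p: float, rr: float) -> tuple[float, int]:
    """Number needed to treat at a posttest probability for an intervention
    with risk ratio ``rr`` (< 1 means benefit).

    Absolute risk reduction ARR = p * (1 - RR); NNT = 1/ARR.  Returns the
    exact value and its nearest-integer rounding.
    """
    if not 0.0 < posttest_p <= 1.0:
        raise ValueError(f"posttest probability must lie in (0, 1], got {posttest_p!r}")
    if rr <= 0.0:
        raise ValueError(f"risk ratio must be positive, got {rr!r}")
    if rr >= 1.0:
        raise ValueError(f"risk ratio {rr!r} implies no benefit; NNT undefined")
    arr = posttest_p * (1.0 - rr)
    value = 1.0 / arr
    return value, int(round(value))


@dataclass
class RiskNode:
    result_path: tuple[str, ...]
    posttest_p: float
    branch_mass: float
    category: str
    nnt_value: float | None = None
    nnt_rounded: int | None = None

    @property
    def depth(self) -> int:
        return len(self.result_path)


@dataclass
class StratificationTree:
    pretest: float
    tests: tuple[DiagnosticTest, ...]
    nodes: list[RiskNode]
    rr: float | None = None
    _index: dict[tuple[str, ...], RiskNode] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {n.result_path: n for n in self.nodes}

    def node(self, path: tuple[str, ...] | str) -> RiskNode:
        if isinstance(path, str):
            path = tuple(path)
        return self._index[path]

    @property
    def leaves(self) -> list[RiskNode]:
        depth = len(self.tests)
        return [n for n in self.nodes if n.depth == depth]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": ["".join(n.result_path) or "(pretest)" for n in self.nodes],
                "depth": [n.depth for n in self.nodes],
                "posttest_p": [n.posttest_p for n in self.nodes],
                "branch_mass": [n.branch_mass for n in self.nodes],
                "category": [n.category for n in self.nodes],
                "nnt": [n.nnt_value for n in self.nodes],
                "nnt_rounded": [n.nnt_rounded for n in self.nodes],
            }
        )

    def to_dict(self) -> dict:
        return {
            "pretest": self.pretest,
            "rr": self.rr,
            "tests": [
                {"name": t.name, "sensitivity": t.sensitivity, "specificity": t.specificity}
                for t in self.tests
            ],
            "nodes": self.to_frame().to_dict(orient="records"),
        }


def build_tree(
    pretest: float,
    tests: list[DiagnosticTest] | tuple[DiagnosticTest, ...],
    rr: float | None = None,
) -> StratificationTree:
    """Enumerate all result paths of the sequential testing scenario.

    Produces a full binary tree of depth ``len(tests)`` (2^(depth+1) - 1
    nodes): each node carries the chained posttest probability, the branch's
    total-probability mass, a risk category, and (when ``rr`` is given) the
    NNT.
    """
    if not 0.0 < pretest < 1.0:
        raise ValueError(f"pretest probability must lie strictly in (0, 1), got {pretest!r}")
    tests = tuple(tests)
    if not tests:
        raise ValueError("at least one diagnostic test is required")

    def make_node(path: tuple[str, ...], p: float, mass: float) -> RiskNode:
        node = RiskNode(
            result_path=path,
            posttest_p=p,
            branch_mass=mass,
            category=assign_risk_category(p),
        )
        if rr is not None:
            node.nnt_value, node.nnt_rounded = nnt(p, rr)
        return node

    nodes = [make_node((), pretest, 1.0)]
    frontier = [((), pretest, 1.0)]
    for test in tests:
        next_frontier = []
        for path, p, mass in frontier:
            pos_rate = test.positive_rate(p)
            for result, rate in zip(RESULTS, (pos_rate, 1.0 - pos_rate)):
                child_p = posttest_probability(p, test, result)
                child = make_node(path + (result,), child_p, mass * rate)
                nodes.append(child)
                next_frontier.append((child.result_path, child_p, child.branch_mass))
        frontier = next_frontier
    return StratificationTree(pretest=pretest, tests=tests, nodes=nodes, rr=rr)


def empirical_branch_rates(
    cohort: pd.DataFrame,
    test_columns: list[str],
    outcome_column: str,
) -> pd.DataFrame:
    """Observed analogue of the theoretical posttest probabilities.

    For each result path over the binary test columns, the outcome rate among
    subjects on that path, with counts; paths with no subjects are flagged
    (rate NaN) rather than divided by zero.
    """
    missing = [c for c in test_columns + [outcome_column] if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks columns: {missing}")
    results = cohort[test_columns].to_numpy().astype(int)
    outcome = cohort[outcome_column].to_numpy().astype(int)
    rows = []
    n_tests = len(test_columns)
    for bits in range(2**n_tests):
        pattern = [(bits >> (n_tests - 1 - i)) & 1 for i in range(n_tests)]
        mask = np.all(results == pattern, axis=1)
        count = int(mask.sum())
        rows.append(
            {
                "path": "".join("+" if b else "-" for b in pattern),
                "n": count,
                "n_bad_outcome": int(outcome[mask].sum()),
                "rate": float(outcome[mask].mean()) if count else np.nan,
                "empty": count == 0,
            }
        )
    return pd.DataFrame(rows)
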