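import itertools

import numpy as np
import pandas as pd
import pytest

from negprog import (
    DiagnosticTest,
    assign_risk_category,
    build_tree,
    empirical_branch_rates,
    nnt,
    posttest_probability,
)

CLINICAL = DiagnosticTest("clinical", 0.47, 0.89)
IMAGING = DiagnosticTest("gyrification", 0.61, 0.64)


class TestPosttestProbability:
    def test_positive_update_worked_value(self):
        assert posttest_probability(0.40, CLINICAL, "+") == pytest.approx(0.7402, abs=5e-5)

    def test_negative_update_worked_value(self):
        assert posttest_probability(0.40, CLINICAL, "-") == pytest.approx(0.2842, abs=5e-5)

    def test_uninformative_test_changes_nothing(self):
        flat = DiagnosticTest("coin", 0.3, 0.7)  # SE + SP = 1
        assert not flat.informative
        for result in "+-":
            assert posttest_probability(0.40, flat, result) == pytest.approx(0.40)

    def test_degenerate_probability_returned_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert posttest_probability(0.0, CLINICAL, "+") == 0.0
        with pytest.warns(RuntimeWarning):
            assert posttest_probability(1.0, CLINICAL, "-") == 1.0

    def test_positive_raises_probability_iff_informative(self):
        for se, sp in [(0.47, 0.89), (0.61, 0.64), (0.9, 0.2), (0.2, 0.9)]:
            t = DiagnosticTest("t", se, sp)
            p1 = posttest_probability(0.40, t, "+")
            if se + sp > 1:
                assert p1 > 0.40
            elif se + sp < 1:
                assert p1 < 0.40

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            posttest_probability(0.4, CLINICAL, "x")
        with pytest.raises(ValueError):
            DiagnosticTest("bad", 1.2, 0.5)


@pytest.fixture(scope="module")
def tree():
    return build_tree(0.40, [CLINICAL, IMAGING], rr=0.15)


class TestTree:
    def test_published_leaf_percentages(self, tree):
        pct = {"".join(l.result_path): round(100 * l.posttest_p) for l in tree.leaves}
        assert pct["++"] == 83
        assert pct["-+"] == 40
        assert pct["--"] == 19
        # the remaining branch computes to 63.4; its printed value (64) is
        # sensitive to the rounding of the inputs
        assert tree.node("+-").posttest_p == pytest.approx(0.6345, abs=5e-4)

    def test_total_probability_conservation(self, tree):
        leaves = tree.leaves
        assert sum(l.branch_mass for l in leaves) == pytest.approx(1.0, abs=1e-12)
        assert sum(l.branch_mass * l.posttest_p for l in leaves) == pytest.approx(
            0.40, abs=1e-12
        )

    def test_node_count_is_full_binary_tree(self, tree):
        assert len(tree.nodes) == 2 ** (len(tree.tests) + 1) - 1

    def test_test_order_invariance_of_terminal_probabilities(self):
        """Likelihood ratios commute: swapping the two tests relabels paths
        but leaves each terminal posttest probability unchanged."""
        fwd = build_tree(0.40, [CLINICAL, IMAGING])
        rev = build_tree(0.40, [IMAGING, CLINICAL])
        for a, b in itertools.product("+-", repeat=2):
            assert fwd.node((a, b)).posttest_p == pytest.approx(
                rev.node((b, a)).posttest_p, abs=1e-12
            )

    def test_nnt_ladder_attached_to_nodes(self, tree):
        rounded = {"".join(l.result_path): l.nnt_rounded for l in tree.leaves}
        assert rounded == {"++": 1, "+-": 2, "-+": 3, "--": 6}

    def test_empty_test_list_rejected(self):
        with pytest.raises(ValueError):
            build_tree(0.40, [])
        with pytest.raises(ValueError):
            build_tree(1.0, [CLINICAL])


class TestRiskCategories:
    @pytest.mark.parametrize(
        "p, category",
        [
            (0.83, "high"),
            (0.81, "high"),
            (0.80, "indeterminate"),  # band is strictly > 80%
            (0.64, "medium"),
            (0.40, "medium"),
            (0.50, "medium"),
            (0.30, "indeterminate"),  # gap between low and medium bands
            (0.70, "indeterminate"),
            (0.19, "low"),
            (0.0, "low"),
        ],
    )
    def test_bands(self, p, category):
        assert assign_risk_category(p) == category


class TestNNT:
    def test_forced_arithmetic(self):
        value, rounded = nnt(0.5, 0.5)
        assert value == pytest.approx(4.0)
        assert rounded == 4

    def test_limit_towards_one(self):
        value, rounded = nnt(1.0, 1e-9)
        assert value == pytest.approx(1.0, abs=1e-6)
        assert rounded == 1

    def test_monotone_decreasing_in_posttest_probability(self):
        grid = np.linspace(0.05, 1.0, 50)
        values = [nnt(p, 0.3)[0] for p in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_no_benefit_rejected(self):
        with pytest.raises(ValueError, match="benefit"):
            nnt(0.5, 1.0)
        with pytest.raises(ValueError):
            nnt(0.5, -0.1)
        with pytest.raises(ValueError):
            nnt(0.0, 0.5)


class TestEmpiricalBranchRates:
    def test_observed_rates_match_theory_in_simulation(self):
        """Simulate tests with known SE/SP: per-path outcome rates should sit
        within binomial sampling error of the chained posttest values."""
        rng = np.random.default_rng(42)
        n = 40_000
        disease = rng.random(n) < 0.40
        def draw(test):
            pos_given_d = rng.random(n) < test.sensitivity
            pos_given_h = rng.random(n) < (1 - test.specificity)
            return np.where(disease, pos_given_d, pos_given_h).astype(int)
        df = pd.DataFrame(
            {"t1": draw(CLINICAL), "t2": draw(IMAGING), "outcome": disease.astype(int)}
        )
        rates = empirical_branch_rates(df, ["t1", "t2"], "outcome").set_index("path")
        tree = build_tree(0.40, [CLINICAL, IMAGING])
        for leaf in tree.leaves:
            path = "".join(leaf.result_path)
            n_path = rates.loc[path, "n"]
            se = np.sqrt(leaf.posttest_p * (1 - leaf.posttest_p) / n_path)
            assert abs(rates.loc[path, "rate"] - leaf.posttest_p) < 4 * se + 1e-9

    def test_all_positive_outcomes(self):
        df = pd.DataFrame({"t1": [0, 1, 0, 1], "t2": [0, 0, 1, 1], "outcome": [1] * 4})
        rates = empirical_branch_rates(df, ["t1", "t2"], "outcome")
        assert (rates["rate"] == 1.0).all()

    def test_empty_path_flagged_not_divided(self):
        df = pd.DataFrame({"t1": [1, 1], "t2": [1, 1], "outcome": [1, 0]})
        rates = empirical_branch_rates(df, ["t1", "t2"], "outcome").set_index("path")
        assert rates.loc["--", "empty"]
        assert np.isnan(rates.loc["--", "rate"])

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            empirical_branch_rates(pd.DataFrame({"a": [1]}), ["t1"], "outcome")
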