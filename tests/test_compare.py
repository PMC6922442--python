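from itertools import combinations

import numpy as np
import pytest

from emci import (
    Ensemble,
    ValidationError,
    balanced_simultaneous_ci,
    compare_cases,
    make_comparison_cases,
    pairwise_differences,
    preselect_top_variables,
)

METHODS = ("univariate", "bonferroni", "exact_normal", "bootstrap")


@pytest.fixture(scope="module")
def four_cases():
    ensembles, truths = make_comparison_cases(n=400, seed=101)
    return ensembles, truths


@pytest.fixture(scope="module")
def selected(four_cases):
    ensembles, _ = four_cases
    rng = np.random.default_rng(102)
    cisets = [balanced_simultaneous_ci(e, 0.05, B=1_000, seed=rng) for e in ensembles]
    return preselect_top_variables(cisets, k=7)


class TestPreselection:
    def test_union_of_top_sevens_has_fifteen_members(self, selected):
        assert len(selected) == 15
        assert selected == sorted(selected)  # deterministic name order

    def test_all_significant_small_k_cap(self, rng):
        values = rng.standard_normal((300, 4)) * 0.01 + np.array([5, 4, 3, 2])
        ens = Ensemble(values, ("a", "b", "c", "d"))
        ciset = balanced_simultaneous_ci(ens, 0.05, B=500, seed=1)
        assert preselect_top_variables([ciset], k=10) == ["a", "b", "c", "d"]
        assert preselect_top_variables([ciset], k=2) == ["a", "b"]

    def test_no_significant_yields_empty_with_warning(self, rng, caplog):
        values = rng.standard_normal((50, 3))
        ens = Ensemble(values, ("a", "b", "c"))
        ciset = balanced_simultaneous_ci(ens, 0.05, B=500, seed=2)
        with caplog.at_level("WARNING", logger="emci"):
            out = preselect_top_variables([ciset])
        assert out == []


class TestPairwiseDifferences:
    def test_four_cases_give_six_pairs(self, four_cases, selected):
        ensembles, _ = four_cases
        df = pairwise_differences(ensembles, selected)
        pairs = set(zip(df["case_a"], df["case_b"]))
        assert len(pairs) == 6
        assert len(df) == 6 * 15  # 90 comparisons overall

    def test_identical_cases_give_zero_differences(self, normal_ensemble):
        a = Ensemble(normal_ensemble.values, normal_ensemble.variable_names, "A")
        b = Ensemble(normal_ensemble.values, normal_ensemble.variable_names, "B")
        df = pairwise_differences([a, b], list(a.variable_names))
        np.testing.assert_allclose(df["diff"], 0.0, atol=1e-14)

    def test_two_observation_hand_arithmetic(self):
        a = Ensemble(np.array([[0.0], [2.0]]), ("x",), "A")  # mean 1, var 2
        b = Ensemble(np.array([[1.0], [5.0]]), ("x",), "B")  # mean 3, var 8
        df = pairwise_differences([a, b], ["x"])
        assert df.loc[0, "diff"] == pytest.approx(-2.0)
        assert df.loc[0, "se"] == pytest.approx(np.sqrt(2.0 / 2 + 8.0 / 2))

    def test_missing_variable_rejected(self, small_ensemble):
        other = Ensemble(np.ones((3, 1)) * [[1.0], [2.0], [3.0]], ("A",), "o")
        with pytest.raises(ValidationError, match="missing"):
            pairwise_differences([small_ensemble, other], ["B"])


class TestCompareCases:
    @pytest.mark.parametrize("method", METHODS)
    def test_identical_cases_never_significant(self, normal_ensemble, method):
        a = Ensemble(normal_ensemble.values, normal_ensemble.variable_names, "A")
        b = Ensemble(normal_ensemble.values, normal_ensemble.variable_names, "B")
        result = compare_cases(
            [a, b], list(a.variable_names), method, 0.05, B=500, M=20_000, seed=3
        )
        assert result.n_significant == 0

    def test_global_q_total_bookkeeping(self, four_cases, selected):
        ensembles, _ = four_cases
        result = compare_cases(ensembles, selected, "bonferroni", seed=4)
        assert result.q_total == 90 == len(result.comparisons)
        assert result.metadata["alpha_per_comparison"] == pytest.approx(0.05 / 90)

    @pytest.mark.parametrize("method", ("bonferroni", "exact_normal", "bootstrap"))
    def test_univariate_flags_at_least_each_corrected_method(
        self, four_cases, selected, method
    ):
        ensembles, _ = four_cases
        uni = compare_cases(ensembles, selected, "univariate", seed=5)
        corrected = compare_cases(
            ensembles, selected, method, B=1_000, M=30_000, seed=5
        )
        uni_flags = {
            (c.case_a, c.case_b, c.variable)
            for c in uni.comparisons
            if c.significant
        }
        corr_flags = {
            (c.case_a, c.case_b, c.variable)
            for c in corrected.comparisons
            if c.significant
        }
        assert corr_flags <= uni_flags

    @pytest.mark.parametrize("method", ("univariate", "bonferroni"))
    def test_pair_orientation_mirror(self, four_cases, selected, method):
        ensembles, _ = four_cases
        fwd = compare_cases(ensembles[:2], selected, method, seed=6)
        rev = compare_cases(ensembles[1::-1], selected, method, seed=6)
        for f, r in zip(fwd.comparisons, rev.comparisons):
            assert r.diff_mean == pytest.approx(-f.diff_mean)
            assert r.lower == pytest.approx(-f.upper)
            assert r.upper == pytest.approx(-f.lower)
            assert r.significant == f.significant

    def test_true_differences_detected_and_nulls_protected(self, four_cases, selected):
        # planted truths: check FWE over true-null comparisons and power on
        # large planted differences, bonferroni method
        ensembles, truths = four_cases
        result = compare_cases(ensembles, selected, "bonferroni", seed=7)
        labels = [e.case_label for e in ensembles]
        idx = {n: j for j, n in enumerate(ensembles[0].variable_names)}
        false_pos = missed_large = 0
        for c in result.comparisons:
            true_diff = (
                truths[c.case_a][idx[c.variable]] - truths[c.case_b][idx[c.variable]]
            )
            if true_diff == 0.0 and c.significant:
                false_pos += 1
            if abs(true_diff) > 0.3 and not c.significant:
                missed_large += 1
        assert false_pos == 0  # family-wise error controlled at 5%
        assert missed_large == 0  # planted effects are ~20+ SEs

    def test_exact_normal_cross_case_toggle(self, four_cases, selected):
        ensembles, _ = four_cases
        shared = compare_cases(
            ensembles, selected, "exact_normal", M=30_000, seed=8,
            cross_case_correlation=True,
        )
        blockdiag = compare_cases(
            ensembles, selected, "exact_normal", M=30_000, seed=8,
            cross_case_correlation=False,
        )
        # both calibrations are valid global corrections of the same family
        assert shared.q_total == blockdiag.q_total == 90
        assert shared.metadata["quantile"] == pytest.approx(
            blockdiag.metadata["quantile"], rel=0.05
        )

    def test_bootstrap_family_wise_error_on_null(self, rng):
        # identical generating distribution for 3 cases: any flag is a
        # family-wise error; over one realization expect none at 95%
        cases = [
            Ensemble(rng.standard_normal((300, 4)), tuple("wxyz"), f"c{i}")
            for i in range(3)
        ]
        result = compare_cases(
            cases, list("wxyz"), "bootstrap", B=1_000, seed=9
        )
        assert result.q_total == 12
        assert result.n_significant == 0
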