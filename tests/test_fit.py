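"""Maximum-likelihood estimation, G² inference and the constraint ladder."""

import numpy as np
import pandas as pd
import pytest

import mptsource as mp
from mptsource.fit import (
    FrequencyTable,
    condition_comparison,
    constraint_ladder,
    expected_frequency_table,
    fit_ml,
    lr_test,
    two_htsm_ladder,
)
from mptsource.models import Branch, ConstraintSet, MPTModel, Parameter, Tree, condition_parameter

from conftest import SLEEP_5A, WAKE_5A, joint_theta, multinomial_table

EXP1_TOTALS = {"target-left": 1950, "target-right": 1950, "distractor": 1950}


def test_frequency_table_csv_round_trip(tmp_path, rng):
    table = multinomial_table(mp.build_2htsm("5a"), joint_theta(WAKE_5A, SLEEP_5A), EXP1_TOTALS, rng)
    path = tmp_path / "counts.csv"
    table.to_csv(path)
    back = FrequencyTable.from_csv(path)
    assert back.aggregated
    pd.testing.assert_frame_equal(back.data, table.data)


def test_counts_alignment_rejects_unknown_trees(joint_5a):
    records = [("ALL", "wake", "mystery-tree", "old-left", 3.0)]
    table = FrequencyTable.from_records(records, aggregated=True)
    with pytest.raises(ValueError, match="not in the model"):
        table.counts_for(joint_5a)


def test_mle_recovers_generating_values_from_expected_data(joint_5a, table2_theta):
    """Fitting a model to its own expected frequencies returns the truth."""
    table = expected_frequency_table(joint_5a, table2_theta, EXP1_TOTALS)
    fit = fit_ml(joint_5a, table, n_starts=10, seed=0)
    for name, value in table2_theta.items():
        assert fit.estimates[name] == pytest.approx(value, abs=1e-4)
    assert fit.g_squared < 1e-6
    assert fit.df == 2
    assert fit.converged


def test_multistart_optima_agree(joint_5a, table2_theta, rng):
    """20 random starts land on the same optimum for a realistic table."""
    table = multinomial_table(joint_5a, table2_theta, EXP1_TOTALS, rng)
    fit = fit_ml(joint_5a, table, n_starts=20, seed=1)
    lls = np.asarray(fit.start_logliks)
    assert lls.max() - lls.min() < 1e-6


def test_saturated_model_g_squared_zero(rng):
    tree = Tree(
        name="only",
        condition="w",
        categories=("c1", "c2", "c3"),
        branches=(
            Branch((("p", False),), "c1"),
            Branch((("p", True), ("q", False)), "c2"),
            Branch((("p", True), ("q", True)), "c3"),
        ),
    )
    model = MPTModel(name="sat", parameters=(Parameter("p"), Parameter("q")), trees=(tree,))
    counts = rng.multinomial(300, [0.5, 0.3, 0.2])
    table = FrequencyTable.from_records(
        [("ALL", "w", "only", c, float(k)) for c, k in zip(tree.categories, counts)],
        aggregated=True,
    )
    fit = fit_ml(model, table, n_starts=5, seed=0)
    assert fit.g_squared == pytest.approx(0.0, abs=1e-8)
    assert fit.df == 0 and fit.p_value == 1.0


def test_g_squared_invariant_to_category_relabelling(rng, table2_theta):
    """Renaming categories consistently leaves the minimized G² unchanged."""
    model = mp.build_2htsm("5a")
    table = multinomial_table(model, table2_theta, EXP1_TOTALS, rng)
    fit0 = fit_ml(model, table, n_starts=6, seed=0)

    renames = {"old-left": "response-A", "old-right": "response-B", "new": "response-C"}
    renamed_trees = tuple(
        Tree(
            name=t.name,
            condition=t.condition,
            categories=tuple(renames[c] for c in t.categories),
            branches=tuple(Branch(b.factors, renames[b.category]) for b in t.branches),
        )
        for t in model.trees
    )
    model_r = MPTModel(name="relabelled", parameters=model.parameters, trees=renamed_trees, conditions=model.conditions)
    data_r = table.data.assign(category=table.data["category"].map(renames))
    fit1 = fit_ml(model_r, FrequencyTable(data_r, aggregated=True), n_starts=6, seed=0)
    assert fit1.g_squared == pytest.approx(fit0.g_squared, abs=1e-6)


def test_lr_test_identical_and_nested(joint_5a, table2_theta, rng):
    table = multinomial_table(joint_5a, table2_theta, EXP1_TOTALS, rng)
    fit5a = fit_ml(joint_5a, table, n_starts=6, seed=0)
    same = lr_test(fit5a, fit5a)
    assert same.delta_g_squared == 0.0 and same.p_value == 1.0

    fit4 = fit_ml(mp.build_2htsm("4"), table, n_starts=6, seed=0)
    cmp_ = lr_test(fit4, fit5a)
    assert cmp_.delta_df == 2
    assert cmp_.delta_g_squared >= 0.0

    with pytest.raises(ValueError, match="more free parameters"):
        lr_test(fit5a, fit4)


def test_delta_g_squared_additive_over_nested_chain(joint_5a, table2_theta, rng):
    """ΔG²(A→C) = ΔG²(A→B) + ΔG²(B→C) for a nested triple."""
    table = multinomial_table(joint_5a, table2_theta, EXP1_TOTALS, rng)
    eq_d = ConstraintSet(equalities=((condition_parameter("d", "wake"), condition_parameter("d", "sleep")),))
    eq_D = ConstraintSet(equalities=((condition_parameter("D", "wake"), condition_parameter("D", "sleep")),))
    mid = mp.apply_constraints(joint_5a, eq_d)
    small = mp.apply_constraints(mid, eq_D)
    f_full = fit_ml(joint_5a, table, n_starts=8, seed=0)
    f_mid = fit_ml(mid, table, n_starts=8, seed=1)
    f_small = fit_ml(small, table, n_starts=8, seed=2)
    total = lr_test(f_small, f_full).delta_g_squared
    step1 = lr_test(f_small, f_mid).delta_g_squared
    step2 = lr_test(f_mid, f_full).delta_g_squared
    assert total == pytest.approx(step1 + step2, abs=1e-6)


def test_condition_comparison_null_and_alternative(joint_5a):
    # expected data with equal d across conditions: ΔG² ~ 0
    equal = joint_theta(WAKE_5A, {**SLEEP_5A, "d": WAKE_5A["d"]})
    table = expected_frequency_table(joint_5a, equal, EXP1_TOTALS)
    res = condition_comparison(joint_5a, table, "d", n_starts=4, seed=0)
    assert res.delta_df == 1
    assert res.delta_g_squared < 1e-6

    # expected data at the published wake/sleep contrast: large ΔG²
    table = expected_frequency_table(joint_5a, joint_theta(WAKE_5A, SLEEP_5A), EXP1_TOTALS)
    res = condition_comparison(joint_5a, table, "d", n_starts=4, seed=0)
    assert res.delta_g_squared > 10
    assert res.p_value < 0.001

    with pytest.raises(ValueError, match="no per-condition copies"):
        condition_comparison(joint_5a, table, "nonexistent")


def test_condition_comparison_type_i_error_near_alpha(joint_5a):
    """Monte-Carlo rejection rate under the null is close to α = .05."""
    rng = np.random.default_rng(77)
    theta = joint_theta(WAKE_5A, {**SLEEP_5A, "d": WAKE_5A["d"]})
    rejections = 0
    reps = 200
    for rep in range(reps):
        table = multinomial_table(joint_5a, theta, EXP1_TOTALS, rng)
        res = condition_comparison(joint_5a, table, "d", n_starts=1, extra_starts=[theta], seed=rep)
        rejections += res.p_value < 0.05
    rate = rejections / reps
    assert 0.015 <= rate <= 0.10  # 0.05 ± ~3 binomial SEs


def _ladder_fit(theta, rng=None):
    base = mp.build_2htsm("general")
    gen = mp.build_2htsm("5a")
    if rng is None:
        table = expected_frequency_table(gen, theta, EXP1_TOTALS)
    else:
        table = multinomial_table(gen, theta, EXP1_TOTALS, rng)
    return base, table


def test_ladder_stops_at_guessing_relaxation_when_a_differs_from_g():
    """Data with a ≠ g reject the full constraint set but keep the rest."""
    base, table = _ladder_fit(joint_theta(WAKE_5A, {**SLEEP_5A, "a": 0.30, "g": 0.70}))
    result = constraint_ladder(base, table, two_htsm_ladder(), alpha=0.05, n_starts=6, seed=0)
    assert result.selected_label == "source-memory invariance"  # 5a-equivalent stage
    assert not result.saturated_fallback
    assert result.stages[-1].rejected  # the a = g stage misfits


def test_ladder_retains_full_constraints_under_submodel_4_data(rng):
    theta4 = joint_theta(
        {**WAKE_5A, "a": WAKE_5A["g"]}, {**SLEEP_5A, "a": SLEEP_5A["g"]}
    )
    base, table = _ladder_fit(theta4, rng)
    result = constraint_ladder(base, table, two_htsm_ladder(), alpha=0.05, n_starts=6, seed=0)
    assert result.selected_label == "guessing invariance"


def test_ladder_alpha_one_gives_saturated_fallback(rng, table2_theta):
    base, table = _ladder_fit(table2_theta, rng)
    result = constraint_ladder(base, table, two_htsm_ladder(), alpha=1.0, n_starts=4, seed=0)
    assert result.saturated_fallback
    assert result.selected_fit is None
    assert len(result.stages) == 4  # base + three constraint groups


def test_boundary_estimate_ci_clipped():
    """A parameter truly at 0 is estimated there with the CI clipped to 0."""
    model = mp.build_2htsm("5a", conditions=("w",))
    theta = {**WAKE_5A, "d": 0.02}
    table = expected_frequency_table(model, {**theta, "d": 0.0}, EXP1_TOTALS)
    fit = fit_ml(model, table, n_starts=8, seed=0)
    assert fit.estimates["d"] < 0.01
    assert fit.ci["d"][0] == 0.0
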