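"""Structure, probabilities and constraint algebra of the MPT models."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mptsource as mp
from mptsource.models import (
    Branch,
    ConstraintSet,
    MPTModel,
    Parameter,
    Tree,
    category_probabilities,
    check_identifiability,
    model_from_yaml,
    model_to_yaml,
)

UNIT = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _all_models():
    return [
        mp.build_2htsm("general"),
        mp.build_2htsm("4"),
        mp.build_2htsm("5a"),
        mp.build_2htsm("5d"),
        mp.build_mdsm(True),
        mp.build_mdsm(False),
    ]


@pytest.mark.parametrize(
    "model,n_free,df",
    [
        (mp.build_2htsm("general"), 16, -4),
        (mp.build_2htsm("4"), 8, 4),
        (mp.build_2htsm("5a"), 10, 2),
        (mp.build_2htsm("5d"), 10, 2),
        (mp.build_mdsm(True), 16, 24),
        (mp.build_mdsm(False), 22, 18),
    ],
    ids=["general", "sub4", "sub5a", "sub5d", "mdsm-constrained", "mdsm-relaxed"],
)
def test_parameter_counts_and_df(model, n_free, df):
    """Free-parameter counts and joint two-condition degrees of freedom."""
    assert model.n_free_parameters == n_free
    assert mp.count_df(model) == df


@given(data=st.data())
@pytest.mark.parametrize("builder", range(6))
def test_tree_probabilities_sum_to_one(builder, data):
    """Law of total probability per tree for any interior assignment."""
    model = _all_models()[builder]
    theta = {n: data.draw(UNIT, label=n) for n in model.free_parameter_names}
    probs = category_probabilities(model, theta)
    for label, vec in probs.items():
        assert vec.sum() == pytest.approx(1.0, abs=1e-12), label
        assert np.all(vec >= -1e-15)


def test_2htsm_branch_composition_examples():
    """Hand-enumerated branch products of the single-dimension model."""
    m = mp.build_2htsm("5a", conditions=("w",))
    p = category_probabilities(m, dict(D=1.0, d=1.0, a=0.3, b=0.2, g=0.7))
    assert p["w:target-left"][0] == pytest.approx(1.0)  # perfect memory
    p = category_probabilities(m, dict(D=0.60, d=0.5, a=0.3, b=0.25, g=0.4))
    # distractor "new": D + (1-D)(1-b)
    assert p["w:distractor"][2] == pytest.approx(0.60 + 0.40 * 0.75)
    p = category_probabilities(m, dict(D=0.60, d=0.48, a=0.44, b=0.25, g=0.47))
    # target miss: (1-D)(1-b)
    assert p["w:target-left"][2] == pytest.approx(0.30)
    # old-left on target-left: D d + D(1-d)a + (1-D)b g
    expected = 0.6 * 0.48 + 0.6 * 0.52 * 0.44 + 0.4 * 0.25 * 0.47
    assert p["w:target-left"][0] == pytest.approx(expected)


def test_mdsm_branch_composition_examples():
    """Position via memory plus colour via conditional guessing, and symmetry."""
    m = mp.build_mdsm(False, conditions=("w",))
    theta = dict(
        D=1.0, d=0.0, e_pos=1.0, e_col=0.0,
        a_pos=0.5, a_col_left=1.0, a_col_right=0.5,
        b=0.5, g_pos=0.5, g_col_left=0.5, g_col_right=0.5,
    )
    p = category_probabilities(m, theta)
    assert p["w:target-left-blue"][0] == pytest.approx(1.0)
    # no memory at all, b = 1, symmetric guessing: uniform over old categories
    theta = dict(
        D=0.0, d=0.0, e_pos=0.0, e_col=0.0,
        a_pos=0.5, a_col_left=0.5, a_col_right=0.5,
        b=1.0, g_pos=0.5, g_col_left=0.5, g_col_right=0.5,
    )
    p = category_probabilities(m, theta)
    for label, vec in p.items():
        assert vec[:4] == pytest.approx([0.25] * 4)
        assert vec[4] == pytest.approx(0.0)


def test_mdsm_colour_blindness_when_unbound_colour_memory_absent(rng):
    """With d = 0 and e_col = 0 colour responses ignore the true colour."""
    m = mp.build_mdsm(False, conditions=("w",))
    theta = {n: rng.uniform(0.1, 0.9) for n in m.free_parameter_names}
    theta["d"] = 0.0
    theta["e_col"] = 0.0
    p = category_probabilities(m, theta)
    blue = p["w:target-left-blue"]
    yellow = p["w:target-left-yellow"]
    assert blue == pytest.approx(yellow, abs=1e-12)


def test_apply_constraints_identity_and_reduction(rng):
    m = mp.build_2htsm("5a", conditions=("w",))
    same = mp.apply_constraints(m, ConstraintSet())
    theta = {n: rng.uniform(0.1, 0.9) for n in m.free_parameter_names}
    assert category_probabilities(m, theta)["w:target-left"] == pytest.approx(
        category_probabilities(same, theta)["w:target-left"]
    )
    # fixing a parameter removes it from the free count
    fixed = mp.apply_constraints(m, ConstraintSet(fixings={"d": 0.0}))
    assert fixed.n_free_parameters == m.n_free_parameters - 1


def test_guessing_equality_reproduces_submodel_4(rng):
    """Equating a = g on submodel 5a yields submodel 4's probabilities."""
    m5a = mp.build_2htsm("5a", conditions=("w",))
    reduced = mp.apply_constraints(m5a, ConstraintSet(equalities=(("g", "a"),)))
    m4 = mp.build_2htsm("4", conditions=("w",))
    assert reduced.n_free_parameters == m4.n_free_parameters == 4
    theta = {n: rng.uniform(0.1, 0.9) for n in m4.free_parameter_names}
    p_red = category_probabilities(reduced, theta)
    p_4 = category_probabilities(m4, theta)
    for label in p_4:
        assert p_red[label] == pytest.approx(p_4[label], abs=1e-14)


def test_contradictory_constraints_raise():
    m = mp.build_2htsm("5a", conditions=("w",))
    with pytest.raises(ValueError, match="contradictory"):
        mp.apply_constraints(
            m, ConstraintSet(equalities=(("a", "g"),), fixings={"a": 0.2, "g": 0.3})
        )
    with pytest.raises(ValueError, match="unknown parameter"):
        mp.apply_constraints(m, ConstraintSet(equalities=(("a", "nope"),)))


def test_saturated_tree_model_has_zero_df():
    tree = Tree(
        name="only",
        categories=("c1", "c2", "c3"),
        branches=(
            Branch((("p", False),), "c1"),
            Branch((("p", True), ("q", False)), "c2"),
            Branch((("p", True), ("q", True)), "c3"),
        ),
    )
    m = MPTModel(name="sat", parameters=(Parameter("p"), Parameter("q")), trees=(tree,))
    assert mp.count_df(m) == 0


def test_identifiability_rank():
    report = check_identifiability(mp.build_2htsm("5a", conditions=("w",)), seed=1)
    assert report.identified and report.rank == 5
    # a redundant product of two parameters is rank deficient
    tree = Tree(
        name="t",
        categories=("c1", "c2"),
        branches=(
            Branch((("p", False), ("q", False)), "c1"),
            Branch((("p", False), ("q", True)), "c2"),
            Branch((("p", True),), "c2"),
        ),
    )
    bad = MPTModel(name="redundant", parameters=(Parameter("p"), Parameter("q")), trees=(tree,))
    # c1 = pq, c2 = 1 - pq: only the product is identified
    rep = check_identifiability(bad, seed=2)
    assert not rep.identified and rep.rank == 1


def test_model_yaml_round_trip(rng):
    for model in (mp.build_2htsm("5a"), mp.build_mdsm(True, conditions=("w",))):
        restored = model_from_yaml(model_to_yaml(model))
        assert restored.free_parameter_names == model.free_parameter_names
        assert mp.count_df(restored) == mp.count_df(model)
        theta = {n: rng.uniform(0.1, 0.9) for n in model.free_parameter_names}
        p0 = category_probabilities(model, theta)
        p1 = category_probabilities(restored, theta)
        for label in p0:
            assert p1[label] == pytest.approx(p0[label], abs=1e-15)


def test_unknown_submodel_rejected():
    with pytest.raises(ValueError):
        mp.build_2htsm("5x")


def test_out_of_range_theta_rejected():
    m = mp.build_2htsm("4", conditions=("w",))
    with pytest.raises(ValueError, match="outside"):
        category_probabilities(m, dict(D=1.2, d=0.5, b=0.5, g=0.5))
    with pytest.raises(ValueError, match="missing"):
        category_probabilities(m, dict(D=0.5))
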