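"""A-priori power analysis for two-group t tests and MPT parameter contrasts.

Two planning tools are provided:

* :func:`ttest_total_n` — the smallest total sample size (equal allocation)
  for which a two-independent-group t test reaches a target power, using the
  exact noncentral-t distribution with noncentrality ``d·sqrt(n/2)`` and
  ``2n - 2`` degrees of freedom.
* :func:`mpt_power` — power of the 1-df ΔG² test for a cross-condition
  difference in one MPT parameter.  The noncentrality λ is obtained by
  fitting the equality-constrained model to the *expected* frequencies under
  the alternative; the test statistic is then noncentral χ²(1, λ) under the
  alternative, and power is its mass beyond the central χ² critical value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FrequencyTable, fit_ml
from .models import (
    ConstraintSet,
    MPTModel,
    apply_constraints,
    condition_parameter,
)

__all__ = [
    "StudyDesign",
    "DESIGNS",
    "PowerResult",
    "ttest_power",
    "ttest_total_n",
    "mpt_power",
    "expected_table_for_design",
]


@dataclass(frozen=True)
class StudyDesign:
    """Item counts per tree (per participant) and participants per group."""

    items_per_tree: Mapping[str, int]
    participants_per_group: Tuple[int, int]

    def total_per_tree(self) -> Dict[str, Tuple[float, float]]:
        n1, n2 = self.participants_per_group
        return {t: (n1 * k, n2 * k) for t, k in self.items_per_tree.items()}


# The two sleep-study designs: 130 planned participants split evenly;
# single-dimension test with 30 targets per side and 30 distractors, and the
# two-dimension test with 30 targets per position×colour combination and 60
# distractors.
DESIGNS: Dict[str, StudyDesign] = {
    "exp1": StudyDesign(
        items_per_tree={"target-left": 30, "target-right": 30, "distractor": 30},
        participants_per_group=(65, 65),
    ),
    "exp2": StudyDesign(
        items_per_tree={
            "target-left-blue": 30,
            "target-left-yellow": 30,
            "target-right-blue": 30,
            "target-right-yellow": 30,
            "distractor": 60,
        },
        participants_per_group=(65, 65),
    ),
}


@dataclass
class PowerResult:
    power: float
    noncentrality: float
    df: int
    critical_value: float
    alpha: float
    total_observations: float


def ttest_power(n_per_group: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of a two-independent-group t test at per-group size n."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    if tails == 2:
        tc = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    if tails == 1:
        tc = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tc, df, ncp))
    raise ValueError("tails must be 1 or 2")


def ttest_total_n(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    max_per_group: int = 1_000_000,
) -> int:
    """Smallest total N (even split) reaching the target t-test power."""
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    for n in range(2, max_per_group + 1):
        if ttest_power(n, d, alpha, tails) >= power:
            return 2 * n
    raise ValueError("target power unreachable within the search limit")


def expected_table_for_design(
    model: MPTModel,
    theta: Mapping[str, float],
    design: StudyDesign,
) -> FrequencyTable:
    """Expected aggregated frequencies for a joint two-condition model."""
    comp = model.compiled()
    probs = comp.category_probs(model.theta_vector(theta))
    cond_index = {c: i for i, c in enumerate(model.conditions)}
    records = []
    for tree, sl in zip(model.trees, comp.tree_slices):
        n_group = design.participants_per_group[cond_index[tree.condition]]
        total = n_group * design.items_per_tree[tree.name]
        for cat, p in zip(tree.categories, probs[sl]):
            records.append(("ALL", tree.condition, tree.name, cat, total * p))
    return FrequencyTable(
        pd.DataFrame(records, columns=["participant", "condition", "tree", "category", "count"]),
        aggregated=True,
    )


def mpt_power(
    model: MPTModel,
    baseline: Mapping[str, float],
    parameter: str,
    delta: float,
    design: StudyDesign,
    alpha: float = 0.05,
    **fit_options,
) -> PowerResult:
    """Noncentral-χ² power for a cross-condition shift in one MPT parameter.

    ``model`` is a joint two-condition model; ``baseline`` assigns the base
    (unsuffixed) parameters, which hold in the first condition, and
    ``parameter`` is shifted by ``delta`` in the second condition.
    """
    if len(model.conditions) != 2:
        raise ValueError("mpt_power expects a joint two-condition model")
    base_val = float(baseline[parameter])
    shifted = base_val + delta
    if not 0.0 <= shifted <= 1.0:
        raise ValueError(f"shifted value {shifted} outside [0, 1]")

    theta: Dict[str, float] = {}
    for cond, shift in zip(model.conditions, (0.0, delta)):
        for base, value in baseline.items():
            theta[condition_parameter(base, cond)] = float(value) + (shift if base == parameter else 0.0)
    table = expected_table_for_design(model, theta, design)

    names = tuple(condition_parameter(parameter, c) for c in model.conditions)
    restricted = apply_constraints(model, ConstraintSet(equalities=(names,)))
    fit_options.setdefault("n_starts", 4)
    extra = list(fit_options.pop("extra_starts", ()) or ())
    extra.append({**{condition_parameter(b, c): v for c in model.conditions for b, v in baseline.items()},
                  names[0]: base_val + delta / 2.0})
    fit = fit_ml(restricted, table, extra_starts=extra, **fit_options)

    lam = max(fit.g_squared, 0.0)
    crit = float(stats.chi2.ppf(1.0 - alpha, 1))
    power = float(stats.ncx2.sf(crit, 1, lam)) if lam > 0 else alpha
    n1, n2 = design.participants_per_group
    total_obs = sum(k * (n1 + n2) for k in design.items_per_tree.values())
    return PowerResult(
        power=power,
        noncentrality=lam,
        df=1,
        critical_value=crit,
        alpha=alpha,
        total_observations=float(total_obs),
    )
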