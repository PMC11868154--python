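"""Maximum-likelihood fitting of MPT models and G²-based inference.

Fitting follows the complete-pooling convention: response counts are summed
over participants within each condition before the multinomial likelihood is
maximised.  Optimisation runs on an unconstrained logit transform of the
unit-interval parameters with analytic gradients and multiple random starts,
because MPT likelihoods can be multimodal near the boundary of the parameter
space.

Goodness of fit is the likelihood-ratio statistic
``G² = 2 Σ n_k ln(n_k / (N p̂_k))`` (with ``0·ln 0 := 0``), asymptotically
χ²-distributed with ``df`` equal to the number of free category
probabilities minus the number of free parameters.  Nested submodels are
compared with ``ΔG²`` (:func:`lr_test`), and :func:`constraint_ladder`
automates the invariance-testing strategy of imposing equality-constraint
groups in order of how essential they are, relaxing the most recently added
group when the fit is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .models import (
    ConstraintSet,
    MPTModel,
    apply_constraints,
    condition_parameter,
    count_df,
)

__all__ = [
    "FrequencyTable",
    "FitResult",
    "ComparisonResult",
    "LadderStage",
    "LadderResult",
    "fit_ml",
    "lr_test",
    "condition_comparison",
    "constraint_ladder",
    "two_htsm_ladder",
    "expected_frequency_table",
]

AGGREGATE_ID = "ALL"
_Z95 = float(stats.norm.ppf(0.975))

TABLE_COLUMNS = ["participant", "condition", "tree", "category", "count"]


class FrequencyTable:
    """Response counts per participant × condition × tree × category.

    Thin wrapper around a tidy :class:`pandas.DataFrame` with columns
    ``participant, condition, tree, category, count``.  Aggregated tables
    (counts summed over participants) carry ``participant == "ALL"``.
    Counts may be non-integral (expected frequencies are valid input to the
    fitting routines).
    """

    def __init__(self, data: pd.DataFrame, aggregated: bool = False) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"frequency table missing columns {missing}")
        df = data.loc[:, TABLE_COLUMNS].copy()
        df["count"] = df["count"].astype(float)
        if (df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        self.data = df.reset_index(drop=True)
        self.aggregated = aggregated

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_records(cls, records, aggregated: bool = False) -> "FrequencyTable":
        return cls(pd.DataFrame.from_records(records, columns=TABLE_COLUMNS), aggregated)

    @classmethod
    def from_csv(cls, path_or_buf) -> "FrequencyTable":
        df = pd.read_csv(path_or_buf)
        aggregated = set(df["participant"].astype(str)) <= {AGGREGATE_ID}
        return cls(df, aggregated=aggregated)

    def to_csv(self, path_or_buf=None) -> Optional[str]:
        return self.data.to_csv(path_or_buf, index=False)

    # -- basic structure -----------------------------------------------------

    @property
    def conditions(self) -> List[str]:
        return sorted(self.data["condition"].unique())

    @property
    def participants(self) -> List[str]:
        return sorted(self.data["participant"].astype(str).unique())

    def subset(self, condition: Optional[str] = None, participant: Optional[str] = None) -> "FrequencyTable":
        df = self.data
        if condition is not None:
            df = df[df["condition"] == condition]
        if participant is not None:
            df = df[df["participant"].astype(str) == str(participant)]
        return FrequencyTable(df, aggregated=self.aggregated)

    def aggregate(self) -> "FrequencyTable":
        """Sum counts over participants within condition (complete pooling)."""
        if self.aggregated:
            return self
        agg = (
            self.data.groupby(["condition", "tree", "category"], as_index=False)["count"]
            .sum()
            .assign(participant=AGGREGATE_ID)
        )
        return FrequencyTable(agg[TABLE_COLUMNS], aggregated=True)

    def counts_for(self, model: MPTModel) -> np.ndarray:
        """Counts aligned with the model's global category order."""
        agg = self.aggregate()
        lookup = {
            (row.condition, row.tree, row.category): row.count
            for row in agg.data.itertuples()
        }
        model_keys = set()
        out = []
        for tree in model.trees:
            for cat in tree.categories:
                key = (tree.condition, tree.name, cat)
                model_keys.add((tree.condition, tree.name))
                out.append(lookup.pop((tree.condition, tree.name, cat), 0.0))
        if lookup:
            extra = sorted({(c, t) for c, t, _ in lookup})
            raise ValueError(f"table contains trees not in the model: {extra}")
        return np.asarray(out, dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FitResult:
    """Maximum-likelihood estimates with Wald inference and fit statistics."""

    model: MPTModel
    estimates: Dict[str, float]
    se: Dict[str, float]
    ci: Dict[str, Tuple[float, float]]
    g_squared: float
    df: int
    p_value: float
    log_lik: float
    n_starts: int
    converged: bool
    start_logliks: List[float] = field(default_factory=list)

    @property
    def n_free_parameters(self) -> int:
        return self.model.n_free_parameters

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.model.free_parameter_names:
            lo, hi = self.ci[name]
            rows.append(
                {
                    "parameter": name,
                    "mle": self.estimates[name],
                    "se": self.se[name],
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Likelihood-ratio comparison of two nested fits."""

    delta_g_squared: float
    delta_df: int
    p_value: float
    restricted: FitResult
    full: FitResult
    parameter: Optional[str] = None


def _g_squared(counts: np.ndarray, probs: np.ndarray, tree_of_cat: np.ndarray, n_trees: int) -> float:
    totals = np.bincount(tree_of_cat, weights=counts, minlength=n_trees)
    expected = totals[tree_of_cat] * probs
    mask = counts > 0
    exp_safe = np.maximum(expected[mask], 1e-300)
    return float(2.0 * np.sum(counts[mask] * np.log(counts[mask] / exp_safe)))


def fit_ml(
    model: MPTModel,
    table: FrequencyTable,
    n_starts: int = 20,
    seed: Optional[int] = None,
    extra_starts: Optional[Sequence[Mapping[str, float]]] = None,
    bound: float = 16.0,
    max_iter: int = 5000,
) -> FitResult:
    """Fit a model to (aggregated) counts by maximum likelihood.

    ``n_starts`` random initialisations are run in addition to a midpoint
    start and any ``extra_starts`` (partial assignments of free parameters;
    unnamed parameters start at 0.5).  Standard errors come from the inverse
    expected information on the probability scale; 95% Wald intervals are
    clipped to the unit interval, as boundary estimates force the asymptotic
    bounds outside the admissible range.
    """
    counts = table.counts_for(model)
    comp = model.compiled()
    n_free = len(comp.param_names)
    if n_free == 0:
        raise ValueError("model has no free parameters")
    rng = np.random.default_rng(seed)

    starts = [np.zeros(n_free)]
    for theta0 in extra_starts or ():
        vec = np.full(n_free, 0.5)
        for i, name in enumerate(comp.param_names):
            if name in theta0:
                vec[i] = float(theta0[name])
        vec = np.clip(vec, 1e-4, 1 - 1e-4)
        starts.append(special.logit(vec))
    for _ in range(max(0, n_starts - 1)):
        starts.append(special.logit(rng.uniform(0.02, 0.98, size=n_free)))

    def objective(eta: np.ndarray) -> Tuple[float, np.ndarray]:
        ll, grad = comp.loglik_grad_eta(eta, counts)
        return -ll, -grad

    best = None
    start_lls: List[float] = []
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-bound, bound)] * n_free,
            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
        )
        start_lls.append(-float(res.fun))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta = special.expit(best.x)
    probs = comp.category_probs(theta)
    g2 = _g_squared(counts, probs, comp.cat_tree, len(comp.tree_labels))
    df = count_df(model)
    p_value = float(stats.chi2.sf(max(g2, 0.0), df)) if df > 0 else (1.0 if df == 0 else float("nan"))

    # Expected Fisher information on the probability scale.
    totals = np.bincount(comp.cat_tree, weights=counts, minlength=len(comp.tree_labels))
    dp = comp.dp_dtheta(theta)
    w = totals[comp.cat_tree] / np.maximum(probs, 1e-12)
    info = dp.T @ (dp * w[:, None])
    cov = np.linalg.pinv(info)
    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    estimates = dict(zip(comp.param_names, map(float, theta)))
    se = dict(zip(comp.param_names, map(float, se_vec)))
    ci = {
        name: (
            float(np.clip(estimates[name] - _Z95 * se[name], 0.0, 1.0)),
            float(np.clip(estimates[name] + _Z95 * se[name], 0.0, 1.0)),
        )
        for name in comp.param_names
    }
    return FitResult(
        model=model,
        estimates=estimates,
        se=se,
        ci=ci,
        g_squared=g2,
        df=df,
        p_value=p_value,
        log_lik=-float(best.fun),
        n_starts=len(starts),
        converged=any_success,
        start_logliks=start_lls,
    )


def lr_test(restricted: FitResult, full: FitResult) -> ComparisonResult:
    """ΔG² test of a restricted model against the full model it nests in."""
    delta_df = full.n_free_parameters - restricted.n_free_parameters
    if delta_df < 0:
        raise ValueError("restricted model has more free parameters than the full model")
    delta_g2 = restricted.g_squared - full.g_squared
    if delta_g2 < -1e-6:
        raise ValueError(
            f"restricted fit beats the full fit (ΔG² = {delta_g2:.3g}); models are not nested "
            "or the full fit did not converge"
        )
    delta_g2 = max(delta_g2, 0.0)
    if delta_df == 0:
        p = 1.0 if delta_g2 <= 1e-6 else 0.0
    else:
        p = float(stats.chi2.sf(delta_g2, delta_df))
    return ComparisonResult(delta_g_squared=delta_g2, delta_df=delta_df, p_value=p, restricted=restricted, full=full)


def condition_comparison(
    model: MPTModel,
    table: FrequencyTable,
    parameter: str,
    **fit_options,
) -> ComparisonResult:
    """Test cross-condition equality of one parameter by ΔG² with 1 df."""
    if len(model.conditions) < 2:
        raise ValueError("condition comparison needs a joint multi-condition model")
    names = [condition_parameter(parameter, c) for c in model.conditions]
    known = {p.name for p in model.parameters}
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValueError(f"parameter {parameter!r} has no per-condition copies {unknown}")
    restricted_model = apply_constraints(model, ConstraintSet(equalities=(tuple(names),)))
    full_fit = fit_ml(model, table, **fit_options)
    fit_options_restricted = dict(fit_options)
    extra = list(fit_options_restricted.pop("extra_starts", ()) or ())
    extra.append(full_fit.estimates)
    restricted_fit = fit_ml(restricted_model, table, extra_starts=extra, **fit_options_restricted)
    result = lr_test(restricted_fit, full_fit)
    result.parameter = parameter
    return result


@dataclass
class LadderStage:
    label: str
    model: MPTModel
    fit: FitResult
    rejected: bool


@dataclass
class LadderResult:
    stages: List[LadderStage]
    selected_label: str
    selected_fit: Optional[FitResult]
    saturated_fallback: bool

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.label,
                    "n_free_parameters": s.fit.n_free_parameters,
                    "g_squared": s.fit.g_squared,
                    "df": s.fit.df,
                    "p_value": s.fit.p_value,
                    "rejected": s.rejected,
                }
                for s in self.stages
            ]
        )


def constraint_ladder(
    base_model: MPTModel,
    table: FrequencyTable,
    ladder: Sequence[Tuple[str, ConstraintSet]],
    alpha: float = 0.05,
    **fit_options,
) -> LadderResult:
    """Impose constraint groups in order; relax the last group on misfit.

    The ladder is ordered from the most to the least essential constraint
    group.  All cumulative models (base plus each prefix of the ladder) are
    fitted; the selected model is the most parsimonious one whose
    goodness-of-fit test is not rejected at ``alpha``.  If every model is
    rejected the per-tree saturated model is returned as fallback
    (``selected_fit`` is ``None`` — it has ``G² = 0`` by construction).
    """
    models: List[Tuple[str, MPTModel]] = [("base", base_model)]
    current = base_model
    for label, cset in ladder:
        current = apply_constraints(current, cset)
        models.append((label, current))

    stages: List[LadderStage] = []
    for label, mdl in models:
        fit = fit_ml(mdl, table, **fit_options)
        # Only stages with a falsifiable fit (df > 0) are selectable; an
        # over-parameterised or just-identified stage fits trivially and is
        # recorded in the audit as rejected.
        rejected = not (fit.df > 0 and fit.p_value >= alpha)
        stages.append(LadderStage(label=label, model=mdl, fit=fit, rejected=rejected))

    for stage in reversed(stages):
        if not stage.rejected:
            return LadderResult(stages=stages, selected_label=stage.label, selected_fit=stage.fit, saturated_fallback=False)
    return LadderResult(stages=stages, selected_label="saturated", selected_fit=None, saturated_fallback=True)


def two_htsm_ladder(conditions: Sequence[str] = ("wake", "sleep")) -> List[Tuple[str, ConstraintSet]]:
    """The invariance ladder for the 2HTSM: item memory, source memory, guessing."""
    conditions = tuple(conditions)
    multi = len(conditions) > 1

    def name(base: str, cond: str) -> str:
        return condition_parameter(base, cond) if multi else base

    item = tuple(tuple(name(b, c) for b in ("D_left", "D_right", "D_new")) for c in conditions)
    source = tuple(tuple(name(b, c) for b in ("d_left", "d_right")) for c in conditions)
    guess = tuple(tuple(name(b, c) for b in ("g", "a")) for c in conditions)
    return [
        ("item-memory invariance", ConstraintSet(equalities=item)),
        ("source-memory invariance", ConstraintSet(equalities=source)),
        ("guessing invariance", ConstraintSet(equalities=guess)),
    ]


def expected_frequency_table(
    model: MPTModel,
    theta: Mapping[str, float],
    totals: Mapping[str, float],
) -> FrequencyTable:
    """Expected counts per tree under ``theta``; ``totals`` maps tree *name*
    (item type) to the total observation count per condition."""
    comp = model.compiled()
    probs = comp.category_probs(model.theta_vector(theta))
    records = []
    for tree, sl in zip(model.trees, comp.tree_slices):
        n = float(totals[tree.name])
        for cat, p in zip(tree.categories, probs[sl]):
            records.append((AGGREGATE_ID, tree.condition, tree.name, cat, n * p))
    return FrequencyTable.from_records(records, aggregated=True)
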