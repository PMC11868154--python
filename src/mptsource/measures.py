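"""Traditional recognition and source-identification measures.

These are the standard, model-free summaries of a source-monitoring test:

* hit and false-alarm rates, and the signal-detection indices
  ``d' = z(H) - z(FA)`` (sensitivity) and ``c = -(z(H) + z(FA)) / 2``
  (response criterion, negative = liberal "old" bias), computed per
  participant and then averaged — never pooled;
* SIM, the proportion of correct source attributions over *all* targets;
  ACSIM, the proportion of correct attributions among recognized targets
  averaged over the two sources; and CSIM, the unaveraged conditional
  proportion, reported when ACSIM is undefined because every recognized
  target was assigned to the same source;
* pooled-variance two-sample t tests with Cohen's d and its large-sample
  normal-approximation confidence interval, and mixed / between-subjects
  ANOVAs with partial η².

Note these measures confound memory and guessing to varying degrees; the
model-based parameters in :mod:`mptsource.fit` are the uncontaminated
counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .fit import FrequencyTable

__all__ = [
    "EffectReport",
    "recognition_summary",
    "source_id_measures",
    "two_sample_t",
    "mixed_anova_table",
    "between_anova_table",
    "partial_eta_squared",
    "cohen_d_ci",
    "group_report",
]

_Z95 = float(stats.norm.ppf(0.975))


def _corrected_rate(successes: float, total: float) -> float:
    """Observed rate with a log-linear correction applied at the extremes.

    Rates of exactly 0 or 1 make the normal quantile infinite; such rates
    are replaced by ``(k + 0.5) / (n + 1)``.  Interior rates are untouched.
    """
    if total <= 0:
        raise ValueError("rate denominator must be positive")
    rate = successes / total
    if rate <= 0.0 or rate >= 1.0:
        rate = (successes + 0.5) / (total + 1.0)
    return rate


def recognition_summary(table: FrequencyTable) -> pd.DataFrame:
    """Per-participant hit/false-alarm rates, d' and criterion c.

    Works for both designs: targets are trees whose name starts with
    ``target``; any category other than ``new`` counts as an "old" response.
    """
    rows = []
    for (pid, cond), df in table.data.groupby(["participant", "condition"], sort=True):
        is_target = df["tree"].str.startswith("target")
        is_old = df["category"] != "new"
        n_targets = df.loc[is_target, "count"].sum()
        n_distractors = df.loc[~is_target, "count"].sum()
        if n_targets <= 0 or n_distractors <= 0:
            raise ValueError(f"participant {pid!r} has empty target or distractor totals")
        hits = df.loc[is_target & is_old, "count"].sum()
        fas = df.loc[~is_target & is_old, "count"].sum()
        h = _corrected_rate(hits, n_targets)
        f = _corrected_rate(fas, n_distractors)
        zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "n_targets": n_targets,
                "n_distractors": n_distractors,
                "hit_rate": hits / n_targets,
                "fa_rate": fas / n_distractors,
                "dprime": zh - zf,
                "criterion": -(zh + zf) / 2.0,
            }
        )
    return pd.DataFrame(rows)


def _source_tokens(tree_name: str, category: str, dimension: Optional[str]) -> Tuple[Optional[str], Optional[str]]:
    """(true source, responded source) on the requested dimension."""
    parts = tree_name.split("-")[1:]  # drop "target"
    if category == "new":
        resp_parts = None
    else:
        resp_parts = category.split("-")[1:]  # drop "old"
    if dimension is None or len(parts) == 1:
        true = parts[0]
        resp = resp_parts[0] if resp_parts else None
    elif dimension == "position":
        true = parts[0]
        resp = resp_parts[0] if resp_parts else None
    elif dimension == "color":
        true = parts[1]
        resp = resp_parts[1] if resp_parts else None
    else:
        raise ValueError(f"unknown source dimension {dimension!r}")
    return true, resp


def source_id_measures(table: FrequencyTable, dimension: Optional[str] = None) -> pd.DataFrame:
    """Per-participant SIM, ACSIM and CSIM for one source dimension.

    ``dimension`` is ``None`` for the single-dimension design, or
    ``"position"`` / ``"color"`` for the two-dimension design.  ``ACSIM`` is
    undefined when one of the two sources has no recognized target; the
    ``source_memory`` column then falls back on CSIM, and ``measure`` says
    which one was used.  Participants without any hit are flagged.
    """
    rows = []
    for (pid, cond), df in table.data.groupby(["participant", "condition"], sort=True):
        targets = df[df["tree"].str.startswith("target")]
        n_targets = targets["count"].sum()
        hits_by_source: dict = {}
        correct_by_source: dict = {}
        for row in targets.itertuples():
            true, resp = _source_tokens(row.tree, row.category, dimension)
            if resp is None:
                continue
            hits_by_source[true] = hits_by_source.get(true, 0.0) + row.count
            if resp == true:
                correct_by_source[true] = correct_by_source.get(true, 0.0) + row.count
        sources = sorted(hits_by_source) if hits_by_source else []
        total_hits = sum(hits_by_source.values())
        total_correct = sum(correct_by_source.values())
        sim = total_correct / n_targets if n_targets > 0 else np.nan
        acsim_defined = len(sources) == 2 and all(hits_by_source[s] > 0 for s in sources)
        if acsim_defined:
            acsim = float(
                np.mean([correct_by_source.get(s, 0.0) / hits_by_source[s] for s in sources])
            )
        else:
            acsim = np.nan
        csim = total_correct / total_hits if total_hits > 0 else np.nan
        if total_hits == 0:
            measure, value = "undefined", np.nan
        elif acsim_defined:
            measure, value = "ACSIM", acsim
        else:
            measure, value = "CSIM", csim
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "sim": sim,
                "acsim": acsim,
                "csim": csim,
                "acsim_defined": acsim_defined,
                "measure": measure,
                "source_memory": value,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EffectReport:
    """Two-group comparison: pooled t, Cohen's d with CI, group summaries."""

    t: float
    df: int
    p_value: float
    cohen_d: float
    d_ci: Tuple[float, float]
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    n_a: int
    n_b: int


def cohen_d_ci(d: float, n_a: int, n_b: int, level: float = 0.95) -> Tuple[float, float]:
    """Large-sample (Hedges–Olkin) normal-approximation CI for Cohen's d."""
    var = (n_a + n_b) / (n_a * n_b) + d**2 / (2.0 * (n_a + n_b))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(var)
    return (float(d - half), float(d + half))


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> EffectReport:
    """Pooled-variance Student t test of group b against reference group a.

    Cohen's d is ``(mean_b - mean_a) / s_pooled``, so a positive d means the
    second group scored higher.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need at least two observations")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    diff = b.mean() - a.mean()
    t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    d = diff / np.sqrt(sp2)
    return EffectReport(
        t=float(t),
        df=df,
        p_value=p,
        cohen_d=float(d),
        d_ci=cohen_d_ci(d, n_a, n_b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(n_a)),
        se_b=float(b.std(ddof=1) / np.sqrt(n_b)),
        n_a=n_a,
        n_b=n_b,
    )


def partial_eta_squared(f: float, df1: int, df2: int) -> float:
    """Partial η² recovered from an F statistic and its degrees of freedom."""
    return float(f * df1 / (f * df1 + df2))


def mixed_anova_table(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
) -> pd.DataFrame:
    """Mixed (between × within) ANOVA; returns F, dfs, p and partial η²."""
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between, subject=subject)
    rows = []
    for row in aov.itertuples():
        f = float(row.F)
        df1, df2 = int(row.DF1), int(row.DF2)
        rows.append(
            {
                "effect": row.Source,
                "F": f,
                "df1": df1,
                "df2": df2,
                "p_value": float(getattr(row, "p_unc", np.nan)),
                "partial_eta_sq": partial_eta_squared(f, df1, df2),
            }
        )
    return pd.DataFrame(rows)


def between_anova_table(data: pd.DataFrame, dv: str, factors: Sequence[str]) -> pd.DataFrame:
    """Two-way between-subjects ANOVA (type II sums of squares)."""
    if data[dv].isna().any():
        data = data.dropna(subset=[dv])
    terms = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"{dv} ~ {terms}", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    df_resid = int(aov.loc["Residual", "df"])
    rows = []
    for effect, row in aov.iterrows():
        if effect == "Residual":
            continue
        ss = float(row["sum_sq"])
        rows.append(
            {
                "effect": effect,
                "F": float(row["F"]),
                "df1": int(row["df"]),
                "df2": df_resid,
                "p_value": float(row["PR(>F)"]),
                "partial_eta_sq": ss / (ss + ss_resid),
            }
        )
    return pd.DataFrame(rows)


def group_report(
    measures: pd.DataFrame,
    columns: Sequence[str],
    conditions: Tuple[str, str],
) -> pd.DataFrame:
    """Table of group means/SEs with t, p and Cohen's d per measure.

    ``measures`` is a per-participant frame with a ``condition`` column;
    ``conditions`` gives (reference, comparison) group order so that a
    positive d favours the second (e.g. sleep) group.
    """
    ref, cmp_ = conditions
    rows = []
    for col in columns:
        sub = measures.dropna(subset=[col])
        a = sub.loc[sub["condition"] == ref, col].to_numpy()
        b = sub.loc[sub["condition"] == cmp_, col].to_numpy()
        rep = two_sample_t(a, b)
        rows.append(
            {
                "measure": col,
                f"mean_{ref}": rep.mean_a,
                f"se_{ref}": rep.se_a,
                f"mean_{cmp_}": rep.mean_b,
                f"se_{cmp_}": rep.se_b,
                "t": rep.t,
                "df": rep.df,
                "p_value": rep.p_value,
                "cohen_d": rep.cohen_d,
                "d_ci_lower": rep.d_ci[0],
                "d_ci_upper": rep.d_ci[1],
            }
        )
    return pd.DataFrame(rows)
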