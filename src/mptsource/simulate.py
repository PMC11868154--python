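"""Synthetic source-monitoring cohorts with latent-trait heterogeneity.

The generator emulates the statistical structure the analysis pipeline
assumes: each participant carries a true MPT parameter vector drawn on the
probit scale around condition-specific group means (so that heterogeneous
parameters stay in the unit interval), responds to the design's items by
multinomial sampling from the model's category probabilities, and comes with
the screening metadata the exclusion rules act on (retention interval,
alcohol intake, reported sex, orienting-task accuracy, distraction flag).

Defaults encode the two study designs:

* ``exp1`` — two conditions (wake/sleep, 65/67 participants), 30 "left" and
  30 "right" targets plus 30 distractors per participant, three response
  categories, generating means taken from the published aggregated
  estimates (wake D=.60, d=.48, a=.44, b=.25, g=.47; sleep D=.65, d=.63,
  a=.48, b=.20, g=.64 — a sleep effect of +.05 on item memory and +.15 on
  source memory);
* ``exp2`` — 62/72 participants, 30 targets per position×colour combination
  plus 60 distractors, five response categories, generating means from the
  published relaxed-guessing estimates.

Metadata distributions are compliant by default; ``exclusion_rates`` dials
in violation pressure per screening rule for testing the screening stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FrequencyTable, TABLE_COLUMNS
from .models import MPTModel, build_2htsm, build_mdsm

__all__ = [
    "EXP1_GROUP_MEANS",
    "EXP2_GROUP_MEANS",
    "SyntheticConfig",
    "SyntheticCohort",
    "design_model",
    "design_items",
    "draw_cohort",
    "screen_participants",
    "aggregate_frequencies",
]

EXP1_GROUP_MEANS: Dict[str, Dict[str, float]] = {
    "wake": {"D": 0.60, "d": 0.48, "a": 0.44, "b": 0.25, "g": 0.47},
    "sleep": {"D": 0.65, "d": 0.63, "a": 0.48, "b": 0.20, "g": 0.64},
}

EXP2_GROUP_MEANS: Dict[str, Dict[str, float]] = {
    "wake": {
        "D": 0.33, "d": 0.04, "e_pos": 0.30, "e_col": 0.07,
        "a_pos": 0.48, "a_col_left": 0.51, "a_col_right": 0.61,
        "b": 0.21, "g_pos": 0.51, "g_col_left": 0.49, "g_col_right": 0.47,
    },
    "sleep": {
        "D": 0.40, "d": 0.04, "e_pos": 0.43, "e_col": 0.10,
        "a_pos": 0.43, "a_col_left": 0.50, "a_col_right": 0.57,
        "b": 0.21, "g_pos": 0.55, "g_col_left": 0.53, "g_col_right": 0.52,
    },
}

_DESIGN_ITEMS = {
    "exp1": {"target-left": 30, "target-right": 30, "distractor": 30},
    "exp2": {
        "target-left-blue": 30,
        "target-left-yellow": 30,
        "target-right-blue": 30,
        "target-right-yellow": 30,
        "distractor": 60,
    },
}

_DESIGN_N = {"exp1": (65, 67), "exp2": (62, 72)}

_METADATA_COLUMNS = ["sex", "retention_h", "alcohol_g", "orienting_acc", "distracted"]


def design_items(design: str) -> Dict[str, int]:
    if design not in _DESIGN_ITEMS:
        raise ValueError(f"unknown design {design!r}; expected 'exp1' or 'exp2'")
    return dict(_DESIGN_ITEMS[design])


def design_model(design: str, condition: str) -> MPTModel:
    """Single-condition generating model for a design."""
    if design == "exp1":
        return build_2htsm("5a", conditions=(condition,))
    if design == "exp2":
        return build_mdsm(constrained_guessing=False, conditions=(condition,))
    raise ValueError(f"unknown design {design!r}; expected 'exp1' or 'exp2'")


@dataclass
class SyntheticConfig:
    """Generating configuration for a synthetic cohort.

    ``probit_sd`` is the between-participant standard deviation of each
    parameter on the probit scale (scalar or per-parameter mapping); 0.3 is
    a moderate heterogeneity default.  ``probit_cov`` overrides it with a
    full covariance matrix over the design's parameter order.
    ``exclusion_rates`` gives the per-rule probability of drawing metadata
    that violates the corresponding screening rule.
    """

    design: str = "exp1"
    conditions: Tuple[str, str] = ("wake", "sleep")
    n_per_condition: Optional[Tuple[int, int]] = None
    group_means: Optional[Dict[str, Dict[str, float]]] = None
    probit_sd: Union[float, Mapping[str, float]] = 0.3
    probit_cov: Optional[np.ndarray] = None
    seed: Optional[int] = None
    female_rate: float = 0.64
    exclusion_rates: Dict[str, float] = field(
        default_factory=lambda: {"distracted": 0.0, "retention": 0.0, "alcohol": 0.0, "orienting": 0.0}
    )

    def resolved_n(self) -> Tuple[int, int]:
        return self.n_per_condition or _DESIGN_N[self.design]

    def resolved_means(self) -> Dict[str, Dict[str, float]]:
        if self.group_means is not None:
            means = self.group_means
        else:
            means = EXP1_GROUP_MEANS if self.design == "exp1" else EXP2_GROUP_MEANS
        for cond, mm in means.items():
            for k, v in mm.items():
                if not 0.0 < v < 1.0:
                    raise ValueError(f"group mean {k}={v} for {cond!r} must be in (0, 1)")
        return means

    def covariance(self, param_order: Sequence[str]) -> np.ndarray:
        if self.probit_cov is not None:
            cov = np.asarray(self.probit_cov, dtype=float)
            if cov.shape != (len(param_order), len(param_order)):
                raise ValueError("probit_cov shape does not match the parameter count")
            eig = np.linalg.eigvalsh(cov)
            if eig.min() < -1e-10:
                raise ValueError("probit_cov is not positive semi-definite")
            return cov
        if isinstance(self.probit_sd, Mapping):
            sds = np.asarray([float(self.probit_sd.get(p, 0.0)) for p in param_order])
        else:
            sds = np.full(len(param_order), float(self.probit_sd))
        return np.diag(sds**2)


@dataclass
class SyntheticCohort:
    """Participant records plus their response counts and provenance."""

    config: SyntheticConfig
    participants: pd.DataFrame  # metadata + true parameter columns (true_*)
    counts: FrequencyTable  # participant-level

    @property
    def parameter_names(self) -> List[str]:
        return [c[len("true_"):] for c in self.participants.columns if c.startswith("true_")]

    def frequency_table(self) -> FrequencyTable:
        return self.counts

    def select(self, participant_ids: Sequence[str]) -> "SyntheticCohort":
        keep = set(map(str, participant_ids))
        part = self.participants[self.participants["participant"].astype(str).isin(keep)]
        cnt = self.counts.data[self.counts.data["participant"].astype(str).isin(keep)]
        return SyntheticCohort(
            config=self.config,
            participants=part.reset_index(drop=True),
            counts=FrequencyTable(cnt, aggregated=False),
        )


def draw_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a fully seed-reproducible cohort under the configured design."""
    rng = np.random.default_rng(config.seed)
    means = config.resolved_means()
    items = design_items(config.design)
    n_by_cond = dict(zip(config.conditions, config.resolved_n()))

    part_rows: List[dict] = []
    count_rows: List[tuple] = []
    for cond in config.conditions:
        model = design_model(config.design, cond)
        comp = model.compiled()
        param_order = comp.param_names
        mu = stats.norm.ppf([means[cond][p] for p in param_order])
        cov = config.covariance(param_order)
        rates = config.exclusion_rates
        for i in range(n_by_cond[cond]):
            pid = f"{cond}-{i + 1:03d}"
            eta = mu + rng.multivariate_normal(np.zeros(len(param_order)), cov)
            theta = stats.norm.cdf(eta)

            sex = "female" if rng.random() < config.female_rate else "male"
            if rng.random() < rates.get("retention", 0.0):
                retention = rng.choice([rng.uniform(9.5, 10.9), rng.uniform(13.1, 14.5)])
            else:
                retention = rng.uniform(11.25, 12.75)
            limit = 20.0 if sex == "female" else 40.0
            if rng.random() < rates.get("alcohol", 0.0):
                alcohol = limit + rng.uniform(5.0, 30.0)
            else:
                alcohol = rng.uniform(0.0, 0.6 * limit)
            if rng.random() < rates.get("orienting", 0.0):
                orienting = rng.uniform(0.2, 0.5)
            else:
                orienting = rng.uniform(0.9, 1.0)
            distracted = bool(rng.random() < rates.get("distracted", 0.0))

            row = {
                "participant": pid,
                "condition": cond,
                "sex": sex,
                "retention_h": float(retention),
                "alcohol_g": float(alcohol),
                "orienting_acc": float(orienting),
                "distracted": distracted,
            }
            for p, v in zip(param_order, theta):
                row[f"true_{p}"] = float(v)
            part_rows.append(row)

            probs = comp.category_probs(theta)
            for tree, sl in zip(model.trees, comp.tree_slices):
                draws = rng.multinomial(items[tree.name], probs[sl] / probs[sl].sum())
                for cat, k in zip(tree.categories, draws):
                    count_rows.append((pid, cond, tree.name, cat, float(k)))

    participants = pd.DataFrame(part_rows)
    counts = FrequencyTable(pd.DataFrame(count_rows, columns=TABLE_COLUMNS), aggregated=False)
    return SyntheticCohort(config=config, participants=participants, counts=counts)


def _recognition_rates(counts: FrequencyTable) -> pd.DataFrame:
    """Raw hit/false-alarm rates per participant (no extreme-rate correction)."""
    df = counts.data
    is_target = df["tree"].str.startswith("target")
    is_old = df["category"] != "new"
    grp = df.assign(target=is_target, old=is_old).groupby("participant")
    out = grp.apply(
        lambda g: pd.Series(
            {
                "hit_rate": g.loc[g.target & g.old, "count"].sum() / max(g.loc[g.target, "count"].sum(), 1.0),
                "fa_rate": g.loc[~g.target & g.old, "count"].sum() / max(g.loc[~g.target, "count"].sum(), 1.0),
            }
        ),
        include_groups=False,
    )
    return out


def screen_participants(cohort: SyntheticCohort) -> Tuple[SyntheticCohort, pd.DataFrame]:
    """Apply the exclusion rules in order and log each exclusion.

    Rules, in order: self-reported distraction; retention interval outside
    11–13 h; alcohol above 20 g (female) / 40 g (male); orienting-task
    accuracy at or below 50%; false-alarm rate exceeding hit rate.  Each
    participant is excluded at most once, under the first rule that fires.
    """
    part = cohort.participants.set_index("participant", drop=False)
    rates = _recognition_rates(cohort.counts)
    log_rows: List[dict] = []
    excluded: set = set()

    def apply_rule(rule: str, mask: pd.Series) -> None:
        for pid in part.index[mask]:
            if pid not in excluded:
                excluded.add(pid)
                log_rows.append({"participant": pid, "rule": rule})

    apply_rule("distracted", part["distracted"].astype(bool))
    apply_rule("retention-interval", (part["retention_h"] < 11.0) | (part["retention_h"] > 13.0))
    limit = np.where(part["sex"] == "female", 20.0, 40.0)
    apply_rule("alcohol", pd.Series(part["alcohol_g"].to_numpy() > limit, index=part.index))
    apply_rule("orienting-task", part["orienting_acc"] <= 0.5)
    fa_gt_hit = rates["fa_rate"] > rates["hit_rate"]
    apply_rule("fa-exceeds-hit", fa_gt_hit.reindex(part.index).fillna(False))

    keep = [pid for pid in part.index if pid not in excluded]
    log = pd.DataFrame(log_rows, columns=["participant", "rule"])
    return cohort.select(keep), log


def aggregate_frequencies(cohort: SyntheticCohort) -> FrequencyTable:
    """Counts summed over participants per condition (complete pooling)."""
    if len(cohort.counts) == 0:
        raise ValueError("empty cohort")
    return cohort.counts.aggregate()
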