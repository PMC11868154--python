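"""Binary multinomial processing tree (MPT) models of source monitoring.

An MPT model explains categorical response frequencies as sums over latent
processing branches.  Each branch is a product of parameters ``θ`` and
complements ``1-θ`` and terminates in exactly one observable response
category, so that for every tree (item type) the category probabilities sum
to one.

Two model families are provided:

* :func:`build_2htsm` — the two-high-threshold source-monitoring model for a
  single source dimension (screen side left/right), together with its
  equality-constrained submodels ``4``, ``5a`` and ``5d``.
* :func:`build_mdsm` — the multidimensional source-monitoring model for two
  orthogonal source dimensions (position left/right × frame colour
  blue/yellow), with item memory ``D`` (shared with distractor detection),
  bound source memory ``d``, unbound source memories ``e_pos``/``e_col`` and
  a conditional colour-guessing stage keyed on the *assigned* position.

Models can span several between-subjects conditions (e.g. wake/sleep); a
joint model simply carries one parameter copy per condition and
cross-condition hypotheses become equality constraints
(:class:`ConstraintSet`, :func:`apply_constraints`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "ROLES",
    "Parameter",
    "Branch",
    "Tree",
    "MPTModel",
    "ConstraintSet",
    "IdentifiabilityReport",
    "condition_parameter",
    "build_2htsm",
    "build_mdsm",
    "apply_constraints",
    "category_probabilities",
    "count_df",
    "check_identifiability",
    "model_to_yaml",
    "model_from_yaml",
]

ROLES = (
    "item-memory",
    "source-memory",
    "bound-source-memory",
    "unbound-source-memory",
    "guessing",
)

EXP1_CATEGORIES = ("old-left", "old-right", "new")
EXP2_CATEGORIES = (
    "old-left-blue",
    "old-left-yellow",
    "old-right-blue",
    "old-right-yellow",
    "new",
)


@dataclass(frozen=True)
class Parameter:
    """A named model probability with a substantive role."""

    name: str
    role: str = "guessing"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown parameter role {self.role!r}; expected one of {ROLES}")


@dataclass(frozen=True)
class Branch:
    """One processing path: a product of factors ending in a category.

    ``factors`` is a sequence of ``(parameter_name, complemented)`` pairs;
    ``complemented`` selects the ``1-θ`` factor.
    """

    factors: Tuple[Tuple[str, bool], ...]
    category: str

    def format(self) -> str:
        if not self.factors:
            return f"1 -> {self.category}"
        terms = " * ".join(f"(1-{n})" if c else n for n, c in self.factors)
        return f"{terms} -> {self.category}"


@dataclass(frozen=True)
class Tree:
    """All processing branches for one item type in one condition."""

    name: str
    categories: Tuple[str, ...]
    branches: Tuple[Branch, ...]
    condition: Optional[str] = None

    @property
    def label(self) -> str:
        return f"{self.condition}:{self.name}" if self.condition else self.name


def condition_parameter(base: str, condition: str) -> str:
    """Name of the per-condition copy of a base parameter in a joint model."""
    return f"{base}|{condition}"


class CompiledModel:
    """Matrix form of an MPT model for fast likelihood work.

    Branch probabilities are ``const * Π θ^A * (1-θ)^C`` with integer
    exponent matrices ``A``/``C`` over the free parameters; fixed parameters
    are folded into ``const``.  ``M`` scatters branches into the global
    category vector (trees concatenated in model order).
    """

    def __init__(self, model: "MPTModel") -> None:
        free = model.free_parameter_names
        self.param_names: List[str] = list(free)
        idx = {n: i for i, n in enumerate(free)}
        n_free = len(free)

        a_rows, c_rows, consts, cat_idx = [], [], [], []
        self.tree_labels: List[str] = []
        self.tree_slices: List[slice] = []
        self.tree_categories: List[Tuple[str, ...]] = []
        offset = 0
        for tree in model.trees:
            self.tree_labels.append(tree.label)
            self.tree_categories.append(tree.categories)
            self.tree_slices.append(slice(offset, offset + len(tree.categories)))
            cat_pos = {c: offset + j for j, c in enumerate(tree.categories)}
            for br in tree.branches:
                a = np.zeros(n_free)
                c = np.zeros(n_free)
                const = 1.0
                for name, comp in br.factors:
                    if name in model.fixed:
                        v = model.fixed[name]
                        const *= (1.0 - v) if comp else v
                    else:
                        if comp:
                            c[idx[name]] += 1
                        else:
                            a[idx[name]] += 1
                a_rows.append(a)
                c_rows.append(c)
                consts.append(const)
                cat_idx.append(cat_pos[br.category])
            offset += len(tree.categories)

        self.A = np.asarray(a_rows)
        self.C = np.asarray(c_rows)
        self.const = np.asarray(consts)
        self.cat_index = np.asarray(cat_idx, dtype=int)
        self.n_categories = offset
        self.M = np.zeros((offset, len(cat_idx)))
        self.M[self.cat_index, np.arange(len(cat_idx))] = 1.0
        # category -> tree index, for per-tree totals
        self.cat_tree = np.empty(offset, dtype=int)
        for t, sl in enumerate(self.tree_slices):
            self.cat_tree[sl] = t

    # -- probability evaluations -------------------------------------------------

    def branch_probabilities(self, theta: np.ndarray) -> np.ndarray:
        return self.const * np.prod(
            np.power(theta, self.A) * np.power(1.0 - theta, self.C), axis=1
        )

    def category_probs(self, theta: np.ndarray) -> np.ndarray:
        return self.M @ self.branch_probabilities(theta)

    def category_probs_multi(self, thetas: np.ndarray) -> np.ndarray:
        """Category probabilities for a batch of parameter vectors (n, P)."""
        th = thetas[:, None, :]
        bp = self.const * np.prod(
            np.power(th, self.A) * np.power(1.0 - th, self.C), axis=2
        )
        return bp @ self.M.T

    def loglik_grad_eta(self, eta: np.ndarray, counts: np.ndarray) -> Tuple[float, np.ndarray]:
        """Multinomial log-likelihood and gradient on the logit scale.

        On the logit scale ``dθ/dη = θ(1-θ)`` cancels the boundary-singular
        terms of the probability-scale gradient, so this is stable even when
        estimates drift toward 0 or 1.
        """
        theta = 1.0 / (1.0 + np.exp(-eta))
        bp = self.branch_probabilities(theta)
        p = self.M @ bp
        p_safe = np.maximum(p, 1e-300)
        ll = float(counts @ np.log(p_safe))
        w = self.A * (1.0 - theta) - self.C * theta  # (B, P)
        dp = self.M @ (bp[:, None] * w)  # (K, P)
        grad = (counts / p_safe) @ dp
        return ll, grad

    def dp_dtheta(self, theta: np.ndarray) -> np.ndarray:
        """Jacobian of category probabilities w.r.t. θ, (K, P)."""
        th = np.clip(theta, 1e-10, 1.0 - 1e-10)
        bp = self.branch_probabilities(th)
        w = self.A / th - self.C / (1.0 - th)
        return self.M @ (bp[:, None] * w)


@dataclass
class MPTModel:
    """A declarative binary MPT model, possibly spanning several conditions."""

    name: str
    parameters: Tuple[Parameter, ...]
    trees: Tuple[Tree, ...]
    conditions: Tuple[str, ...] = ()
    fixed: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique within a model")
        known = set(names)
        for k, v in self.fixed.items():
            if k not in known:
                raise ValueError(f"fixed parameter {k!r} is not declared")
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"fixed value for {k!r} outside [0, 1]")
        if not self.conditions:
            conds = []
            for t in self.trees:
                if t.condition and t.condition not in conds:
                    conds.append(t.condition)
            self.conditions = tuple(conds)
        for tree in self.trees:
            for br in tree.branches:
                for n, _ in br.factors:
                    if n not in known:
                        raise ValueError(f"branch factor {n!r} in tree {tree.label!r} is not a declared parameter")
                if br.category not in tree.categories:
                    raise ValueError(f"branch category {br.category!r} not among tree {tree.label!r} categories")

    # -- derived structure ---------------------------------------------------

    @property
    def free_parameter_names(self) -> List[str]:
        return [p.name for p in self.parameters if p.name not in self.fixed]

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameter_names)

    def parameter_roles(self) -> Dict[str, str]:
        return {p.name: p.role for p in self.parameters}

    def compiled(self) -> CompiledModel:
        comp = self.__dict__.get("_compiled")
        if comp is None:
            comp = CompiledModel(self)
            self.__dict__["_compiled"] = comp
        return comp

    def tree(self, label: str) -> Tree:
        for t in self.trees:
            if t.label == label:
                return t
        raise KeyError(label)

    def theta_vector(self, theta: Mapping[str, float]) -> np.ndarray:
        free = self.free_parameter_names
        missing = [n for n in free if n not in theta]
        if missing:
            raise ValueError(f"incomplete parameter assignment; missing {missing}")
        vec = np.asarray([float(theta[n]) for n in free])
        if np.any((vec < 0.0) | (vec > 1.0)):
            bad = [n for n, v in zip(free, vec) if not 0.0 <= v <= 1.0]
            raise ValueError(f"parameter values outside [0, 1]: {bad}")
        return vec


@dataclass(frozen=True)
class ConstraintSet:
    """Equality classes and fixings defining a submodel.

    ``equalities`` is a sequence of name classes; the first member of each
    class becomes the surviving (canonical) parameter.  ``fixings`` pins
    parameters to constants.
    """

    equalities: Tuple[Tuple[str, ...], ...] = ()
    fixings: Mapping[str, float] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not self.equalities and not self.fixings


def apply_constraints(model: MPTModel, constraints: ConstraintSet) -> MPTModel:
    """Return the reduced model obtained by equating/fixing parameters.

    The category-probability function is unchanged under any assignment that
    respects the constraints; contradictory fixings raise ``ValueError``.
    """
    declared = [p.name for p in model.parameters]
    known = set(declared)
    for cls in constraints.equalities:
        for n in cls:
            if n not in known:
                raise ValueError(f"equality constraint names unknown parameter {n!r}")
    for n in constraints.fixings:
        if n not in known:
            raise ValueError(f"fixing names unknown parameter {n!r}")

    # Union-find; the canonical member is the first listed in its class, and
    # for merged classes the canonical of the earlier class wins.
    parent: Dict[str, str] = {n: n for n in declared}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for cls in constraints.equalities:
        if len(cls) < 2:
            continue
        head = find(cls[0])
        for other in cls[1:]:
            parent[find(other)] = head

    # Resolve fixed values per class, detecting contradictions.
    class_value: Dict[str, float] = {}
    for source in (model.fixed, constraints.fixings):
        for n, v in source.items():
            root = find(n)
            v = float(v)
            if root in class_value and abs(class_value[root] - v) > 1e-12:
                raise ValueError(
                    f"contradictory constraints: class of {root!r} fixed to both "
                    f"{class_value[root]} and {v}"
                )
            class_value[root] = v

    new_params = tuple(p for p in model.parameters if find(p.name) == p.name)
    new_fixed = dict(class_value)
    new_trees = tuple(
        Tree(
            name=t.name,
            categories=t.categories,
            branches=tuple(
                Branch(tuple((find(n), c) for n, c in br.factors), br.category)
                for br in t.branches
            ),
            condition=t.condition,
        )
        for t in model.trees
    )
    return MPTModel(
        name=model.name if constraints.is_empty() else f"{model.name}+constraints",
        parameters=new_params,
        trees=new_trees,
        conditions=model.conditions,
        fixed=new_fixed,
    )


def category_probabilities(model: MPTModel, theta: Mapping[str, float]) -> Dict[str, np.ndarray]:
    """Per-tree category probability vectors under a full assignment."""
    comp = model.compiled()
    p = comp.category_probs(model.theta_vector(theta))
    return {lbl: p[sl] for lbl, sl in zip(comp.tree_labels, comp.tree_slices)}


def count_df(model: MPTModel) -> int:
    """Goodness-of-fit degrees of freedom.

    Free category probabilities (categories minus one, per tree, summed over
    all trees and conditions) minus free parameters.  A negative value
    signals an over-parameterised model.
    """
    free_probs = sum(len(t.categories) - 1 for t in model.trees)
    return free_probs - model.n_free_parameters


@dataclass(frozen=True)
class IdentifiabilityReport:
    rank: int
    n_free_parameters: int
    n_probes: int
    identified: bool


def check_identifiability(model: MPTModel, n_probes: int = 5, seed: Optional[int] = None) -> IdentifiabilityReport:
    """Numerical local identifiability via the Jacobian rank at interior points."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    comp = model.compiled()
    rng = np.random.default_rng(seed)
    # Rank is evaluated per probe point (local identifiability); the generic
    # rank is the maximum over random interior points.
    rank = 0
    for _ in range(n_probes):
        theta = rng.uniform(0.15, 0.85, size=len(comp.param_names))
        jac = comp.dp_dtheta(theta)
        rank = max(rank, int(np.linalg.matrix_rank(jac, tol=1e-8)))
    n_free = model.n_free_parameters
    return IdentifiabilityReport(rank=rank, n_free_parameters=n_free, n_probes=n_probes, identified=rank >= n_free)


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

_2HTSM_BASE_ROLES = {
    "D_left": "item-memory",
    "D_right": "item-memory",
    "D_new": "item-memory",
    "d_left": "source-memory",
    "d_right": "source-memory",
    "a": "guessing",
    "b": "guessing",
    "g": "guessing",
}

_2HTSM_MAPS = {
    "general": {},
    "4": {"D_left": "D", "D_right": "D", "D_new": "D", "d_left": "d", "d_right": "d", "a": "g"},
    "5a": {"D_left": "D", "D_right": "D", "D_new": "D", "d_left": "d", "d_right": "d"},
    "5d": {"D_left": "D", "D_right": "D", "D_new": "D", "a": "g"},
}

# (base factors, category) per item-type tree of the general 2HTSM
_2HTSM_TREES = {
    "target-left": [
        ((("D_left", False), ("d_left", False)), "old-left"),
        ((("D_left", False), ("d_left", True), ("a", False)), "old-left"),
        ((("D_left", False), ("d_left", True), ("a", True)), "old-right"),
        ((("D_left", True), ("b", False), ("g", False)), "old-left"),
        ((("D_left", True), ("b", False), ("g", True)), "old-right"),
        ((("D_left", True), ("b", True)), "new"),
    ],
    "target-right": [
        ((("D_right", False), ("d_right", False)), "old-right"),
        ((("D_right", False), ("d_right", True), ("a", False)), "old-left"),
        ((("D_right", False), ("d_right", True), ("a", True)), "old-right"),
        ((("D_right", True), ("b", False), ("g", False)), "old-left"),
        ((("D_right", True), ("b", False), ("g", True)), "old-right"),
        ((("D_right", True), ("b", True)), "new"),
    ],
    "distractor": [
        ((("D_new", False),), "new"),
        ((("D_new", True), ("b", False), ("g", False)), "old-left"),
        ((("D_new", True), ("b", False), ("g", True)), "old-right"),
        ((("D_new", True), ("b", True)), "new"),
    ],
}


def _suffixer(conditions: Sequence[str]):
    multi = len(conditions) > 1

    def suffix(base: str, cond: str) -> str:
        return condition_parameter(base, cond) if multi else base

    return suffix


def build_2htsm(submodel: str = "5a", conditions: Sequence[str] = ("wake", "sleep")) -> MPTModel:
    """The two-high-threshold source-monitoring model or one of its submodels.

    ``submodel``:

    * ``"general"`` — per-condition parameters ``D_left, D_right, D_new,
      d_left, d_right, a, b, g``;
    * ``"4"`` — single ``D``, single ``d``, source guessing equated
      (``a = g``): parameters ``D, d, b, g``;
    * ``"5a"`` — like 4 but with separate source guessing for recognized
      items: ``D, d, a, b, g``;
    * ``"5d"`` — like 4 but with source memory split by source instead:
      ``D, d_left, d_right, b, g``.
    """
    submodel = str(submodel)
    if submodel not in _2HTSM_MAPS:
        raise ValueError(f"unknown 2HTSM submodel {submodel!r}; expected one of {sorted(_2HTSM_MAPS)}")
    mapping = _2HTSM_MAPS[submodel]
    conditions = tuple(conditions)
    suffix = _suffixer(conditions)

    params: List[Parameter] = []
    seen = set()
    trees: List[Tree] = []
    for cond in conditions:
        for base in _2HTSM_BASE_ROLES:
            mapped = mapping.get(base, base)
            full = suffix(mapped, cond)
            if full not in seen:
                seen.add(full)
                params.append(Parameter(full, _2HTSM_BASE_ROLES[base]))
        for item, branches in _2HTSM_TREES.items():
            trees.append(
                Tree(
                    name=item,
                    categories=EXP1_CATEGORIES,
                    branches=tuple(
                        Branch(tuple((suffix(mapping.get(n, n), cond), c) for n, c in factors), cat)
                        for factors, cat in branches
                    ),
                    condition=cond,
                )
            )
    return MPTModel(
        name=f"2htsm-{submodel}",
        parameters=tuple(params),
        trees=tuple(trees),
        conditions=conditions,
    )


_MDSM_ROLES = {
    "D": "item-memory",
    "d": "bound-source-memory",
    "e_pos": "unbound-source-memory",
    "e_col": "unbound-source-memory",
    "a_pos": "guessing",
    "a_col_left": "guessing",
    "a_col_right": "guessing",
    "b": "guessing",
    "g_pos": "guessing",
    "g_col_left": "guessing",
    "g_col_right": "guessing",
}


def _mdsm_target_branches(pos: str, col: str) -> List[Tuple[Tuple[Tuple[str, bool], ...], str]]:
    """Branches of one target tree of the multidimensional model.

    A recognized item (``D``) either retrieves the bound source combination
    (``d``) or falls back on the two dimensions independently: position via
    memory ``e_pos`` or guess ``a_pos``, colour via memory ``e_col`` or a
    guess conditional on the *assigned* position (``a_col_left``/
    ``a_col_right``), whether that position came from memory or guessing.
    Unrecognized items are guessed "old" with ``b`` and sourced via the
    ``g``-stage mirror of the same position→colour cascade.
    """
    other_pos = "right" if pos == "left" else "left"
    other_col = "yellow" if col == "blue" else "blue"

    def cat(p: str, c: str) -> str:
        return f"old-{p}-{c}"

    def col_stage(assigned: str, via: str) -> List[Tuple[Tuple[Tuple[str, bool], ...], str]]:
        # colour sub-branches given the assigned position; via in {"a", "g"}
        guess = f"{via}_col_{assigned}"
        rows = []
        if via == "a":  # recognized: colour memory may still succeed
            rows.append(((("e_col", False),), cat(assigned, col)))
            tail: Tuple[Tuple[str, bool], ...] = (("e_col", True),)
        else:
            tail = ()
        rows.append((tail + ((guess, False),), cat(assigned, "blue")))
        rows.append((tail + ((guess, True),), cat(assigned, "yellow")))
        return rows

    branches: List[Tuple[Tuple[Tuple[str, bool], ...], str]] = []
    rec: Tuple[Tuple[str, bool], ...] = (("D", False),)
    branches.append((rec + (("d", False),), cat(pos, col)))
    unbound = rec + (("d", True),)
    # position retrieved from memory
    branches.append((unbound + (("e_pos", False), ("e_col", False)), cat(pos, col)))
    branches.append((unbound + (("e_pos", False), ("e_col", True), (f"a_col_{pos}", False)), cat(pos, "blue")))
    branches.append((unbound + (("e_pos", False), ("e_col", True), (f"a_col_{pos}", True)), cat(pos, "yellow")))
    # position guessed
    for assigned, a_factor in (("left", ("a_pos", False)), ("right", ("a_pos", True))):
        head = unbound + (("e_pos", True), a_factor)
        for tail, category in col_stage(assigned, "a"):
            branches.append((head + tail, category))
    # unrecognized, guessed old
    old_guess = (("D", True), ("b", False))
    for assigned, g_factor in (("left", ("g_pos", False)), ("right", ("g_pos", True))):
        head = old_guess + (g_factor,)
        for tail, category in col_stage(assigned, "g"):
            branches.append((head + tail, category))
    branches.append(((("D", True), ("b", True)), "new"))
    _ = other_pos, other_col  # naming clarity only
    return branches


_MDSM_DISTRACTOR = [
    ((("D", False),), "new"),
    ((("D", True), ("b", False), ("g_pos", False), ("g_col_left", False)), "old-left-blue"),
    ((("D", True), ("b", False), ("g_pos", False), ("g_col_left", True)), "old-left-yellow"),
    ((("D", True), ("b", False), ("g_pos", True), ("g_col_right", False)), "old-right-blue"),
    ((("D", True), ("b", False), ("g_pos", True), ("g_col_right", True)), "old-right-yellow"),
    ((("D", True), ("b", True)), "new"),
]

_MDSM_CONSTRAINED_MAP = {
    "a_pos": "g_pos",
    "a_col_left": "g_col_left",
    "a_col_right": "g_col_right",
}


def build_mdsm(constrained_guessing: bool = True, conditions: Sequence[str] = ("wake", "sleep")) -> MPTModel:
    """The multidimensional source-monitoring model (position × colour).

    Item memory is equated across source combinations and with distractor
    detection (single ``D``); bound source memory is a single ``d``; unbound
    source memories are ``e_pos`` and ``e_col``.  With
    ``constrained_guessing`` the three recognized-item source-guessing
    parameters are equated with their unrecognized-item counterparts
    (``a_pos = g_pos`` etc.), giving 8 free parameters per condition;
    the relaxed variant keeps them separate (11 per condition).
    """
    mapping = _MDSM_CONSTRAINED_MAP if constrained_guessing else {}
    conditions = tuple(conditions)
    suffix = _suffixer(conditions)

    params: List[Parameter] = []
    seen = set()
    trees: List[Tree] = []
    for cond in conditions:
        for base, role in _MDSM_ROLES.items():
            mapped = mapping.get(base, base)
            full = suffix(mapped, cond)
            if full not in seen:
                seen.add(full)
                params.append(Parameter(full, _MDSM_ROLES[mapped]))
        for pos in ("left", "right"):
            for col in ("blue", "yellow"):
                branches = _mdsm_target_branches(pos, col)
                trees.append(
                    Tree(
                        name=f"target-{pos}-{col}",
                        categories=EXP2_CATEGORIES,
                        branches=tuple(
                            Branch(tuple((suffix(mapping.get(n, n), cond), c) for n, c in factors), cat)
                            for factors, cat in branches
                        ),
                        condition=cond,
                    )
                )
        trees.append(
            Tree(
                name="distractor",
                categories=EXP2_CATEGORIES,
                branches=tuple(
                    Branch(tuple((suffix(mapping.get(n, n), cond), c) for n, c in factors), cat)
                    for factors, cat in _MDSM_DISTRACTOR
                ),
                condition=cond,
            )
        )
    return MPTModel(
        name="mdsm-constrained" if constrained_guessing else "mdsm-relaxed",
        parameters=tuple(params),
        trees=tuple(trees),
        conditions=conditions,
    )


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

_COMPLEMENT_RE = re.compile(r"^\(1-(.+)\)$")


def _parse_branch(text: str) -> Branch:
    lhs, _, category = text.partition("->")
    category = category.strip()
    lhs = lhs.strip()
    if lhs == "1":
        return Branch((), category)
    factors: List[Tuple[str, bool]] = []
    for term in lhs.split("*"):
        term = term.strip()
        m = _COMPLEMENT_RE.match(term)
        if m:
            factors.append((m.group(1).strip(), True))
        else:
            factors.append((term, False))
    return Branch(tuple(factors), category)


def model_to_yaml(model: MPTModel) -> str:
    """Serialize a model as a human-editable plain-text config."""
    doc = {
        "name": model.name,
        "conditions": list(model.conditions),
        "parameters": [{"name": p.name, "role": p.role} for p in model.parameters],
        "fixed": {k: float(v) for k, v in sorted(model.fixed.items())},
        "trees": [
            {
                "name": t.name,
                "condition": t.condition,
                "categories": list(t.categories),
                "branches": [b.format() for b in t.branches],
            }
            for t in model.trees
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> MPTModel:
    doc = yaml.safe_load(text)
    return MPTModel(
        name=doc["name"],
        parameters=tuple(Parameter(p["name"], p.get("role", "guessing")) for p in doc["parameters"]),
        trees=tuple(
            Tree(
                name=t["name"],
                categories=tuple(t["categories"]),
                branches=tuple(_parse_branch(b) for b in t["branches"]),
                condition=t.get("condition"),
            )
            for t in doc["trees"]
        ),
        conditions=tuple(doc.get("conditions", ())),
        fixed={k: float(v) for k, v in (doc.get("fixed") or {}).items()},
    )
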