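"""Context-dependent eye-motion units and decision-tree state tying.

A motion in a continuous sequence is modelled either context-free
("mono", unit name ``t``), conditioned on its predecessor ("bi",
``p-t``), or on both neighbours ("tri", ``p-t+s``), mirroring the
mono/bi/triphone hierarchy of speech recognition.  Sequence boundaries
yield one-sided units: the first motion of a tri-expanded sequence
carries only its right context (``t+s``), the last only its left
(``p-t``).  Because the input protocol forbids adjacent repeats, a
context never equals its target.

Tri-unit inventories grow with the cube of the motion count, so states
are tied with a likelihood-driven binary decision tree per (target
motion, state position): all context variants start pooled at the root
and are greedily split by the question whose answer partition maximises
the gain in an approximate single-Gaussian log-likelihood, until the
best gain falls below a threshold.  Unseen context combinations are
routed through the same trees, so any valid unit can be synthesised at
decode time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .gmm_hmm import GmmHmm, StateGmm, Accumulator
from .synthetic_eog import MOTIONS, SIL, MotionSequence

__all__ = [
    "ContextUnit",
    "Question",
    "expand_units",
    "unit_names",
    "count_state_inventory",
    "default_questions",
    "state_stats_from_accumulator",
    "tie_states",
    "TyingTree",
    "TiedModelSet",
    "resolve_unit",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ContextUnit:
    """A modelling unit ``left-target+right`` with optional contexts."""

    target: str
    left: Optional[str] = None
    right: Optional[str] = None

    def __post_init__(self):
        if self.left == self.target or self.right == self.target:
            raise ValueError("context equal to target violates the no-repeat rule")

    @property
    def kind(self) -> str:
        if self.left is None and self.right is None:
            return "mono"
        if self.left is not None and self.right is not None:
            return "tri"
        return "bi"

    @property
    def name(self) -> str:
        s = self.target
        if self.left is not None:
            s = f"{self.left}-{s}"
        if self.right is not None:
            s = f"{s}+{self.right}"
        return s

    @classmethod
    def from_name(cls, name: str) -> "ContextUnit":
        left = right = None
        rest = name
        if "-" in rest:
            left, rest = rest.split("-", 1)
        if "+" in rest:
            rest, right = rest.split("+", 1)
        return cls(target=rest, left=left, right=right)


def expand_units(seq: MotionSequence | Sequence[str], kind: str) -> list[ContextUnit]:
    """Expand a motion sequence into mono, bi or tri units.

    Bi: the first unit is context-free, later units carry their left
    context.  Tri: interior units carry both contexts; the first only
    its right, the last only its left.
    """
    motions = list(seq)
    if not motions:
        raise ValueError("empty motion sequence")
    if kind == "mono":
        return [ContextUnit(m) for m in motions]
    if kind == "bi":
        return [
            ContextUnit(m, left=motions[i - 1] if i > 0 else None)
            for i, m in enumerate(motions)
        ]
    if kind == "tri":
        n = len(motions)
        return [
            ContextUnit(
                m,
                left=motions[i - 1] if i > 0 else None,
                right=motions[i + 1] if i < n - 1 else None,
            )
            for i, m in enumerate(motions)
        ]
    raise ValueError(f"unknown unit kind {kind!r}")


def unit_names(seq, kind: str) -> list[str]:
    return [u.name for u in expand_units(seq, kind)]


def count_state_inventory(
    n_motions: int, states_per_model: int, *, motions: Optional[Sequence] = None
) -> int:
    """Untied context-dependent state count by explicit unit enumeration.

    Counts every tri unit (left and right context each differing from
    the target) plus the one-sided left-bi and right-bi boundary units,
    and multiplies by the states per model.  For five motions and four
    states this gives 4 x (4*5*4 + 4*5 + 5*4) = 480.
    """
    if n_motions < 2:
        raise ValueError("need at least two motions")
    if motions is None:
        motions = list(range(n_motions))
    motions = list(motions)[:n_motions]
    n_models = 0
    for t in motions:
        for p in motions:
            if p == t:
                continue
            n_models += 1  # left-bi  p-t
            n_models += 1  # right-bi t+p
            for s in motions:
                if s != t:
                    n_models += 1  # tri p-t+s
    return states_per_model * n_models


# ---------------------------------------------------------------------------
# Decision-tree state tying


@dataclass(frozen=True)
class Question:
    """A yes/no context question: is the left/right context in ``motions``?

    An absent context answers "no" to every question, which routes the
    one-sided boundary units through the same trees.
    """

    name: str
    side: str  # "left" or "right"
    motions: frozenset

    def answer(self, unit: ContextUnit) -> bool:
        ctx = unit.left if self.side == "left" else unit.right
        return ctx is not None and ctx in self.motions


def default_questions(motions: Sequence[str] = MOTIONS) -> list[Question]:
    """Identity questions per motion plus axis-group questions, each side."""
    qs: list[Question] = []
    groups: list[tuple[str, frozenset]] = [
        (f"is_{m}", frozenset([m])) for m in motions
    ]
    horizontal = frozenset(m for m in motions if m in ("left", "right"))
    vertical = frozenset(m for m in motions if m in ("up", "down"))
    if horizontal:
        groups.append(("is_horizontal", horizontal))
    if vertical:
        groups.append(("is_vertical", vertical))
    for side in ("left", "right"):
        for gname, gset in groups:
            qs.append(Question(f"{side}:{gname}", side, gset))
    return qs


def state_stats_from_accumulator(
    models: dict[str, GmmHmm], acc: Accumulator
) -> dict[str, list[tuple[float, np.ndarray, np.ndarray]]]:
    """Pooled per-(unit, state) (occupancy, sum x, sum x^2) statistics."""
    out: dict[str, list] = {}
    for name, m in models.items():
        rows = []
        for g in m.states:
            stats = acc.state_stats.get(id(g))
            if stats is None:
                rows.append((0.0, np.zeros(m.dim), np.zeros(m.dim)))
            else:
                rows.append(stats.pooled())
        out[name] = rows
    return out


def _set_loglik(occ: float, sx: np.ndarray, sxx: np.ndarray,
                var_floor: np.ndarray) -> float:
    """Log-likelihood of pooled frames under their own single Gaussian."""
    if occ <= 1e-6:
        return 0.0
    mean = sx / occ
    var = np.maximum(sxx / occ - mean**2, var_floor)
    return float(-0.5 * occ * np.sum(np.log(2.0 * np.pi * var) + 1.0))


class _Node:
    __slots__ = ("question", "yes", "no", "leaf_id", "members")

    def __init__(self, members):
        self.question = None
        self.yes = None
        self.no = None
        self.leaf_id = None
        self.members = members  # list of unit names (seen units only)

    @property
    def is_leaf(self) -> bool:
        return self.question is None


class TyingTree:
    """The per-(target motion, state position) question trees."""

    def __init__(self, trees: dict[tuple[str, int], _Node], n_tied: int):
        self.trees = trees
        self.n_tied = n_tied

    def resolve(self, unit: ContextUnit | str, state_pos: int) -> int:
        """Tied-state id for any (possibly unseen) context variant."""
        if isinstance(unit, str):
            unit = ContextUnit.from_name(unit)
        node = self.trees[(unit.target, state_pos)]
        while not node.is_leaf:
            node = node.yes if node.question.answer(unit) else node.no
        return node.leaf_id

    def dump(self) -> str:
        """Indented text rendering of all trees."""
        lines = []
        for (target, pos), root in sorted(self.trees.items()):
            lines.append(f"tree {target} state {pos}")

            def rec(node, indent):
                pad = "  " * indent
                if node.is_leaf:
                    lines.append(f"{pad}leaf {node.leaf_id} "
                                 f"[{', '.join(sorted(node.members))}]")
                else:
                    lines.append(f"{pad}{node.question.name}?")
                    lines.append(f"{pad}yes:")
                    rec(node.yes, indent + 1)
                    lines.append(f"{pad}no:")
                    rec(node.no, indent + 1)

            rec(root, 1)
        return "\n".join(lines)


class TiedModelSet:
    """Tied tri-unit models: shared physical states behind logical units.

    ``model_for`` synthesises (and caches) the model of any valid unit,
    including context combinations unseen in training, by routing each
    state position through the tying trees.  Units whose target has no
    tree (e.g. the boundary silence) fall back to the untied extra set.
    """

    def __init__(
        self,
        tree: TyingTree,
        leaf_states: dict[int, StateGmm],
        trans: dict[str, np.ndarray],
        extra: dict[str, GmmHmm],
        n_states: int,
    ):
        self.tree = tree
        self.leaf_states = leaf_states
        self.trans = trans
        self.extra = dict(extra)
        self.n_states = n_states
        self._cache: dict[str, GmmHmm] = dict(extra)

    def model_for(self, name_or_unit) -> GmmHmm:
        name = name_or_unit if isinstance(name_or_unit, str) else name_or_unit.name
        cached = self._cache.get(name)
        if cached is not None:
            return cached
        unit = ContextUnit.from_name(name)
        if (unit.target, 0) not in self.tree.trees:
            raise KeyError(f"unresolvable unit {name!r}")
        states = [
            self.leaf_states[self.tree.resolve(unit, pos)]
            for pos in range(self.n_states)
        ]
        model = GmmHmm(name, states, self.trans[unit.target])
        self._cache[name] = model
        return model

    def models_dict(self, names: Iterable[str]) -> dict[str, GmmHmm]:
        return {n: self.model_for(n) for n in names}

    def all_cached(self) -> dict[str, GmmHmm]:
        return dict(self._cache)


def tie_states(
    models: dict[str, GmmHmm],
    stats: dict[str, list[tuple[float, np.ndarray, np.ndarray]]],
    questions: Optional[list[Question]] = None,
    threshold: float = 0.0,
    *,
    var_floor: Optional[np.ndarray] = None,
    min_occupancy: float = 0.0,
) -> tuple[TyingTree, TiedModelSet]:
    """Greedy decision-tree tying of context-dependent unit states.

    ``models`` are the (typically single-Gaussian) trained tri models;
    ``stats`` their per-state pooled occupancy statistics.  Splitting of
    a leaf is accepted while the best question's likelihood gain is at
    least ``threshold``; sides with occupancy below ``min_occupancy``
    are not created.  Units without contexts in their name but matching
    a tree target are tied as well; units with untied targets (silence)
    are carried over unchanged.
    """
    questions = default_questions() if questions is None else questions
    dim = next(iter(models.values())).dim
    n_states = next(iter(models.values())).n_states
    if var_floor is None:
        pooled_sxx = np.zeros(dim)
        pooled_sx = np.zeros(dim)
        pooled_occ = 0.0
        for rows in stats.values():
            for occ, sx, sxx in rows:
                pooled_occ += occ
                pooled_sx += sx
                pooled_sxx += sxx
        if pooled_occ > 0:
            gmean = pooled_sx / pooled_occ
            gvar = np.maximum(pooled_sxx / pooled_occ - gmean**2, 1e-12)
        else:
            gvar = np.ones(dim)
        var_floor = np.maximum(1e-4 * gvar, 1e-12)

    targets = sorted({ContextUnit.from_name(n).target for n in models if n != SIL})
    by_target: dict[str, list[str]] = {t: [] for t in targets}
    extra: dict[str, GmmHmm] = {}
    for name in models:
        if name == SIL:
            extra[name] = models[name]
            continue
        by_target[ContextUnit.from_name(name).target].append(name)

    trees: dict[tuple[str, int], _Node] = {}
    leaf_states: dict[int, StateGmm] = {}
    next_leaf = 0

    def node_stat(members, pos):
        occ = 0.0
        sx = np.zeros(dim)
        sxx = np.zeros(dim)
        for name in members:
            o, x, xx = stats[name][pos]
            occ += o
            sx += x
            sxx += xx
        return occ, sx, sxx

    for target in targets:
        members_all = by_target[target]
        units = {name: ContextUnit.from_name(name) for name in members_all}
        for pos in range(n_states):
            root = _Node(list(members_all))
            leaves = [root]
            while True:
                best = None  # (gain, leaf, question, yes_members, no_members)
                for leaf in leaves:
                    if len(leaf.members) < 2:
                        continue
                    occ_p, sx_p, sxx_p = node_stat(leaf.members, pos)
                    ll_parent = _set_loglik(occ_p, sx_p, sxx_p, var_floor)
                    for q in questions:
                        yes = [n for n in leaf.members if q.answer(units[n])]
                        if not yes or len(yes) == len(leaf.members):
                            continue
                        no = [n for n in leaf.members if n not in set(yes)]
                        occ_y, sx_y, sxx_y = node_stat(yes, pos)
                        occ_n = occ_p - occ_y
                        if occ_y < min_occupancy or occ_n < min_occupancy:
                            continue
                        gain = (
                            _set_loglik(occ_y, sx_y, sxx_y, var_floor)
                            + _set_loglik(occ_n, sx_p - sx_y, sxx_p - sxx_y, var_floor)
                            - ll_parent
                        )
                        if best is None or gain > best[0]:
                            best = (gain, leaf, q, yes, no)
                if best is None or best[0] < threshold:
                    break
                _, leaf, q, yes, no = best
                leaf.question = q
                leaf.yes = _Node(yes)
                leaf.no = _Node(no)
                leaves.remove(leaf)
                leaves.extend([leaf.yes, leaf.no])
            for leaf in leaves:
                leaf.leaf_id = next_leaf
                occ, sx, sxx = node_stat(leaf.members, pos)
                if occ > 1e-6:
                    mean = sx / occ
                    var = np.maximum(sxx / occ - mean**2, var_floor)
                else:  # no data reached this leaf; borrow the models' params
                    g0 = models[leaf.members[0]].states[pos] if leaf.members else None
                    mean = g0.means[0].copy() if g0 is not None else np.zeros(dim)
                    var = g0.variances[0].copy() if g0 is not None else np.ones(dim)
                leaf_states[next_leaf] = StateGmm.single(mean, var)
                next_leaf += 1
            trees[(target, pos)] = root

    # shared transition matrix per target: occupancy-weighted member average
    trans: dict[str, np.ndarray] = {}
    for target in targets:
        members = by_target[target]
        weights = np.array([sum(stats[n][pos][0] for pos in range(n_states))
                            for n in members])
        if weights.sum() <= 0:
            weights = np.ones(len(members))
        probs = np.zeros_like(models[members[0]].log_trans)
        for w, n in zip(weights, members):
            probs += w * np.exp(models[n].log_trans)
        probs /= weights.sum()
        rows = probs.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            trans[target] = np.where(probs > 0, np.log(probs / rows), -np.inf)

    tree = TyingTree(trees, n_tied=next_leaf)
    tied = TiedModelSet(tree, leaf_states, trans, extra, n_states)
    # materialise tied variants of all seen units so training can proceed
    for name in models:
        if name != SIL:
            tied.model_for(name)
    return tree, tied


def resolve_unit(models, name: str) -> GmmHmm:
    """Look up a unit model with context back-off.

    Accepts a plain dict or a :class:`TiedModelSet`.  When the exact
    unit is unavailable, the right context is dropped first, then the
    left, ending at the context-free target model.
    """
    if isinstance(models, TiedModelSet):
        try:
            return models.model_for(name)
        except KeyError:
            if name in models.extra:
                return models.extra[name]
            raise
    unit = ContextUnit.from_name(name) if name != SIL else None
    candidates = [name]
    if unit is not None:
        candidates += [
            ContextUnit(unit.target, left=unit.left).name,
            ContextUnit(unit.target, right=unit.right).name,
            unit.target,
        ]
    for cand in candidates:
        if cand in models:
            return models[cand]
    raise KeyError(f"unresolvable unit {name!r}")
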