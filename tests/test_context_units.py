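import itertools

import numpy as np
import pytest

from eogdeco.context_units import (
    ContextUnit,
    Question,
    count_state_inventory,
    default_questions,
    expand_units,
    resolve_unit,
    tie_states,
    unit_names,
)
from eogdeco.gmm_hmm import GmmHmm


class TestExpandUnits:
    def test_bi_expansion_worked_example(self):
        assert unit_names(["up", "down", "up", "center"], "bi") == [
            "up", "up-down", "down-up", "up-center"]

    def test_tri_expansion_worked_example(self):
        assert unit_names(["up", "down", "up", "center"], "tri") == [
            "up+down", "up-down+up", "down-up+center", "up-center"]

    def test_mono_expansion(self):
        assert unit_names(["up", "down"], "mono") == ["up", "down"]

    def test_singleton_tri_has_no_contexts(self):
        assert unit_names(["left"], "tri") == ["left"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            expand_units([], "tri")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unit kind"):
            expand_units(["up"], "quad")

    def test_name_parse_roundtrip(self):
        for name in ("up", "up-down", "down+left", "up-down+center"):
            assert ContextUnit.from_name(name).name == name

    def test_context_equal_to_target_rejected(self):
        with pytest.raises(ValueError):
            ContextUnit("up", left="up")


class TestStateInventory:
    def test_paper_scale_inventory(self):
        assert count_state_inventory(5, 4) == 480

    def test_small_case_equals_direct_enumeration(self):
        # brute force over explicit unit tuples for 2 motions
        motions = ["a", "b"]
        tri = [(p, t, s) for p, t, s in itertools.product(motions, repeat=3)
               if p != t and s != t]
        left_bi = [(p, t) for p, t in itertools.product(motions, repeat=2) if p != t]
        right_bi = list(left_bi)
        assert count_state_inventory(2, 1) == len(tri) + len(left_bi) + len(right_bi)
        assert count_state_inventory(2, 1) == 6

    def test_zero_states_per_model(self):
        assert count_state_inventory(5, 0) == 0

    def test_too_few_motions_rejected(self):
        with pytest.raises(ValueError):
            count_state_inventory(1, 4)


def _stats_for(units, means, occ=100.0, var=1.0, dim=1, n_states=1):
    """Hand-built single-state sufficient statistics per unit."""
    stats = {}
    for u, mu in zip(units, means):
        mu = np.full(dim, mu, dtype=float)
        stats[u] = [(occ, occ * mu, occ * (var + mu**2))] * n_states
    return stats


def _models_for(units, dim=1, n_states=1):
    out = {}
    for u in units:
        out[u] = GmmHmm.left_to_right(u, n_states, np.zeros(dim), np.ones(dim))
    return out


class TestTieStates:
    units3 = ["up-center", "down-center", "left-center"]

    def test_infinite_threshold_fully_ties(self):
        models = _models_for(self.units3, n_states=2)
        stats = _stats_for(self.units3, [0.0, 1.0, 5.0], n_states=2)
        tree, tied = tie_states(models, stats, threshold=np.inf)
        # one leaf per state position
        assert tree.n_tied == 2

    def test_zero_threshold_fully_splits_distinct_data(self):
        models = _models_for(self.units3)
        stats = _stats_for(self.units3, [0.0, 5.0, 10.0])
        tree, tied = tie_states(models, stats, threshold=0.0)
        leaves = {tree.resolve(u, 0) for u in self.units3}
        assert len(leaves) == 3

    def test_greedy_first_split_matches_exhaustive_search(self):
        """On hand-built 3-context statistics the first question chosen
        equals the best question under exhaustive gain evaluation."""
        units = ["up-center", "down-center", "left-center"]
        means = [0.0, 0.2, 8.0]  # left-context "left" is the outlier
        models = _models_for(units)
        stats = _stats_for(units, means)
        questions = default_questions()
        var_floor = np.array([1e-8])

        # independent exhaustive evaluation of every question's gain
        from eogdeco.context_units import _set_loglik

        def pooled(us):
            occ = sum(stats[u][0][0] for u in us)
            sx = sum(stats[u][0][1] for u in us)
            sxx = sum(stats[u][0][2] for u in us)
            return occ, sx, sxx

        best_q, best_gain = None, -np.inf
        parent = _set_loglik(*pooled(units), var_floor)
        for q in questions:
            yes = [u for u in units if q.answer(ContextUnit.from_name(u))]
            if not yes or len(yes) == len(units):
                continue
            no = [u for u in units if u not in yes]
            gain = (_set_loglik(*pooled(yes), var_floor)
                    + _set_loglik(*pooled(no), var_floor) - parent)
            if gain > best_gain:
                best_gain, best_q = gain, q

        tree, _ = tie_states(models, stats, questions, threshold=best_gain / 2,
                             var_floor=var_floor)
        root = tree.trees[("center", 0)]
        assert not root.is_leaf
        # the chosen split must isolate the same partition as the best one
        chosen_yes = set(root.yes.members)
        expect_yes = {u for u in units
                      if best_q.answer(ContextUnit.from_name(u))}
        assert chosen_yes in (expect_yes, set(units) - expect_yes)

    def test_tied_count_non_increasing_in_threshold(self):
        units = [f"{p}-center" for p in ("up", "down", "left", "right")]
        models = _models_for(units, n_states=2)
        stats = _stats_for(units, [0.0, 1.0, 3.0, 9.0], n_states=2)
        counts = [tie_states(models, stats, threshold=t)[0].n_tied
                  for t in (0.0, 50.0, 500.0, np.inf)]
        assert counts == sorted(counts, reverse=True)

    def test_unseen_unit_resolves_to_exactly_one_leaf(self):
        units = ["up-center", "down-center"]
        models = _models_for(units, n_states=4)
        stats = _stats_for(units, [0.0, 4.0], n_states=4)
        tree, tied = tie_states(models, stats, threshold=0.0)
        unseen = ContextUnit("center", left="up", right="left")
        model = tied.model_for(unseen.name)
        assert model.n_states == 4
        for pos in range(4):
            leaf = tree.resolve(unseen, pos)
            assert tied.leaf_states[leaf] is model.states[pos]
        # cached: same object on second lookup
        assert tied.model_for(unseen.name) is model

    def test_accepted_split_gains_meet_threshold(self):
        units = [f"{p}-center" for p in ("up", "down", "left", "right")]
        models = _models_for(units)
        stats = _stats_for(units, [0.0, 1.0, 3.0, 9.0])
        thr = 100.0
        tree, _ = tie_states(models, stats, threshold=thr)

        from eogdeco.context_units import _set_loglik

        def node_ll(members):
            occ = sum(stats[u][0][0] for u in members)
            sx = sum(stats[u][0][1] for u in members)
            sxx = sum(stats[u][0][2] for u in members)
            return _set_loglik(occ, sx, sxx, np.array([1e-12]))

        def walk(node):
            if node.is_leaf:
                return
            gain = (node_ll(node.yes.members) + node_ll(node.no.members)
                    - node_ll(node.members))
            assert gain >= thr - 1e-6
            walk(node.yes)
            walk(node.no)

        walk(tree.trees[("center", 0)])

    def test_tree_dump_is_text(self):
        models = _models_for(self.units3)
        stats = _stats_for(self.units3, [0.0, 1.0, 9.0])
        tree, _ = tie_states(models, stats, threshold=10.0)
        text = tree.dump()
        assert "tree center state 0" in text and "leaf" in text


class TestResolveUnit:
    def test_backoff_chain(self):
        models = {"center": GmmHmm.left_to_right("center", 2, np.zeros(1), np.ones(1))}
        m = resolve_unit(models, "up-center+down")
        assert m is models["center"]
        with pytest.raises(KeyError, match="unresolvable"):
            resolve_unit({}, "up-center+down")


class TestQuestions:
    def test_default_question_set_structure(self):
        qs = default_questions()
        # 5 identity + 2 axis groups per side
        assert len(qs) == 14
        sides = {q.side for q in qs}
        assert sides == {"left", "right"}

    def test_absent_context_answers_no(self):
        q = Question("left:is_up", "left", frozenset(["up"]))
        assert not q.answer(ContextUnit("center", right="up"))
        assert q.answer(ContextUnit("center", left="up"))
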