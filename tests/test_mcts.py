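import math

import numpy as np
import pytest

from rxntree.grammar import apply_template
from rxntree.mcts import (
    MCTSConfig,
    SearchNode,
    SyntheticRoute,
    backpropagate,
    extract_route,
    random_search_baseline,
    ucb_score,
)


def make_child(parent, mol="C", rank=0, t_idx=0, reward=0.0):
    child = SearchNode(mol, parent=parent, template_index=t_idx, beam_rank=rank, reward=reward)
    parent.children.append(child)
    return child


class TestUCB:
    def test_symmetry_for_equal_stats(self):
        p = SearchNode("C")
        p.visits = 10
        a, b = make_child(p), make_child(p)
        for c in (a, b):
            c.visits, c.value_sum = 4, 2.0
        assert ucb_score(a, p, 0.7) == ucb_score(b, p, 0.7)

    def test_unvisited_child_is_infinite(self):
        p = SearchNode("C")
        p.visits = 3
        assert ucb_score(make_child(p), p, 1.0) == math.inf

    def test_hand_evaluated_formula(self):
        p = SearchNode("C")
        p.visits = 10
        c = make_child(p)
        c.visits, c.value_sum = 2, 1.0  # Q = 0.5
        cp = 1 / math.sqrt(2)
        want = 0.5 + 2 * cp * math.sqrt(math.log(10) / 2)
        assert ucb_score(c, p, cp) == pytest.approx(want, abs=1e-12)

    def test_agrees_with_scalar_recomputation_on_random_instances(self, rng):
        for _ in range(100):
            p = SearchNode("C")
            p.visits = int(rng.integers(1, 1000))
            c = make_child(p)
            c.visits = int(rng.integers(1, 100))
            c.value_sum = float(rng.random() * c.visits)
            cp = float(rng.random() * 2)
            want = c.value_sum / c.visits + 2 * cp * math.sqrt(math.log(p.visits) / c.visits)
            assert ucb_score(c, p, cp) == pytest.approx(want, rel=1e-12)

    def test_invalid_counts_raise(self):
        p = SearchNode("C")
        with pytest.raises(ValueError):
            ucb_score(make_child(p), p, 1.0)  # parent never visited


class TestBackpropagation:
    def test_depth_two_updates_three_nodes(self):
        root = SearchNode("C")
        mid = make_child(root, "CC")
        leaf = make_child(mid, "CCC")
        backpropagate(leaf, 0.8)
        assert (root.visits, mid.visits, leaf.visits) == (1, 1, 1)
        assert root.value_sum == mid.value_sum == leaf.value_sum == 0.8

    def test_root_q_is_mean_of_propagated_values(self):
        root = SearchNode("C")
        leaf = make_child(root, "CC")
        backpropagate(leaf, 0.2)
        backpropagate(leaf, 0.6)
        assert root.q == pytest.approx(0.4)

    def test_q_matches_logged_update_mean(self, rng):
        root = SearchNode("C")
        a = make_child(root, "CC")
        b = make_child(root, "CO")
        log = {id(a): [], id(b): [], id(root): []}
        for _ in range(200):
            leaf = a if rng.random() < 0.5 else b
            v = float(rng.random())
            backpropagate(leaf, v)
            log[id(leaf)].append(v)
            log[id(root)].append(v)
        for node in (root, a, b):
            if node.visits:
                assert node.q == pytest.approx(np.mean(log[id(node)]))


class TestSelectionPolicy:
    def run_bandit(self, c_p, rewards, iters=300):
        """Frozen-reward bandit: selection + backprop only."""
        root = SearchNode("C")
        root.expanded = True
        children = [make_child(root, f"C{i}", rank=i, reward=r) for i, r in enumerate(rewards)]
        backpropagate(root, 0.0)  # root visited once so ln N is defined
        for _ in range(iters):
            best = min(children, key=lambda c: (-ucb_score(c, root, c_p), c.beam_rank))
            backpropagate(best, best.reward)
        return children

    def test_infinite_exploration_visits_uniformly(self):
        children = self.run_bandit(c_p=1e9, rewards=[0.9, 0.1, 0.5])
        visits = [c.visits for c in children]
        assert max(visits) - min(visits) <= 1

    def test_zero_exploration_exploits_best_child(self):
        children = self.run_bandit(c_p=0.0, rewards=[0.2, 0.9, 0.4])
        visits = [c.visits for c in children]
        # after every arm's forced first visit, all pulls go to the best arm
        assert visits[1] >= 0.95 * sum(visits)

    def test_select_descends_to_unvisited_child_first(self, search_system):
        mcts = search_system.mcts
        root = SearchNode(search_system.start)
        root.expanded = True
        backpropagate(root, 0.5)
        seen = make_child(root, "CC", rank=1)
        seen.visits = 1
        unseen = make_child(root, "CO", rank=0)
        assert mcts.select(root) is unseen

    def test_select_fresh_tree_returns_root(self, search_system):
        root = SearchNode(search_system.start)
        assert search_system.mcts.select(root) is root

    def test_hand_built_tree_matches_bruteforce_argmax_path(self, search_system):
        mcts = search_system.mcts
        mcts.config.c_p = 1 / math.sqrt(2)
        root = SearchNode("C")
        root.expanded = True
        root.visits = 20
        stats = [(5, 2.0), (8, 6.0), (7, 1.0)]
        for i, (n, w) in enumerate(stats):
            c = make_child(root, f"C{i}", rank=i)
            c.visits, c.value_sum = n, w
            c.expanded = c.terminal = True  # leaves
        scores = [ucb_score(c, root, mcts.config.c_p) for c in root.children]
        assert mcts.select(root) is root.children[int(np.argmax(scores))]


class TestRoutes:
    def test_root_route_is_empty(self):
        root = SearchNode("CCO")
        assert len(extract_route(root)) == 0

    def test_depth_three_route_has_three_steps(self):
        root = SearchNode("C")
        n = root
        for i in range(3):
            n = make_child(n, "C" * (i + 2), t_idx=i)
        route = extract_route(n)
        assert len(route) == 3 == n.depth
        assert route.molecules()[0] == "C"
        assert [t for _, t in route.steps] == [0, 1, 2]


class TestRunSearch:
    def test_invalid_start_rejected(self, search_system):
        with pytest.raises(ValueError):
            search_system.mcts.run_search("x(x")

    def test_zero_iterations_root_only(self, search_system):
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=0, seed=0)
        )
        assert len(res.generated) == 1
        assert res.generated.smiles() == [search_system.start]

    def test_root_visits_equal_iterations(self, search_system):
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=25, beam_width=3, seed=1)
        )
        assert res.root.visits == 25

    def test_node_visits_equal_backprops_through_them(self, search_system):
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=30, beam_width=3, seed=2)
        )

        def check(node):
            if node.children:
                assert node.visits >= sum(c.visits for c in node.children)
            for c in node.children:
                check(c)

        check(res.root)

    def test_same_seed_identical_results(self, search_system):
        cfg = MCTSConfig(iterations=20, beam_width=3, seed=5)
        a = search_system.mcts.run_search(search_system.start, cfg)
        b = search_system.mcts.run_search(search_system.start, cfg)
        assert a.generated.smiles() == b.generated.smiles()
        assert [e.reward for e in a.generated] == [e.reward for e in b.generated]
        assert a.root.visits == b.root.visits

    def test_rewards_in_range_and_molecules_canonical(self, search_system):
        from rxntree.chem import canonical_smiles

        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=20, beam_width=3, seed=3)
        )
        for e in res.generated:
            assert 0.0 <= e.reward <= 1.0
            assert e.smiles == canonical_smiles(e.smiles)

    def test_expansion_children_reachable_by_grammar(self, search_system):
        """At beam width 1 every child of the root is the oracle product of its
        recorded template."""
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=10, beam_width=1, seed=4)
        )
        for child in res.root.children:
            oracle = apply_template(search_system.start,
                                    search_system.templates[child.template_index])
            assert child.molecule == oracle

    def test_simulation_candidate_budget(self, search_system):
        """The rollout schedule (5 templates x 1 molecule x 2 steps) takes its
        max over at most 25 candidates."""
        mcts = search_system.mcts
        mcts.run_search(search_system.start, MCTSConfig(iterations=15, beam_width=3, seed=6))
        assert mcts.config.sim_templates == 5
        assert mcts.config.sim_depth == 2
        assert mcts.config.sim_per_template == 1
        rng = np.random.default_rng(0)
        node = SearchNode(search_system.start, reward=mcts.reward(search_system.start))
        value = mcts.simulate(node, rng)
        assert 0.0 <= value <= 1.0
        assert mcts.last_sim_candidates <= 25

    def test_simulation_dead_end_falls_back_to_node_reward(self, search_system):
        mcts = search_system.mcts
        dead = SearchNode("CC(C)C", reward=0.42)  # no template applies to isobutane
        rng = np.random.default_rng(0)
        assert mcts.simulate(dead, rng) == 0.42

    def test_routes_replay_through_grammar_oracle_at_width_one(self, search_system):
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=30, beam_width=1, seed=7)
        )
        for e in res.generated:
            cur = e.route.start
            for smi, t_idx in e.route.steps:
                assert apply_template(cur, search_system.templates[t_idx]) == smi
                cur = smi
            assert cur == e.smiles


class TestBaseline:
    def test_baseline_respects_budget_and_range(self, search_system):
        gen = random_search_baseline(search_system.mcts, search_system.start, 15, seed=0)
        assert len(gen) <= 16
        assert all(0 <= e.reward <= 1 for e in gen)
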