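import math

import numpy as np
import pytest

from oracles import recompute_tree_costs
from pathweaver.geometry import circular_difference
from pathweaver.kinematics import lrmsd, set_dihedral
from pathweaver.rigidity import analyze_conformation
from pathweaver.search import (
    NoEligibleAngles,
    SearchConfig,
    SearchTree,
    TreeNode,
    choose_parent,
    mc_accept,
    near_neighbors,
    node_cost,
    perturb,
    prune,
    rewire,
    run_search,
    select_node,
    should_recompute_rigidity,
)


def build_random_tree(start, goal, pairing, rng, n_nodes=60):
    """Tree of random single-torsion variants of `start`, all children of
    the root, with g/h fields filled in from real lRMSDs."""
    root = TreeNode(start, None, 0.0, lrmsd(start, goal, pairing), 0.0)
    tree = SearchTree(root, pairing)
    goal_ca = tree.centered_ca(goal)
    for _ in range(n_nodes - 1):
        res = int(rng.integers(1, start.n_residues - 1))
        kind = "phi" if rng.uniform() < 0.5 else "psi"
        cur = (start.dihedrals.phi if kind == "phi" else start.dihedrals.psi)[res]
        conf = set_dihedral(start, res, kind, cur + rng.uniform(-25, 25))
        centered = tree.centered_ca(conf)
        h = float(tree.lrmsd_to_nodes(centered, [TreeNode(goal, None, 0, 0, 0, centered_ca=goal_ca)])[0])
        to_start = float(tree.lrmsd_to_nodes(centered, [root])[0])
        node = TreeNode(conf, root, to_start, h, to_start, centered_ca=centered)
        tree.add(node)
    return tree


class TestSelectNode:
    def test_single_node_tree(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        root = TreeNode(start, None, 0.0, 1.0, 0.0)
        tree = SearchTree(root, pairing)
        assert select_node(tree, rng, SearchConfig()) is root

    def test_bias_fraction_of_draws_hits_k_best(self, hinge8_pair, rng):
        """With bias 1/3 toward the 20 best of 100 nodes, a draw lands in
        the 20 best with probability 1/3 + (2/3)(20/100) = 0.4667."""
        start, goal, pairing = hinge8_pair
        tree = build_random_tree(start, goal, pairing, rng, n_nodes=100)
        config = SearchConfig()
        by_h = sorted(tree.nodes, key=lambda n: (n.h, n.index))
        top20 = {id(n) for n in by_h[:20]}
        draws = 30_000
        hits = sum(id(select_node(tree, rng, config)) in top20 for _ in range(draws))
        expected = config.bias_fraction + (1 - config.bias_fraction) * 20 / 100
        assert hits / draws == pytest.approx(expected, abs=0.02)

    def test_small_pool_still_well_defined(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        tree = build_random_tree(start, goal, pairing, rng, n_nodes=5)
        for _ in range(50):
            assert select_node(tree, rng, SearchConfig()) in tree.nodes


class TestPerturb:
    def test_no_eligible_angles_when_identical_to_goal(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        node = TreeNode(goal, None, 0.0, 0.0, 0.0)
        with pytest.raises(NoEligibleAngles):
            perturb(node, None, goal, pairing, rng, SearchConfig())

    def test_rigidity_restricts_to_flexible_residues(self, two_domain, rng):
        start, goal, hinge, pairing = two_domain
        report = analyze_conformation(start, min_cluster_atoms=6)
        node = TreeNode(start, None, 0.0, lrmsd(start, goal, pairing), 0.0)
        config = SearchConfig()
        for _ in range(1000):
            conf = perturb(node, report, goal, pairing, rng, config)
            changed = [
                (i, kind)
                for i in range(start.n_residues)
                for kind, a, b in (
                    ("phi", conf.dihedrals.phi[i], start.dihedrals.phi[i]),
                    ("psi", conf.dihedrals.psi[i], start.dihedrals.psi[i]),
                )
                if np.isfinite(a) and np.isfinite(b) and abs(a - b) > 1e-9
            ]
            assert changed, "perturbation changed no torsion"
            assert all(i in report.flexible_residues for i, _ in changed)

    def test_without_rigidity_all_differing_angles_eligible(self, two_domain, rng):
        start, goal, hinge, pairing = two_domain
        node = TreeNode(start, None, 0.0, lrmsd(start, goal, pairing), 0.0)
        config = SearchConfig(perturb_max_angles=1)
        seen = set()
        for _ in range(3000):
            conf = perturb(node, None, goal, pairing, rng, config)
            for i in range(start.n_residues):
                for kind, a, b in (
                    ("phi", conf.dihedrals.phi[i], start.dihedrals.phi[i]),
                    ("psi", conf.dihedrals.psi[i], start.dihedrals.psi[i]),
                ):
                    if np.isfinite(a) and np.isfinite(b) and abs(a - b) > 1e-9:
                        seen.add((i, kind))
        expected = set()
        for si, gi in pairing.pairs:
            for kind in ("phi", "psi"):
                a = (start.dihedrals.phi if kind == "phi" else start.dihedrals.psi)[si]
                b = (goal.dihedrals.phi if kind == "phi" else goal.dihedrals.psi)[gi]
                if np.isfinite(a) and np.isfinite(b) and circular_difference(a, b) > 5.0:
                    expected.add((si, kind))
        assert seen == expected


class TestNearNeighbors:
    def test_radius_is_inclusive(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        tree = build_random_tree(start, goal, pairing, rng, n_nodes=40)
        conf = tree.nodes[7].conformation
        centered = tree.nodes[7].centered_ca
        d = tree.lrmsd_to_nodes(centered, tree.pool_nodes())
        result = near_neighbors(tree, conf, SearchConfig())
        expected = [n for n, di in zip(tree.pool_nodes(), d) if di <= 1.0]
        assert result == expected

    def test_fallback_to_single_nearest(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        root = TreeNode(start, None, 0.0, lrmsd(start, goal, pairing), 0.0)
        tree = SearchTree(root, pairing)
        far = set_dihedral(start, 4, "psi", 100.0)
        result = near_neighbors(tree, far, SearchConfig())
        assert result == [root]

    def test_matches_linear_scan_oracle(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        tree = build_random_tree(start, goal, pairing, rng, n_nodes=200)
        for probe in (3, 57, 140):
            conf = tree.nodes[probe].conformation
            result = {id(n) for n in near_neighbors(tree, conf, SearchConfig())}
            # brute force: pairwise lrmsd via the public function
            scan = {}
            for n in tree.pool_nodes():
                scan[id(n)] = lrmsd(conf, n.conformation, _identity_pairing(pairing))
            within = {k for k, v in scan.items() if v <= 1.0}
            expected = within or {min(scan, key=scan.get)}
            assert result == expected


def _identity_pairing(pairing):
    from pathweaver.structure import ResiduePairing

    return ResiduePairing(pairs=[(s, s) for s, _ in pairing.pairs])


class TestCostAndParent:
    def test_root_cost_is_initial_lrmsd(self, hinge8_pair):
        start, goal, pairing = hinge8_pair
        h0 = lrmsd(start, goal, pairing)
        root = TreeNode(start, None, 0.0, h0, 0.0)
        assert node_cost(root) == pytest.approx(h0)

    def test_chain_recurrence_hand_values(self):
        root = TreeNode(None, None, 0.0, 6.0, 0.0)
        a = TreeNode(None, root, 0.0 + 1.0, 5.5, 1.0)
        b = TreeNode(None, a, a.g + 1.8, 5.0, 1.8)
        assert b.g == pytest.approx(2.8)
        assert node_cost(b) == pytest.approx(7.8)
        # reparenting b to root: g = 0 + 1.8
        b.parent, b.g = root, root.g + b.lrmsd_to_start
        assert node_cost(b) == pytest.approx(6.8)

    def test_choose_parent_hand_case(self):
        config = SearchConfig()
        n1 = TreeNode(None, None, 2.0, 1.0, 0.0, index=1)   # cost via n1: 2.0 + 0.8 + 5.0
        n2 = TreeNode(None, None, 1.1, 1.0, 0.0, index=2)   # cost via n2: 1.1 + 0.8 + 5.0
        n3 = TreeNode(None, None, 3.3, 1.0, 0.0, index=3)
        chosen = choose_parent([n1, n2, n3], conf_h=5.0, conf_lrmsd_to_start=0.8,
                               lrmsd_to_neighbors=np.array([0.5, 0.9, 0.2]), config=config)
        assert chosen is n2

    def test_choose_parent_tie_broken_by_proximity(self):
        config = SearchConfig()
        n1 = TreeNode(None, None, 1.0, 1.0, 0.0, index=1)
        n2 = TreeNode(None, None, 1.0, 1.0, 0.0, index=2)
        chosen = choose_parent([n1, n2], conf_h=5.0, conf_lrmsd_to_start=0.8,
                               lrmsd_to_neighbors=np.array([0.9, 0.3]), config=config)
        assert chosen is n2


class TestRewire:
    def test_no_improvement_leaves_tree(self):
        config = SearchConfig()
        root = TreeNode(None, None, 0.0, 5.0, 0.0, index=0)
        a = TreeNode(None, root, 1.0, 4.0, 1.0, index=1)
        root.children.append(a)
        new = TreeNode(None, root, 3.0, 3.0, 3.0, index=2)
        root.children.append(new)
        count = rewire(None, new, [a], np.array([0.4]), config)
        assert count == 0
        assert a.parent is root

    def test_shortcut_triangle_reparents(self):
        config = SearchConfig()
        root = TreeNode(None, None, 0.0, 5.0, 0.0, index=0)
        detour = TreeNode(None, root, 4.0, 4.5, 4.0, index=1)
        root.children.append(detour)
        far = TreeNode(None, detour, 4.0 + 2.0, 4.0, 2.0, index=2)
        detour.children.append(far)
        new = TreeNode(None, root, 1.0, 3.0, 1.0, index=3)
        root.children.append(new)
        old_cost = node_cost(far)
        count = rewire(None, new, [far], np.array([0.5]), config)
        assert count == 1
        assert far.parent is new
        assert far.g == pytest.approx(new.g + far.lrmsd_to_start)
        assert node_cost(far) < old_cost

    def test_subtree_costs_updated(self):
        config = SearchConfig()
        root = TreeNode(None, None, 0.0, 5.0, 0.0, index=0)
        detour = TreeNode(None, root, 2.0, 4.5, 2.0, index=1)
        root.children.append(detour)
        mid = TreeNode(None, detour, 2.0 + 3.0, 4.0, 3.0, index=2)
        detour.children.append(mid)
        leaf = TreeNode(None, mid, 5.0 + 2.5, 3.5, 2.5, index=3)
        mid.children.append(leaf)
        new = TreeNode(None, root, 0.5, 3.0, 0.5, index=4)
        root.children.append(new)
        rewire(None, new, [mid], np.array([0.2]), config)
        assert mid.g == pytest.approx(new.g + mid.lrmsd_to_start)
        assert leaf.g == pytest.approx(mid.g + leaf.lrmsd_to_start)

    def test_ancestors_never_reparented(self):
        config = SearchConfig()
        root = TreeNode(None, None, 0.0, 5.0, 0.0, index=0)
        new = TreeNode(None, root, 10.0, 3.0, 10.0, index=1)
        root.children.append(new)
        count = rewire(None, new, [root], np.array([0.1]), config)
        assert count == 0
        assert root.parent is None


class TestMcAccept:
    def test_improvement_always_accepted(self, rng):
        assert all(mc_accept(3.0, 4.0, 0.01, rng) for _ in range(100))

    def test_equal_scores_accepted(self, rng):
        assert all(mc_accept(4.0, 4.0, 0.01, rng) for _ in range(100))

    def test_empirical_rate_matches_boltzmann_bound(self, rng):
        lrmsd_new, lrmsd_parent, a = 10.1, 10.0, 0.01
        expected = math.exp(-(lrmsd_new - lrmsd_parent) / (lrmsd_new * a))
        trials = 100_000
        accepted = sum(mc_accept(lrmsd_new, lrmsd_parent, a, rng) for _ in range(trials))
        assert accepted / trials == pytest.approx(expected, abs=0.01)


class TestPrune:
    def test_redundant_pair_drops_farther_node(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        root = TreeNode(start, None, 0.0, 4.0, 0.0)
        tree = SearchTree(root, pairing)
        # a virtually identical conformation but farther from the goal
        twin = TreeNode(start, root, 0.0, 5.0, 0.0, centered_ca=root.centered_ca.copy())
        tree.add(twin)
        removed = prune(tree)
        assert removed == 1
        assert root.in_pool and not twin.in_pool
        assert twin.parent is root  # tree edge intact

    def test_matches_brute_force_pair_scan(self, hinge8_pair, rng):
        start, goal, pairing = hinge8_pair
        tree = build_random_tree(start, goal, pairing, rng, n_nodes=80)
        pool_before = tree.pool_nodes()
        # independent brute-force application of the 10% rule in h order
        expected_out = set()
        ordered = sorted(pool_before, key=lambda n: (n.h, n.index))
        for i, u in enumerate(ordered):
            if id(u) in expected_out:
                continue
            for v in ordered[i + 1:]:
                if id(v) in expected_out:
                    continue
                d = lrmsd(u.conformation, v.conformation, _identity_pairing(pairing))
                if d <= 0.10 * min(u.h, v.h):
                    expected_out.add(id(v))
        prune(tree)
        actually_out = {id(n) for n in pool_before if not n.in_pool}
        assert actually_out == expected_out

    def test_no_close_pairs_no_change(self, hinge8_pair):
        start, goal, pairing = hinge8_pair
        root = TreeNode(start, None, 0.0, 4.0, 0.0)
        tree = SearchTree(root, pairing)
        far = set_dihedral(start, 4, "psi", 60.0)
        node = TreeNode(far, root, 1.0, 3.0, 1.0)
        tree.add(node)
        assert prune(tree) == 0
        assert all(n.in_pool for n in tree.nodes)


class TestRigidityRecomputeTrigger:
    @pytest.mark.parametrize("delta,expected", [(2.1, True), (2.0, False), (1.9, False)])
    def test_strict_drift_threshold(self, hinge8_pair, delta, expected, monkeypatch):
        start, goal, pairing = hinge8_pair
        import pathweaver.search as search_mod

        monkeypatch.setattr(search_mod, "lrmsd", lambda *a, **k: delta)
        assert search_mod.should_recompute_rigidity(start, start, pairing, 2.0) is expected


class TestRunSearch:
    def test_identical_start_and_goal(self, helix12):
        res = run_search(helix12, helix12, SearchConfig(rng_seed=0))
        assert res.best_lrmsd == pytest.approx(0.0, abs=1e-12)
        assert res.iterations_used == 0
        assert len(res.path) == 1
        assert res.stop_reason == "goal_threshold"

    def test_hinge_fixture_converges_below_half_angstrom(self, hinge8_pair):
        start, goal, _ = hinge8_pair
        config = SearchConfig(
            rng_seed=2, goal_threshold=0.45, rigidity_mode="off", max_iterations=5000
        )
        res = run_search(start, goal, config)
        assert res.best_lrmsd < 0.5
        assert res.iterations_used < 5000

    def test_trace_is_non_increasing(self, hinge8_pair):
        start, goal, _ = hinge8_pair
        res = run_search(
            start, goal,
            SearchConfig(rng_seed=3, goal_threshold=0.45, rigidity_mode="off",
                         max_iterations=2000),
        )
        assert np.all(np.diff(res.lrmsd_trace) <= 1e-12)

    def test_deterministic_given_seed(self, hinge8_pair):
        start, goal, _ = hinge8_pair
        config = SearchConfig(rng_seed=11, goal_threshold=0.5, rigidity_mode="off",
                              max_iterations=800)
        r1 = run_search(start, goal, config)
        r2 = run_search(start, goal, config)
        assert r1.best_lrmsd == r2.best_lrmsd
        assert r1.iterations_used == r2.iterations_used
        assert r1.tree_size == r2.tree_size
        assert np.array_equal(r1.lrmsd_trace, r2.lrmsd_trace)

    def test_tree_structure_and_cost_consistency(self, hinge8_pair):
        start, goal, _ = hinge8_pair
        config = SearchConfig(rng_seed=5, goal_threshold=0.45, rigidity_mode="off",
                              max_iterations=1500)
        res = run_search(start, goal, config)
        nodes = res.tree.nodes
        # single root, no cycles, parents precede nothing circularly
        roots = [n for n in nodes if n.parent is None]
        assert roots == [nodes[0]]
        for n in nodes:
            seen = set()
            walker = n
            while walker is not None:
                assert id(walker) not in seen
                seen.add(id(walker))
                walker = walker.parent
        # Every stored g equals the recurrence recomputed along the chain
        expected_g = recompute_tree_costs(nodes, config.g_mode)
        for n in nodes:
            assert n.g == pytest.approx(expected_g[n.index], abs=1e-9)

    def test_path_is_parent_chain_from_start(self, hinge8_pair):
        start, goal, _ = hinge8_pair
        res = run_search(
            start, goal,
            SearchConfig(rng_seed=7, goal_threshold=0.45, rigidity_mode="off",
                         max_iterations=1500),
        )
        assert res.path[0] is start
        assert res.best_lrmsd == pytest.approx(
            lrmsd(res.path[-1], goal, res.tree.pairing), abs=1e-9
        )

    def test_flexible_override_restricts_perturbation(self, two_domain):
        start, goal, hinge, _ = two_domain
        override = frozenset(hinge)
        # minimisation off: torsion changes then come from perturbation only
        res = run_search(
            start, goal,
            SearchConfig(rng_seed=1, goal_threshold=1.2, max_iterations=1200,
                         minimize_steps=0),
            flexible_override=override,
        )
        # every non-root tree node must differ from start only at hinge torsions
        for node in res.tree.nodes[1:]:
            d = node.conformation.dihedrals
            for i in range(start.n_residues):
                if i in override:
                    continue
                for a, b in ((d.phi[i], start.dihedrals.phi[i]), (d.psi[i], start.dihedrals.psi[i])):
                    if np.isfinite(a) and np.isfinite(b):
                        assert abs(a - b) < 1e-9

    def test_edge_cost_mode_also_consistent(self, hinge8_pair):
        start, goal, _ = hinge8_pair
        config = SearchConfig(rng_seed=9, goal_threshold=0.5, rigidity_mode="off",
                              g_mode="edge", max_iterations=800)
        res = run_search(start, goal, config)
        expected_g = recompute_tree_costs(res.tree.nodes, "edge")
        for n in res.tree.nodes:
            assert n.g == pytest.approx(expected_g[n.index], abs=1e-9)
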