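"""V-shaped penalties, structural statistics, and the total cost."""

import random

import networkx as nx
import pytest

from netter import (
    DirectedLink,
    StructuralConfig,
    SubnetworkConfig,
    VShapePenalty,
    antidominating_y,
    build,
    default_config,
    identity_ranking,
    regulatory_y,
    total_cost,
    vshape,
    with_weights,
)
from netter.penalties import (
    load_config,
    save_config,
    structural_cost,
    subnetwork_penalty,
    total_cost_fresh,
)


def _digraph(edges):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


@pytest.mark.parametrize(
    "a, b, y, expected",
    [(1, -1, 1.0, 0.0), (1, -1, 0.25, 0.75), (-2, 1, 0.0, 1.0)],
)
def test_vshape(a, b, y, expected):
    p = VShapePenalty("p", "regulator_fraction", a=a, b=b, weight=1.0)
    assert vshape(p, y) == pytest.approx(expected)

def test_vshape_clamped_below_intercept():
    p = VShapePenalty(
        "anti", "max_outdegree_share", a=1.0, b=-0.1, weight=1.0,
        clamp_below_zero=True,
    )
    assert vshape(p, 0.05) == 0.0
    assert vshape(p, 0.3) == pytest.approx(0.2)


class TestStatistics:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([("A", "B"), ("A", "C"), ("B", "C")], 2 / 3),
            ([("A", "B"), ("A", "C"), ("A", "D")], 0.25),
            ([("A", "B"), ("B", "A"), ("B", "C"), ("C", "B"),
              ("A", "C"), ("C", "A")], 1.0),
        ],
    )
    def test_regulatory_fraction(self, edges, expected):
        assert regulatory_y(_digraph(edges)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")], 0.75),
            ([("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")], 0.25),
            ([("A", "B")], 1.0),
        ],
    )
    def test_antidominating_share(self, edges, expected):
        assert antidominating_y(_digraph(edges)) == pytest.approx(expected)

    def test_empty_graphs_are_zero(self):
        assert regulatory_y(nx.DiGraph()) == 0.0
        assert antidominating_y(nx.DiGraph()) == 0.0

    def test_cached_stats_agree_with_graph_functions(self, small_fixture):
        """Dual route: the stack's O(1) statistics vs direct graph evaluation."""
        _, _, r0 = small_fixture
        stack = build(r0, SubnetworkConfig(n=25, x=len(r0)))
        for sub, cut in zip(stack.subnets, stack.cfg.cut_points):
            g = nx.DiGraph()
            g.add_nodes_from(sub.incident)
            g.add_edges_from(r0.links[:cut])
            assert sub.n_regulators / sub.n_nodes == pytest.approx(regulatory_y(g))
            assert sub.max_out_degree / sub.n_links == pytest.approx(
                antidominating_y(g)
            )


class TestStructuralCost:
    def _stack(self, n_links=40, n=20):
        links = [DirectedLink(f"R{i % 4}", f"T{i}") for i in range(n_links)]
        return build(identity_ranking(links), SubnetworkConfig(n=n, x=n_links))

    def test_single_subnetwork_single_penalty(self):
        # one penalty (w=1, a=1, b=-1) with y=0.25 at pi_1=0.5 -> 0.375
        links = [DirectedLink(f"R{i}", f"T{i}") for i in range(40)]
        stack = build(identity_ranking(links), SubnetworkConfig(n=20, x=40))
        pen = VShapePenalty("p", "regulator_fraction", a=1.0, b=-1.0, weight=1.0)
        y = stack.subnets[0].n_regulators / stack.subnets[0].n_nodes  # 0.5
        cfg = StructuralConfig((pen,), alpha=0.0)
        assert structural_cost(stack, cfg) == pytest.approx(0.5 * (1 - y))

    def test_zero_weights_cost_nothing(self):
        stack = self._stack()
        cfg = with_weights(default_config(), graphlet=0, regulatory=0,
                           antidominating=0)
        assert structural_cost(stack, cfg) == 0.0

    def test_pi_coefficients_sum_over_identical_subnetworks(self):
        # two subnetworks with identical y: cost = (0.5 + 0.25) * per-subnet
        links = [DirectedLink(f"R{i}", f"T{i}") for i in range(60)]
        stack = build(identity_ranking(links), SubnetworkConfig(n=20, x=60))
        pen = VShapePenalty("p", "regulator_fraction", a=1.0, b=0.0, weight=2.0)
        cfg = StructuralConfig((pen,), alpha=0.0)
        per = subnetwork_penalty(stack.subnets[0], (pen,))
        assert per == subnetwork_penalty(stack.subnets[1], (pen,))
        assert structural_cost(stack, cfg) == pytest.approx(0.75 * per)

    def test_total_cost_is_structural_at_identity(self):
        stack = self._stack()
        cfg = default_config(alpha=3.0)
        assert stack.divergence == 0
        assert total_cost(stack, cfg) == structural_cost(stack, cfg)

    def test_alpha_zero_ignores_divergence(self, small_fixture):
        _, _, r0 = small_fixture
        stack = build(r0, SubnetworkConfig(n=25, x=len(r0)))
        stack.apply_move([(r0.links[0], 100)])
        cfg = default_config(alpha=0.0)
        assert total_cost(stack, cfg) == structural_cost(stack, cfg)

    def test_incremental_equals_fresh_after_moves(self, small_fixture):
        _, _, r0 = small_fixture
        rng = random.Random(0)
        cfg = default_config()
        stack = build(r0, SubnetworkConfig(n=25, x=len(r0)))
        for _ in range(50):
            move = [
                (stack.links[lid], rng.randint(1, len(r0)))
                for lid in rng.sample(range(len(r0)), 3)
            ]
            stack.apply_move(move)
            inc = total_cost(stack, cfg)
            fresh = total_cost_fresh(stack.current_ranking(), cfg, 25)
            assert inc == pytest.approx(fresh, abs=1e-9)


class TestConfigRules:
    def test_pi_strictly_decreasing(self):
        cfg = default_config()
        pis = [cfg.pi(i) for i in range(1, 6)]
        assert pis == sorted(pis, reverse=True)
        assert all(p > 0 for p in pis)

    def test_default_weights(self):
        weights = {p.name: p.weight for p in default_config().penalties}
        assert weights == {"graphlet": 25.0, "regulatory": 2.0,
                           "antidominating": 75.0}
        assert default_config().alpha == pytest.approx(1e-5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            VShapePenalty("p", "regulator_fraction", 1.0, 0.0, weight=-1.0)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            VShapePenalty("p", "nope", 1.0, 0.0, weight=1.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(alpha=1e-4, pi_base=0.4)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, {"n": 25, "x": 750}, path)
        loaded, extras = load_config(path)
        assert loaded == cfg
        assert extras == {"n": 25, "x": 750}
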