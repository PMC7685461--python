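"""Influence-diagram engine: enumeration, decisions, co-simulation."""

import itertools

import numpy as np
import pytest

from emt import models
from emt.influence import (
    ChanceNodeSpec,
    InCombination,
    InputNodeSpec,
    OutCombination,
    SimulatorSpec,
    SubmodelSpec,
    build_parameter_vector,
    decide,
    enumerate_conditioning_combinations,
    expected_metrics,
    simulate,
    time_grid,
)

IC = InCombination(2020.0, "none", "none", "none")


def make_group(actions, probs, gid="krr", extra_inputs=()):
    group, hyp = models.scenario_group(gid, actions, "ecosys", probs)
    if extra_inputs:
        group = SubmodelSpec(
            id=group.id, role="group", input_nodes=tuple(extra_inputs),
            nodes=group.nodes, menu=group.menu, value_node=group.value_node,
            choice_node=group.choice_node,
        )
    sim = SimulatorSpec(groups=(group,))
    return group, build_parameter_vector([group], {gid: hyp})


class TestEnumeration:
    @pytest.mark.parametrize(
        "domains, expected",
        [
            (((0, 1), (0, 1)), 4),
            ((("a", "b", "c"),), 3),
        ],
    )
    def test_counts(self, domains, expected):
        spec = SubmodelSpec(
            id="ecosys", role="ecosystem",
            input_nodes=tuple(
                InputNodeSpec(f"x{i}", "discrete", d) for i, d in enumerate(domains)
            ),
            nodes=(ChanceNodeSpec("U", "discrete", domain=(0, 1)),),
            output_metrics=("U",),
        )
        combos = enumerate_conditioning_combinations(spec)
        assert len(combos) == expected
        assert spec.n_conditioning_combinations() == expected

    def test_cheetah_like_group_matches_hand_enumeration(self):
        spec = models.mixed_input_group()  # input sizes (2, 3, 2), one-element menu
        combos = enumerate_conditioning_combinations(spec)
        # brute-force oracle over the declared domains, lexicographic order
        oracle = [
            {"input_action": a, "season": s, "pressure": p,
             "output_action": "act", "target": "ecosys"}
            for a, s, p in itertools.product(
                ("none", "poach"), ("dry", "wet", "mixed"), ("low", "high")
            )
        ]
        assert combos == oracle
        assert len(combos) == 12

    def test_continuous_input_without_discretization_errors(self):
        spec = SubmodelSpec(
            id="ecosys", role="ecosystem",
            input_nodes=(InputNodeSpec("z", "continuous"),),
            nodes=(ChanceNodeSpec("U", "discrete", domain=(0, 1)),),
            output_metrics=("U",),
        )
        with pytest.raises(ValueError, match="discretization"):
            enumerate_conditioning_combinations(spec)


class TestDecide:
    def test_single_element_menu(self):
        group, b = make_group(("only",), (1.0,))
        assert decide(group, IC, b, mc_reals=5, seed=0) == OutCombination("only", "ecosys")

    def test_deterministic_utilities_pick_the_larger(self):
        # payoff depends only on the chosen action: 0.2 vs 0.9
        group = SubmodelSpec(
            id="krr", role="group",
            nodes=(
                ChanceNodeSpec(
                    "oga", "deterministic", parents=("output_action",),
                    table= ((("low",), 0.2), (("high",), 0.9)),
                ),
            ),
            menu=(OutCombination("low", "ecosys"), OutCombination("high", "ecosys")),
            value_node="oga",
        )
        b = build_parameter_vector([group], {"krr": {"oga": None}})
        assert decide(group, IC, b, mc_reals=1, seed=0).output_action == "high"

    def test_matches_enumerated_expected_utilities(self):
        # E[OGA | action a] = P(scenario = a): exact by CPT enumeration
        probs = (0.25, 0.45, 0.30)
        group, b = make_group(("a", "b", "c"), probs)
        oracle_best = ("a", "b", "c")[int(np.argmax(probs))]
        assert decide(group, IC, b, mc_reals=100_000, seed=1).output_action == oracle_best

    def test_menu_permutation_invariance(self):
        probs = (0.25, 0.45, 0.30)
        group, b = make_group(("a", "b", "c"), probs)
        base = decide(group, IC, b, mc_reals=2000, seed=3)
        shuffled = (group.menu[2], group.menu[0], group.menu[1])
        assert decide(group, IC, b, mc_reals=2000, seed=3, menu=shuffled) == base

    def test_empty_menu_errors(self):
        group, b = make_group(("a",), (1.0,))
        with pytest.raises(ValueError, match="empty"):
            decide(group, IC, b, menu=(), mc_reals=1, seed=0)


class TestSimulate:
    def test_ecosystem_only_constant_dynamics(self, gaussian_submodel):
        eco, b = gaussian_submodel(5.0, sd=1e-9, rng=(0.0, 10.0))
        sim = SimulatorSpec(groups=(), ecosystem=eco)
        rec = simulate(sim, b, time_grid(2020.0, 2020.5), mc_reals=100, seed=0)
        assert np.allclose(rec.metric_means[:, 0], 5.0, atol=1e-6)

    def test_fixed_seed_is_bit_reproducible(self, one_group):
        sim, b = one_group
        grid = time_grid(2020.0, 2020.5)
        r1 = simulate(sim, b, grid, mc_reals=50, seed=9, decision_mc=1)
        r2 = simulate(sim, b, grid, mc_reals=50, seed=9, decision_mc=1)
        assert np.array_equal(r1.metric_means, r2.metric_means)
        assert r1.postings == r2.postings

    def test_metric_means_match_closed_form_recursion(self, one_group):
        # with near-certain poaching decisions the abundance mean follows
        # x_t = b0 + poach_effect + carry * x_{t-1} deterministically
        sim, b = one_group
        T = 10
        grid = time_grid(2020.0, 2030.0)[:T]
        rec = simulate(sim, b, grid, mc_reals=2000, seed=5, decision_mc=500)
        x = 100.0
        expected = []
        for _ in range(T):
            x = 12.0 - 8.0 + (0.9 - 0.05) * x
            expected.append(x)
        # per-step MC s.e. = scale/sqrt(mc); AR propagation < 1/(1-carry)
        tol = 3.0 * (1.0 / np.sqrt(2000)) / (1 - 0.85)
        assert np.allclose(rec.metric_means[:, 0], expected, atol=tol)

    def test_bad_time_grid_errors(self, one_group):
        sim, b = one_group
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate(sim, b, [2020.0, 2020.0], mc_reals=5, seed=0)

    def test_undeclared_route_errors(self, one_group):
        sim, _ = one_group
        with pytest.raises(ValueError, match="undeclared"):
            SimulatorSpec(groups=sim.groups, ecosystem=sim.ecosystem,
                          routes=(("krr", "ghost"),))


class TestExpectedMetrics:
    def test_query_order_and_shape(self, one_group):
        sim, b = one_group
        grid = time_grid(2020.0, 2020.5)
        q = [("cheetah", grid[3]), ("cheetah", grid[1])]
        out = expected_metrics(sim, b, q, grid, mc_reals=50, seed=0, decision_mc=20)
        assert out.shape == (2,)

    def test_unknown_metric_errors(self, one_group):
        sim, b = one_group
        grid = time_grid(2020.0, 2020.5)
        with pytest.raises(KeyError, match="lion"):
            expected_metrics(sim, b, [("lion", grid[0])], grid, mc_reals=5, seed=0)

    def test_deterministic_metric_is_exact(self, gaussian_submodel):
        eco, b = gaussian_submodel(7.0, sd=1e-9, rng=(0.0, 10.0))
        sim = SimulatorSpec(groups=(), ecosystem=eco)
        grid = time_grid(2020.0, 2020.2)
        out = expected_metrics(sim, b, [("U", grid[1])], grid, mc_reals=200, seed=0)
        assert out[0] == pytest.approx(7.0, abs=1e-6)


def test_two_node_diagram_mean_converges():
    # U1 ~ Bernoulli(b1) influencing U2 ~ Normal(b2 + u1 b3, b4):
    # E[U2] = b2 + b1 b3
    from emt.distance import submodel_draws

    b1, b2, b3, b4 = 0.3, 1.0, 2.0, 0.5
    sim, b = models.two_node_gaussian((b1, b2, b3, b4))
    draws = submodel_draws(sim.ecosystem, b, {}, 100_000, seed=12)
    se = np.sqrt(b4**2 + b3**2 * b1 * (1 - b1)) / np.sqrt(100_000)
    assert abs(draws["U2"].mean() - (b2 + b1 * b3)) < 4 * se
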