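"""Built-in toy simulators.

Small influence-diagram models exercising every statistical job at desk
scale: a two-node conditional-Gaussian diagram, a single political group
whose action choice is driven by a categorical scenario node, and one- and
two-group political-ecological simulators with a linear-Gaussian abundance
metric.  Group decision structure: a scenario node ``S`` over the action
labels, and an Overall Goal Attainment payoff of 1 when the chosen output
action matches the scenario and 0 otherwise — so the group's choice
distribution equals the scenario node's probability row, which makes
parameter recovery from observed action frequencies well-posed.
"""

from __future__ import annotations

import numpy as np

from .influence import (
    ChanceNodeSpec,
    EcoBinding,
    InputNodeSpec,
    OutCombination,
    SimulatorSpec,
    SubmodelSpec,
    build_parameter_vector,
)
from .parameters import ParameterVector


def two_node_gaussian(beta=(0.3, 1.0, 2.0, 0.5)) -> tuple:
    """The minimal two-node ID: U1 ~ Bernoulli(b1) influencing
    U2 ~ Normal(b2 + u1 b3, b4).  Returns (spec, B)."""
    b1, b2, b3, b4 = beta
    spec = SubmodelSpec(
        id="ecosys",
        role="ecosystem",
        nodes=(
            ChanceNodeSpec("U1", "discrete", domain=(0, 1)),
            ChanceNodeSpec("U2", "continuous", parents=("U1",),
                           range=(b2 - 6 * b4, b2 + b3 + 6 * b4)),
        ),
        output_metrics=("U2",),
    )
    hypothesis = {"ecosys": {
        "U1": (1.0 - b1, b1),
        "U2": {"b0": b2, "b": {"U1": b3}, "scale": b4},
    }}
    sim = SimulatorSpec(groups=(), ecosystem=spec)
    return sim, build_parameter_vector(sim.submodels, hypothesis)


def scenario_group(
    gid: str = "krr",
    actions=("poach", "farm", "protest"),
    target: str = "ecosys",
    probs=(0.6, 0.3, 0.1),
) -> tuple:
    """A group whose choice distribution over ``actions`` equals the CPT of
    its scenario node.  Returns (SubmodelSpec, hypothesis dict)."""
    table = tuple(
        ((a, s), 1.0 if a == s else 0.0)
        for a in actions
        for s in actions
    )
    spec = SubmodelSpec(
        id=gid,
        role="group",
        nodes=(
            ChanceNodeSpec("scenario", "discrete", domain=tuple(actions)),
            ChanceNodeSpec("oga", "deterministic",
                           parents=("output_action", "scenario"), table=table),
        ),
        menu=tuple(OutCombination(a, target) for a in actions),
        value_node="oga",
        choice_node="scenario",
    )
    return spec, {"scenario": tuple(probs), "oga": None}


def group_only_simulator(
    probs=(0.6, 0.3, 0.1),
    actions=("poach", "farm", "protest"),
    gid: str = "krr",
) -> tuple:
    """A single scenario-driven group with no ecosystem submodel — the
    standard test-bed for recovering choice probabilities from an observed
    actions history.  Returns (SimulatorSpec, B_H)."""
    group, group_hyp = scenario_group(gid, actions, "ecosys", probs)
    sim = SimulatorSpec(groups=(group,), ecosystem=None)
    return sim, build_parameter_vector(sim.submodels, {gid: group_hyp})


def one_group_simulator(
    probs=(0.6, 0.3, 0.1),
    actions=("poach", "farm", "protest"),
    r0: float = 0.05,
    poach_effect: float = -8.0,
    carry: float = 0.9,
    base: float = 12.0,
    scale: float = 1.0,
    init_abundance: float = 100.0,
) -> tuple:
    """One scenario-driven group plus a linear-Gaussian cheetah-abundance
    ecosystem:

        cheetah_t ~ Normal(base + (carry - r0) cheetah_{t-1}
                           + poach_effect * poaching_t, scale).

    Returns (SimulatorSpec, B_H ParameterVector).
    """
    group, group_hyp = scenario_group("krr", actions, "ecosys", probs)
    eco = SubmodelSpec(
        id="ecosys",
        role="ecosystem",
        input_nodes=(
            InputNodeSpec("poaching", "discrete", domain=(0, 1)),
            InputNodeSpec("prev_cheetah", "continuous",
                          discretization=(50.0, 100.0, 150.0)),
        ),
        nodes=(
            ChanceNodeSpec("cheetah", "continuous",
                           parents=("prev_cheetah", "poaching"),
                           range=(0.0, 300.0)),
        ),
        output_metrics=("cheetah",),
    )
    hypothesis = {
        "krr": group_hyp,
        "ecosys": {
            "cheetah": {
                "b0": base,
                "b": {"prev_cheetah": carry - r0, "poaching": poach_effect},
                "scale": scale,
            }
        },
    }
    sim = SimulatorSpec(
        groups=(group,),
        ecosystem=eco,
        eco_bindings=(
            EcoBinding("poaching", "action_count", "poach"),
            EcoBinding("prev_cheetah", "prev_metric", "cheetah"),
        ),
        metric_init=(("cheetah", init_abundance),),
    )
    return sim, build_parameter_vector(sim.submodels, hypothesis)


def two_group_simulator(
    kep_probs=(0.3, 0.7),
    krr_probs=(0.55, 0.35, 0.1),
    park_effect: float = 10.0,
    poach_effect: float = -12.0,
    carry: float = 0.85,
    base: float = 15.0,
    scale: float = 1.0,
    init_abundance: float = 80.0,
) -> tuple:
    """Two groups (an environmental protection agency that may create parks,
    and rural residents who may poach) sharing one abundance metric.
    Returns (SimulatorSpec, B_H)."""
    kep, kep_hyp = scenario_group("kep", ("create_park", "report"), "ecosys", kep_probs)
    krr, krr_hyp = scenario_group("krr", ("poach", "farm", "protest"), "ecosys", krr_probs)
    eco = SubmodelSpec(
        id="ecosys",
        role="ecosystem",
        input_nodes=(
            InputNodeSpec("poaching", "discrete", domain=(0, 1)),
            InputNodeSpec("parks", "discrete", domain=(0, 1)),
            InputNodeSpec("prev_cheetah", "continuous",
                          discretization=(40.0, 80.0, 160.0)),
        ),
        nodes=(
            ChanceNodeSpec("cheetah", "continuous",
                           parents=("prev_cheetah", "poaching", "parks"),
                           range=(0.0, 400.0)),
        ),
        output_metrics=("cheetah",),
    )
    hypothesis = {
        "kep": kep_hyp,
        "krr": krr_hyp,
        "ecosys": {
            "cheetah": {
                "b0": base,
                "b": {"prev_cheetah": carry, "poaching": poach_effect,
                      "parks": park_effect},
                "scale": scale,
            }
        },
    }
    sim = SimulatorSpec(
        groups=(kep, krr),
        ecosystem=eco,
        routes=(("kep", "krr"), ("krr", "kep")),
        eco_bindings=(
            EcoBinding("poaching", "action_count", "poach"),
            EcoBinding("parks", "action_count", "create_park"),
            EcoBinding("prev_cheetah", "prev_metric", "cheetah"),
        ),
        metric_init=(("cheetah", init_abundance),),
    )
    return sim, build_parameter_vector(sim.submodels, hypothesis)


def mixed_input_group() -> SubmodelSpec:
    """A group ID with input-node cardinalities (2, 3, 2) — twelve
    conditioning combinations before the decision nodes (used to exercise
    conditioning-combination enumeration)."""
    actions = ("act",)
    spec = SubmodelSpec(
        id="tep",
        role="group",
        input_nodes=(
            InputNodeSpec("input_action", "discrete", domain=("none", "poach")),
            InputNodeSpec("season", "discrete", domain=("dry", "wet", "mixed")),
            InputNodeSpec("pressure", "discrete", domain=("low", "high")),
        ),
        nodes=(
            ChanceNodeSpec("scenario", "discrete", domain=actions),
            ChanceNodeSpec("oga", "deterministic",
                           parents=("output_action", "scenario"),
                           table=((("act", "act"), 1.0),)),
        ),
        menu=(OutCombination("act", "ecosys"),),
        value_node="oga",
        choice_node="scenario",
    )
    return spec
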