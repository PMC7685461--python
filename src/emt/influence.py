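"""Minimal influence-diagram simulator framework.

Political-ecological simulators are built from small influence diagrams
(IDs): one ID per political group plus one ecosystem ID.  A group ID receives
an *in-combination* ``{time, input action, actor, subject}``, and selects the
*out-combination* ``{output action, target}`` from its finite menu that
maximizes the Monte-Carlo estimate of the expected value of its terminal
node, Overall Goal Attainment.  The ecosystem ID advances continuous metrics
(e.g. species abundances) each time step, driven by the actions the groups
post.

Only two stochastic node families are supported — categorical conditional
probability tables for discrete nodes and conditional Gaussians with mean
affine in the parent values for continuous nodes — which is the minimum
needed for every statistic computed downstream.  Deterministic nodes (payoff
tables) carry the utility arithmetic and contribute no parameters.

Randomness discipline: one base seed per job; every (time step, submodel)
pair draws from its own deterministic substream, so two simulations with the
same seed are bit-identical and objective evaluations at different trial
parameter points share common random numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .parameters import (
    ECO_BLOCK,
    GROUP_BLOCK,
    ParamKey,
    ParameterBuilder,
    ParameterVector,
)

NONE_VALUE = "none"
OUT_ACTION_NODE = "output_action"
TARGET_NODE = "target"


@dataclass(frozen=True)
class InCombination:
    """Values on a group ID's input nodes: {time, input action, actor, subject}."""

    time: float
    input_action: str
    actor: str
    subject: str


@dataclass(frozen=True, order=True)
class OutCombination:
    """A group's posted output: {output action, target (of that action)}."""

    output_action: str
    target: str


@dataclass(frozen=True)
class InputNodeSpec:
    """A conditioning (input) node of an ID.

    Continuous inputs (e.g. a lagged ecosystem metric) must declare a finite
    ``discretization`` before the ID's conditioning combinations can be
    enumerated.
    """

    name: str
    kind: str = "discrete"  # "discrete" | "continuous"
    domain: tuple = ()
    discretization: tuple = ()

    def enumeration_values(self) -> tuple:
        if self.kind == "discrete":
            return tuple(self.domain)
        if not self.discretization:
            raise ValueError(
                f"continuous input node {self.name!r} has no declared discretization"
            )
        return tuple(self.discretization)


@dataclass(frozen=True)
class ChanceNodeSpec:
    """A stochastic or deterministic node of an ID.

    discrete
        categorical CPT; one probability row per combination of discrete
        parent values, stored in the :class:`ParameterVector`.
    continuous
        conditional Gaussian: mean affine in the (numerically encoded)
        parent values, constant scale; ``range`` bounds the node for uniform
        design-point sampling.
    deterministic
        value given by a payoff ``table`` mapping parent-value combinations
        to reals; carries no parameters (used for terminal value nodes).
    """

    name: str
    kind: str  # "discrete" | "continuous" | "deterministic"
    parents: tuple = ()
    domain: tuple = ()
    range: tuple = ()
    table: tuple = ()  # ((parent values tuple, value), ...) for deterministic

    def table_dict(self) -> dict:
        return {tuple(k): float(v) for k, v in self.table}


@dataclass(frozen=True)
class SubmodelSpec:
    """One influence diagram: a political group or the ecosystem.

    Group submodels declare a finite ``menu`` of out-combinations, a terminal
    ``value_node`` (Overall Goal Attainment) and optionally a ``choice_node``
    — the categorical node whose conditional probability rows directly drive
    which action wins (used by the Initialize step of consistency analysis).
    The ecosystem submodel declares ``output_metrics`` naming its observable
    continuous nodes.
    """

    id: str
    role: str  # "group" | "ecosystem"
    input_nodes: tuple = ()
    nodes: tuple = ()
    menu: tuple = ()
    value_node: str = ""
    choice_node: str = ""
    output_metrics: tuple = ()

    def __post_init__(self):
        if self.role not in ("group", "ecosystem"):
            raise ValueError(f"unknown submodel role {self.role!r}")
        if self.role == "group":
            if not self.value_node:
                raise ValueError(f"group submodel {self.id!r} has no terminal value node")
            if not any(n.name == self.value_node for n in self.nodes):
                raise ValueError(
                    f"group submodel {self.id!r}: value node {self.value_node!r} not declared"
                )
        if self.role == "ecosystem" and len(self.output_metrics) < 1:
            raise ValueError(f"ecosystem submodel {self.id!r} declares no output metrics")
        self._validate_graph()

    # -- structure ---------------------------------------------------------
    def _validate_graph(self) -> None:
        known = {n.name for n in self.input_nodes}
        if self.role == "group":
            known |= {OUT_ACTION_NODE, TARGET_NODE}
        order = []
        placed = set()
        remaining = list(self.nodes)
        while remaining:
            progressed = False
            for node in list(remaining):
                if all(p in known or p in placed for p in node.parents):
                    order.append(node)
                    placed.add(node.name)
                    remaining.remove(node)
                    progressed = True
            if not progressed:
                raise ValueError(
                    f"submodel {self.id!r}: cyclic or dangling parent references among "
                    f"{[n.name for n in remaining]}"
                )
        object.__setattr__(self, "_topo_order", tuple(order))

    @property
    def topo_nodes(self) -> tuple:
        return self._topo_order

    def node(self, name: str) -> ChanceNodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"submodel {self.id!r} has no node {name!r}")

    def conditioning_nodes(self) -> tuple:
        """Input nodes of the ID, including (for groups) the decision nodes
        Out-Action and Target, whose values are also conditioning inputs."""
        nodes = list(self.input_nodes)
        if self.role == "group":
            actions = tuple(dict.fromkeys(m.output_action for m in self.menu))
            targets = tuple(dict.fromkeys(m.target for m in self.menu))
            nodes.append(InputNodeSpec(OUT_ACTION_NODE, "discrete", actions))
            nodes.append(InputNodeSpec(TARGET_NODE, "discrete", targets))
        return tuple(nodes)

    def pdpf_nodes(self) -> tuple:
        """The chance nodes over which the ID's joint PDPF is defined
        (stochastic nodes only; terminal value/payoff nodes are excluded)."""
        return tuple(n for n in self.topo_nodes if n.kind in ("discrete", "continuous"))

    def n_conditioning_combinations(self) -> int:
        out = 1
        for node in self.conditioning_nodes():
            out *= len(node.enumeration_values())
        return out

    # -- parameters --------------------------------------------------------
    def _parent_value_sets(self, node: ChanceNodeSpec) -> list:
        """Enumerable values of each parent of ``node`` (for CPT rows)."""
        sets = []
        inputs = {n.name: n for n in self.conditioning_nodes()}
        chance = {n.name: n for n in self.nodes}
        for p in node.parents:
            if p in inputs:
                sets.append((p, inputs[p].enumeration_values()))
            elif p in chance:
                parent = chance[p]
                if parent.kind != "discrete":
                    raise ValueError(
                        f"node {node.name!r}: non-discrete parent {p!r} cannot index a CPT"
                    )
                sets.append((p, tuple(parent.domain)))
            else:
                raise ValueError(f"node {node.name!r}: unknown parent {p!r}")
        return sets

    def cpt_contexts(self, node: ChanceNodeSpec) -> list:
        """All conditioning contexts (CPT rows) of a discrete node, in
        lexicographic order of the declared parent domains."""
        sets = self._parent_value_sets(node)
        names = [s[0] for s in sets]
        return [tuple(zip(names, combo)) for combo in itertools.product(*[s[1] for s in sets])]

    def add_parameters(self, builder: ParameterBuilder, hypothesis: dict) -> None:
        """Append this submodel's parameter slots (at their hypothesis
        values) to ``builder``.  ``hypothesis`` maps node names to their
        parameterization; see the builders in :mod:`emt.models`."""
        block = GROUP_BLOCK if self.role == "group" else ECO_BLOCK
        for node in self.topo_nodes:
            if node.kind == "discrete":
                spec = hypothesis[node.name]
                for context in self.cpt_contexts(node):
                    probs = _row_for_context(spec, context)
                    if len(probs) != len(node.domain):
                        raise ValueError(
                            f"CPT row for {node.name!r} context {context} has wrong length"
                        )
                    if abs(sum(probs) - 1.0) > 1e-9:
                        raise ValueError(
                            f"CPT row for {node.name!r} context {context} does not sum to 1"
                        )
                    builder.add_simplex_row(
                        [
                            (ParamKey(self.id, context, f"p({node.name}={v})"), p)
                            for v, p in zip(node.domain, probs)
                        ],
                        block,
                    )
            elif node.kind == "continuous":
                spec = hypothesis[node.name]
                builder.add(ParamKey(self.id, (), f"{node.name}.b0"), spec["b0"], block)
                for p in node.parents:
                    builder.add(
                        ParamKey(self.id, (), f"{node.name}.b[{p}]"), spec["b"][p], block
                    )
                scale = spec["scale"]
                if scale <= 0:
                    raise ValueError(f"node {node.name!r}: scale must be positive")
                builder.add(
                    ParamKey(self.id, (), f"{node.name}.scale"), scale, block,
                    bounds=(1e-9, np.inf),
                )


def _row_for_context(spec, context) -> tuple:
    """Resolve a CPT row from a hypothesis declaration.

    ``spec`` is either a flat probability sequence (no parents / shared row)
    or a mapping from parent-value tuples (or single values) to rows.
    """
    if isinstance(spec, dict):
        values = tuple(v for _, v in context)
        if values in spec:
            return tuple(spec[values])
        if len(values) == 1 and values[0] in spec:
            return tuple(spec[values[0]])
        raise KeyError(f"no CPT row declared for context {context}")
    return tuple(spec)


def build_parameter_vector(submodels, hypothesis: dict) -> ParameterVector:
    """Assemble the hypothesis parameter vector ``B_H`` of a simulator.

    ``hypothesis`` maps submodel id -> node name -> parameterization.
    """
    builder = ParameterBuilder()
    for sub in submodels:
        sub.add_parameters(builder, hypothesis[sub.id])
    return builder.build()


# ---------------------------------------------------------------------------
# Conditioning-combination enumeration
# ---------------------------------------------------------------------------

def enumerate_conditioning_combinations(spec: SubmodelSpec) -> list:
    """All combinations of the ID's input-node values, in lexicographic
    (declared-domain) order.  The count equals ``l_i``, the number of belief
    networks formed by conditioning the ID."""
    nodes = spec.conditioning_nodes()
    names = [n.name for n in nodes]
    values = [n.enumeration_values() for n in nodes]
    return [dict(zip(names, combo)) for combo in itertools.product(*values)]


# ---------------------------------------------------------------------------
# Forward sampling
# ---------------------------------------------------------------------------

def _value_as_float(node_like, value):
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    domain = tuple(getattr(node_like, "domain", ()) or getattr(node_like, "discretization", ()))
    if value in domain:
        return float(domain.index(value))
    raise ValueError(f"cannot encode value {value!r} of node {node_like!r} numerically")


def _float_array(node_like, values: np.ndarray) -> np.ndarray:
    if values.dtype.kind in "fi":
        return values.astype(float)
    domain = tuple(node_like.domain)
    lut = {v: float(i) for i, v in enumerate(domain)}
    return np.array([lut[v] for v in values], dtype=float)


def sample_nodes(
    spec: SubmodelSpec,
    B: ParameterVector,
    conditioning: dict,
    uniforms: np.ndarray,
) -> dict:
    """Sample every non-input node of ``spec`` once per row of ``uniforms``.

    ``uniforms`` has shape ``(n, len(spec.topo_nodes))``; column ``k`` feeds
    node ``k`` in topological order (deterministic nodes ignore theirs).
    Reusing the same ``uniforms`` across calls with different conditioning
    values yields common-random-number coupled samples.
    """
    n = uniforms.shape[0]
    values: dict = {}
    inputs = {k: v for k, v in conditioning.items()}
    cond_nodes = {nd.name: nd for nd in spec.conditioning_nodes()}

    def parent_column(name: str) -> np.ndarray:
        if name in values:
            return values[name]
        if name in inputs:
            return np.repeat(np.array([inputs[name]], dtype=object), n)
        raise ValueError(f"submodel {spec.id!r}: missing value for parent {name!r}")

    for k, node in enumerate(spec.topo_nodes):
        u = uniforms[:, k]
        if node.kind == "discrete":
            values[node.name] = _sample_discrete(spec, B, node, parent_column, inputs, u, n)
        elif node.kind == "continuous":
            mean = np.full(n, B.get(ParamKey(spec.id, (), f"{node.name}.b0")))
            for p in node.parents:
                coef = B.get(ParamKey(spec.id, (), f"{node.name}.b[{p}]"))
                col = parent_column(p)
                if col.dtype == object:
                    ref = values.get(p)
                    node_like = cond_nodes.get(p) or spec.node(p)
                    col = np.array([_value_as_float(node_like, v) for v in col])
                else:
                    col = col.astype(float)
                mean = mean + coef * col
            scale = B.get(ParamKey(spec.id, (), f"{node.name}.scale"))
            values[node.name] = mean + scale * ndtri(np.clip(u, 1e-12, 1 - 1e-12))
        else:  # deterministic payoff table
            table = node.table_dict()
            cols = [parent_column(p) for p in node.parents]
            out = np.empty(n, dtype=float)
            for i in range(n):
                key = tuple(c[i] for c in cols)
                out[i] = table[key]
            values[node.name] = out
    return values


def _sample_discrete(spec, B, node, parent_column, inputs, u, n):
    contexts = spec.cpt_contexts(node)
    domain = tuple(node.domain)
    if not node.parents:
        probs = np.array(
            [B.get(ParamKey(spec.id, (), f"p({node.name}={v})")) for v in domain]
        )
        idx = _categorical(probs, u)
        return np.array(domain, dtype=object)[idx]
    # group draws by realized parent-value combination
    cols = [parent_column(p) for p in node.parents]
    out = np.empty(n, dtype=object)
    combo_keys = np.array([tuple(c[i] for c in cols) for i in range(n)], dtype=object)
    rows = {}
    for context in contexts:
        key = tuple(v for _, v in context)
        rows[key] = np.array(
            [B.get(ParamKey(spec.id, context, f"p({node.name}={v})")) for v in domain]
        )
    for i in range(n):
        probs = rows[tuple(combo_keys[i])]
        out[i] = domain[int(_categorical(probs, np.array([u[i]]))[0])]
    return out


def _categorical(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    probs = np.clip(np.asarray(probs, dtype=float), 0.0, None)
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate probability row (all zero)")
    cdf = np.cumsum(probs / total)
    return np.searchsorted(cdf, u, side="right").clip(0, len(probs) - 1)


def _substream(seed, *path) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, path)]))


# ---------------------------------------------------------------------------
# Decision rule
# ---------------------------------------------------------------------------

def decide(
    group: SubmodelSpec,
    incoming: InCombination,
    B: ParameterVector,
    mc_reals: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    menu: tuple | None = None,
) -> OutCombination:
    """Select the out-combination maximizing the Monte-Carlo estimate of
    E[Overall Goal Attainment].

    Utility estimates across menu elements share one matrix of uniform
    draws (common random numbers).  Ties break lexicographically on
    ``(output_action, target)``.
    """
    if group.role != "group":
        raise ValueError(f"decide called on non-group submodel {group.id!r}")
    menu = tuple(menu if menu is not None else group.menu)
    if not menu:
        raise ValueError(f"group {group.id!r} has an empty out-combination menu")
    if mc_reals < 1:
        raise ValueError("mc_reals must be >= 1")
    rng = rng if rng is not None else _substream(seed, 0, 0)
    uniforms = rng.random((int(mc_reals), len(group.topo_nodes)))
    conditioning = _in_conditioning(group, incoming)
    best = None
    best_val = -np.inf
    for oc in sorted(menu):
        cond = dict(conditioning)
        cond[OUT_ACTION_NODE] = oc.output_action
        cond[TARGET_NODE] = oc.target
        vals = sample_nodes(group, B, cond, uniforms)
        util = float(np.mean(_float_array(group.node(group.value_node), vals[group.value_node])))
        if util > best_val:
            best, best_val = oc, util
    return best


def _in_conditioning(group: SubmodelSpec, incoming: InCombination) -> dict:
    """Map an in-combination onto the group's declared input nodes.

    Input nodes named after in-combination fields receive the field value if
    it lies in their domain, else the node's first domain value (a declared
    "none"-style fallback).  Other input nodes take their first domain value.
    """
    fields = {
        "time": incoming.time,
        "input_action": incoming.input_action,
        "actor": incoming.actor,
        "subject": incoming.subject,
    }
    cond = {}
    for node in group.input_nodes:
        if node.name in fields and node.kind == "discrete":
            v = fields[node.name]
            cond[node.name] = v if v in node.domain else node.domain[0]
        elif node.kind == "discrete":
            cond[node.name] = node.domain[0]
        else:
            cond[node.name] = fields.get(node.name, 0.0)
    return cond


# ---------------------------------------------------------------------------
# Co-simulation
# ---------------------------------------------------------------------------

DEFAULT_TIME_STEP = 13.0 / 365.25  # the 13-day step, in decimal years


@dataclass(frozen=True)
class EcoBinding:
    """How one ecosystem input node is driven during co-simulation.

    kind "action_count": the number of postings of ``ref`` (an action label)
    at the current step, snapped to the node's discrete domain.
    kind "prev_metric": the previous step's Monte-Carlo mean of metric
    ``ref`` (continuous input).
    """

    node: str
    kind: str  # "action_count" | "prev_metric"
    ref: str


@dataclass(frozen=True)
class SimulatorSpec:
    """Wiring of group submodels and the ecosystem submodel.

    ``routes`` is a tuple of ``(sender id, receiver id)`` pairs: a receiver's
    in-combination at step t is the most recent step-(t-1) posting of the
    first routed sender that posted.  ``eco_bindings`` drive the ecosystem's
    input nodes; ``metric_init`` gives time-zero metric values.
    """

    groups: tuple
    ecosystem: SubmodelSpec | None = None
    routes: tuple = ()
    eco_bindings: tuple = ()
    metric_init: tuple = ()  # ((metric, value), ...)

    def __post_init__(self):
        ids = {g.id for g in self.groups}
        if self.ecosystem is not None:
            ids.add(self.ecosystem.id)
        for s, r in self.routes:
            if s not in ids or r not in ids:
                raise ValueError(f"route ({s!r}, {r!r}) references an undeclared submodel")

    def group(self, gid: str) -> SubmodelSpec:
        for g in self.groups:
            if g.id == gid:
                return g
        raise KeyError(f"no group {gid!r}")

    @property
    def submodels(self) -> tuple:
        subs = tuple(self.groups)
        if self.ecosystem is not None:
            subs = subs + (self.ecosystem,)
        return subs

    def metric_names(self) -> tuple:
        return tuple(self.ecosystem.output_metrics) if self.ecosystem is not None else ()


@dataclass
class SimulationRecord:
    """Output of one simulator run."""

    times: np.ndarray
    postings: list  # per step: list of (group id, OutCombination)
    metric_names: tuple
    metric_means: np.ndarray  # shape (T, e)
    mc_reals: int
    seed: int

    def postings_frame(self):
        import pandas as pd

        rows = [
            (float(t), g, oc.output_action, oc.target)
            for t, step in zip(self.times, self.postings)
            for g, oc in step
        ]
        return pd.DataFrame(rows, columns=["time", "group", "action", "target"])


def simulate(
    spec: SimulatorSpec,
    B: ParameterVector,
    time_grid,
    mc_reals: int = 1000,
    seed: int = 0,
    decision_mc: int | None = None,
    forbidden: dict | None = None,
) -> SimulationRecord:
    """Time-stepped co-simulation of the group and ecosystem submodels.

    At each step every group receives its routed in-combination from the
    previous step's postings, decides (with ``decision_mc`` Monte-Carlo
    realizations; defaults to ``mc_reals``) and posts an out-combination;
    then the ecosystem submodel advances and the Monte-Carlo means of its
    output metrics are recorded.  ``forbidden`` optionally maps group ids to
    sets of excluded out-combinations (menu filtering used by sensitivity
    and policy runs).  Identical seeds give bit-identical records.
    """
    times = np.asarray(list(time_grid), dtype=float)
    if len(times) == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be nonempty and strictly increasing")
    decision_mc = int(decision_mc if decision_mc is not None else mc_reals)
    forbidden = forbidden or {}
    metric_names = spec.metric_names()
    metric_means = np.zeros((len(times), len(metric_names)))
    metric_state = dict(spec.metric_init)
    for m in metric_names:
        metric_state.setdefault(m, 0.0)
    postings_all: list = []
    prev_postings: list = []
    group_index = {g.id: k for k, g in enumerate(spec.groups)}

    for step, t in enumerate(times):
        step_postings = []
        for g in spec.groups:
            incoming = _route_incoming(spec, g.id, prev_postings, t)
            menu = tuple(m for m in g.menu if m not in set(forbidden.get(g.id, ())))
            if not menu:
                raise ValueError(f"group {g.id!r}: every menu element is forbidden")
            rng = _substream(seed, step, group_index[g.id])
            oc = decide(g, incoming, B, mc_reals=decision_mc, rng=rng, menu=menu)
            step_postings.append((g.id, oc))
        if spec.ecosystem is not None:
            eco = spec.ecosystem
            cond = _eco_conditioning(spec, step_postings, metric_state)
            rng = _substream(seed, step, len(spec.groups))
            uniforms = rng.random((int(mc_reals), len(eco.topo_nodes)))
            vals = sample_nodes(eco, B, cond, uniforms)
            for j, m in enumerate(metric_names):
                mean = float(np.mean(_float_array(eco.node(m), vals[m])))
                if not np.isfinite(mean):
                    raise FloatingPointError(f"non-finite mean for metric {m!r} at t={t}")
                metric_means[step, j] = mean
                metric_state[m] = mean
        postings_all.append(step_postings)
        prev_postings = step_postings
    return SimulationRecord(times, postings_all, metric_names, metric_means, mc_reals, int(seed))


def _route_incoming(spec: SimulatorSpec, gid: str, prev_postings, t: float) -> InCombination:
    for sender, receiver in spec.routes:
        if receiver != gid:
            continue
        for pg, oc in prev_postings:
            if pg == sender:
                return InCombination(t, oc.output_action, pg, oc.target)
    return InCombination(t, NONE_VALUE, NONE_VALUE, NONE_VALUE)


def _eco_conditioning(spec: SimulatorSpec, step_postings, metric_state) -> dict:
    eco = spec.ecosystem
    cond = {}
    bindings = {b.node: b for b in spec.eco_bindings}
    for node in eco.input_nodes:
        b = bindings.get(node.name)
        if b is None:
            cond[node.name] = (
                node.domain[0] if node.kind == "discrete" else float(node.discretization[0])
            )
        elif b.kind == "action_count":
            count = sum(1 for _, oc in step_postings if oc.output_action == b.ref)
            if node.kind == "discrete":
                dom = np.asarray(node.domain, dtype=float)
                cond[node.name] = node.domain[int(np.argmin(np.abs(dom - count)))]
            else:
                cond[node.name] = float(count)
        elif b.kind == "prev_metric":
            cond[node.name] = float(metric_state[b.ref])
        else:
            raise ValueError(f"unknown ecosystem binding kind {b.kind!r}")
    return cond


def expected_metrics(
    spec: SimulatorSpec,
    B: ParameterVector,
    query,
    time_grid,
    mc_reals: int = 1000,
    seed: int = 0,
    decision_mc: int | None = None,
    forbidden: dict | None = None,
) -> np.ndarray:
    """Monte-Carlo estimate of E[Q(B)] for ``query`` = [(metric, time), ...].

    Queried times must lie on the simulation grid (within half a step).
    """
    rec = simulate(spec, B, time_grid, mc_reals=mc_reals, seed=seed,
                   decision_mc=decision_mc, forbidden=forbidden)
    names = list(rec.metric_names)
    out = np.empty(len(query))
    step = np.min(np.diff(rec.times)) if len(rec.times) > 1 else 1.0
    for i, (metric, t) in enumerate(query):
        if metric not in names:
            raise KeyError(f"unknown ecosystem metric {metric!r}")
        k = int(np.argmin(np.abs(rec.times - t)))
        if abs(rec.times[k] - t) > 0.5 * step + 1e-9:
            raise ValueError(f"queried time {t} is not on the simulation grid")
        out[i] = rec.metric_means[k, names.index(metric)]
    return out


def time_grid(start: float, stop: float, step: float = DEFAULT_TIME_STEP) -> np.ndarray:
    """Regular time grid in decimal years, inclusive of ``start``."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)
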