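"""Most practical ecosystem management plan (MPEMP).

An ecosystem manager states a desired future state ``q_d`` (expected values
of selected ecosystem metrics at designated times) and a constraint set of
actions that must happen and actions that must cease.  The MPEMP is the set
of group-submodel parameter values that brings the predicted ecosystem state
as close as possible to ``q_d`` while deviating minimally from the
hypothesis beliefs:

    B_MPEMP = argmax over B^(Grp) of  gH(B^(Grp)) - ||E[Q(B)] - q_d|| / ||q_H - q_d||

subject to the required/forbidden action constraints, with
q_H = E[Q(B_H)].  The plan's political feasibility is the ratio

    psi = gH^(Grp)(B_MPEMP) / gH^(Grp)(B_H):

values near 1 mean the plan demands little change in the groups' belief
systems; values near 0 predict stiff political resistance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement as agr
from .agreement import HellingerSettings
from .consistency import FitSettings, analyze, initialize
from .data import ActionsDataset
from .distance import euclidean_agreement
from .influence import OutCombination, SimulatorSpec, expected_metrics, simulate
from .optimize import SearchSpec, mdas_maximize
from .parameters import ParameterVector, project_rows
from .taskrun import SerialExecutor

logger = logging.getLogger(__name__)


@dataclass
class PolicyProblem:
    """The manager's desired state and action constraints.

    desired : list of (metric, time, value) rows defining q_d.
    required / forbidden : {group: [(action, target), ...]} — actions the
        plan must produce / must never produce (the complement set).
    variable_block : group parameters allowed to move ("grp" or explicit
        parameter keys).
    """

    desired: list
    required: dict = field(default_factory=dict)
    forbidden: dict = field(default_factory=dict)
    variable_block: object = "grp"
    time_grid: object = None
    lam: float = 0.5

    def __post_init__(self):
        for g in set(self.required) & set(self.forbidden):
            overlap = set(self.required[g]) & set(self.forbidden[g])
            if overlap:
                raise ValueError(f"group {g!r}: actions {overlap} both required and forbidden")


@dataclass
class PolicyResults:
    params: ParameterVector  # B_MPEMP
    b_h: ParameterVector
    psi: float
    objective: float  # reported (Hellinger-mode) objective at the optimum
    q_desired: np.ndarray
    q_hypothesis: np.ndarray
    q_achieved: np.ndarray
    gh_grp_mpemp: float
    gh_grp_h: float
    changed_beliefs: pd.DataFrame
    nfev: int
    trace: list

    def summary(self) -> str:
        lines = ["Most practical ecosystem management plan", "=" * 40]
        lines.append(f"objective (gH - normalized distance): {self.objective:.4f}")
        lines.append(f"political feasibility psi = {self.psi:.4f}")
        lines.append("desired vs achieved expected metrics:")
        for qd, qa in zip(self.q_desired, self.q_achieved):
            lines.append(f"  target {qd:.4f} -> achieved {qa:.4f}")
        lines.append("largest belief changes:")
        for row in self.changed_beliefs.head(5).itertuples(index=False):
            lines.append(f"  {row.parameter}: {row.beta_H:.4f} -> {row.beta_C:.4f}")
        return "\n".join(lines)


class PolicyOptimization:
    """Computes the MPEMP for a simulator and hypothesis parameter vector.

    The search runs MDAS over the variable group-parameter block with the
    smooth Euclidean surrogate standing in for gH inside the loop, forbidden
    actions enforced by menu filtering, and required actions checked on a
    confirmation run of every accepted plan.  Reported gH values (and psi)
    use Hellinger-mode agreement.
    """

    def __init__(self, problem: PolicyProblem, simulator: SimulatorSpec,
                 b_h: ParameterVector, settings: FitSettings | None = None,
                 hellinger: HellingerSettings | None = None):
        if simulator.ecosystem is None:
            raise ValueError("policy optimization needs an ecosystem submodel")
        self.problem = problem
        self.simulator = simulator
        self.b_h = b_h
        self.settings = settings or FitSettings()
        self.hellinger = hellinger or HellingerSettings()

    def _grid(self) -> np.ndarray:
        if self.problem.time_grid is not None:
            return np.asarray(self.problem.time_grid, dtype=float)
        from .influence import time_grid as mk

        times = [t for _, t, _ in self.problem.desired]
        return mk(float(min(times)) - 1.0, float(max(times)))

    def _forbidden_menus(self) -> dict:
        return {
            g: tuple(OutCombination(a, t) for a, t in pairs)
            for g, pairs in self.problem.forbidden.items()
        }

    def _expected(self, B: ParameterVector, grid) -> np.ndarray:
        query = [(m, t) for m, t, _ in self.problem.desired]
        return expected_metrics(
            self.simulator, B, query, grid, mc_reals=self.settings.eco_mc,
            seed=self.settings.seed, decision_mc=self.settings.decision_mc,
            forbidden=self._forbidden_menus(),
        )

    def _required_satisfied(self, B: ParameterVector, grid) -> bool:
        rec = simulate(self.simulator, B, grid, mc_reals=self.settings.eco_mc,
                       seed=self.settings.seed, decision_mc=self.settings.decision_mc,
                       forbidden=self._forbidden_menus())
        posted = {(g, oc.output_action, oc.target) for step in rec.postings for g, oc in step}
        for g, pairs in self.problem.required.items():
            for a, t in pairs:
                if (g, a, t) not in posted:
                    return False
        return True

    def _initial(self) -> ParameterVector:
        """Step 4: seed the search with the consistency Initialize step run
        on a pseudo-observed file of the required actions."""
        grid = self._grid()
        rows = [
            (float(t), g, a, tgt)
            for g, pairs in self.problem.required.items()
            for a, tgt in pairs
            for t in grid
        ]
        codes = tuple(g.id for g in self.simulator.groups) + (self.simulator.ecosystem.id,)
        if rows:
            ds = ActionsDataset(
                pd.DataFrame(rows, columns=["time", "group", "action", "target"]),
                None, codes,
            )
            b0 = initialize(self.b_h, ds, self.simulator, lam=self.problem.lam)
        else:
            b0 = self.b_h.copy()
        b0.active = self._variable_mask(b0)
        return b0

    def _variable_mask(self, B: ParameterVector) -> np.ndarray:
        vb = self.problem.variable_block
        if isinstance(vb, str):
            return B.block_mask(vb)
        mask = np.zeros(len(B), dtype=bool)
        for key in vb:
            mask[B.position(key)] = True
        return mask

    def fit(self, executor=None) -> PolicyResults:
        executor = executor or SerialExecutor()
        grid = self._grid()
        q_d = np.array([v for _, _, v in self.problem.desired], dtype=float)
        q_h = self._expected(self.b_h, grid)
        denom = float(np.linalg.norm(q_h - q_d))
        if denom == 0.0:
            raise ValueError("desired state already attained at B_H (q_H = q_d)")
        b0 = self._initial()
        active = np.flatnonzero(b0.active)
        if len(active) == 0:
            raise ValueError("variable block selects no parameters")

        def embed(x):
            B = b0.copy()
            B.values[active] = np.asarray(x, dtype=float)
            return project_rows(B, touched=active)

        def objective(x):
            B = embed(x)
            eH = euclidean_agreement(B, self.b_h, "grp")
            q = self._expected(B, grid)
            return eH - float(np.linalg.norm(q - q_d)) / denom

        def feasible(x):
            return self._required_satisfied(embed(x), grid)

        s = self.settings
        spec = SearchSpec(
            bounds=b0.bounds[active], start=b0.values[active], steps=s.steps,
            tol=s.tol, dims_ahead=s.dims_ahead, max_evals=s.max_evals,
            seed=s.seed, feasibility=feasible if self.problem.required else None,
        )
        res = mdas_maximize(objective, spec, executor=executor)
        b_mpemp = embed(res.x)
        b_mpemp.validate()
        self._confirm(b_mpemp, grid)
        gh_m = agr.g_hypothesis_block(b_mpemp, self.b_h, self.simulator, "grp", self.hellinger)
        gh_h = agr.g_hypothesis_block(self.b_h, self.b_h, self.simulator, "grp", self.hellinger)
        q_achieved = self._expected(b_mpemp, grid)
        reported = gh_m - float(np.linalg.norm(q_achieved - q_d)) / denom
        psi = political_feasibility_from_components(gh_m, gh_h)
        changes = analyze(self.b_h, b_mpemp)
        return PolicyResults(
            params=b_mpemp, b_h=self.b_h, psi=psi, objective=reported,
            q_desired=q_d, q_hypothesis=q_h, q_achieved=q_achieved,
            gh_grp_mpemp=gh_m, gh_grp_h=gh_h, changed_beliefs=changes,
            nfev=res.nfev, trace=res.trace,
        )

    def _confirm(self, B: ParameterVector, grid) -> None:
        """Hard verification that a confirmation simulation of the plan never
        posts a forbidden action and posts every required one."""
        rec = simulate(self.simulator, B, grid, mc_reals=self.settings.eco_mc,
                       seed=self.settings.seed, decision_mc=self.settings.decision_mc,
                       forbidden=self._forbidden_menus())
        posted = {(g, oc.output_action, oc.target) for step in rec.postings for g, oc in step}
        for g, pairs in self.problem.forbidden.items():
            for a, t in pairs:
                if (g, a, t) in posted:
                    raise AssertionError(f"plan posts forbidden action {(g, a, t)}")
        if self.problem.required and not self._required_satisfied(B, grid):
            logger.warning("plan does not post every required action")


def political_feasibility_from_components(gh_grp_mpemp: float, gh_grp_h: float) -> float:
    """psi = gH^(Grp)(B_MPEMP) / gH^(Grp)(B_H)."""
    if gh_grp_h == 0:
        raise ValueError("psi undefined: gH^(Grp)(B_H) is zero")
    return float(gh_grp_mpemp / gh_grp_h)


def political_feasibility(
    b_mpemp: ParameterVector,
    b_h: ParameterVector,
    simulator: SimulatorSpec,
    settings: HellingerSettings | None = None,
) -> float:
    """Political feasibility of a plan, computed with identical Monte-Carlo
    settings in numerator and denominator."""
    settings = settings or HellingerSettings()
    gh_m = agr.g_hypothesis_block(b_mpemp, b_h, simulator, "grp", settings)
    gh_h = agr.g_hypothesis_block(b_h, b_h, simulator, "grp", settings)
    return political_feasibility_from_components(gh_m, gh_h)
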