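"""Consistency analysis: Specify / Initialize / Maximize / Analyze.

Consistency analysis estimates a simulator's parameters so that its output
distributions agree as closely as possible with an observed actions history
while staying as close as possible to the theory-derived hypothesis values.
The four steps:

Specify
    the hypothesis parameter vector ``B_H`` (built with the model).
Initialize
    shift the choice-relevant conditional probability rows of each observed
    group toward the empirical frequencies of its observed out-combinations
    (a convex combination with weight ``lam``); entries that moved form the
    active set, so the optimization runs in a reduced dimension.
Maximize
    run MDAS over the active entries on gCA = (1 - cH) gS + cH eH, with the
    smooth Euclidean surrogate eH standing in for the Hellinger-based gH
    inside the loop; probability rows are projected back onto the simplex
    after every coordinate move.
Analyze
    rank the |beta_H - beta_C| differences to flag the areas of theory whose
    hypothesis values the data most disagrees with.

The class follows the Model/Results convention: build a
:class:`ConsistencyAnalysis` from a simulator, a dataset and ``B_H``, call
``fit()``, and read estimates and diagnostics off the returned
:class:`ConsistencyResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import agreement as agr
from .agreement import AgreementBreakdown, HellingerSettings
from .data import ActionsDataset
from .influence import SimulatorSpec, simulate, time_grid as make_time_grid
from .optimize import SearchSpec, mdas_maximize
from .parameters import ParameterVector, assert_same_structure, project_rows

logger = logging.getLogger(__name__)


@dataclass
class FitSettings:
    """Tunables of one consistency-analysis job.

    cH : priority on hypothesis agreement (case-study default 0.99).
    lam : Initialize shift weight toward empirical action frequencies.
    decision_mc / eco_mc : in-loop Monte-Carlo realizations per decision and
        per ecosystem step.
    report : Monte-Carlo settings for the Hellinger-mode reporting pass.
    """

    cH: float = 0.99
    lam: float = 0.5
    time_grid: object = None
    decision_mc: int = 1000
    eco_mc: int = 1000
    report: HellingerSettings = field(default_factory=lambda: HellingerSettings(
        n_design=1000, n_draws=1000))
    report_mc: int = 5000
    seed: int = 0
    max_evals: int = 200
    steps: object = 0.1
    tol: object = 1e-3
    dims_ahead: int = 3


def initialize(
    B_H: ParameterVector,
    observed: ActionsDataset,
    spec: SimulatorSpec,
    lam: float = 0.5,
) -> ParameterVector:
    """The Initialize step: frequency-matching convex shift.

    For every group with observed out-combinations and a declared choice
    node whose domain coincides with the group's action labels, each
    conditional probability row of that node moves to
    ``(1 - lam) * row_H + lam * freq`` (renormalized), where ``freq`` is the
    empirical distribution of the group's observed actions.  Unobserved
    groups keep their hypothesis values.  The active mask is set to the
    entries whose initial value differs from the hypothesis value.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    out = B_H.copy()
    rec = observed.records
    for group in spec.groups:
        if not group.choice_node:
            continue
        rows = rec[rec["group"] == group.id]
        if not len(rows):
            continue
        node = group.node(group.choice_node)
        counts = rows["action"].value_counts()
        total = float(counts.sum())
        freq = np.array([counts.get(v, 0) / total for v in node.domain])
        if not np.isclose(freq.sum(), 1.0):
            logger.warning(
                "group %s: %.0f%% of observed actions fall outside the choice node "
                "domain; frequencies renormalized", group.id, 100 * (1 - freq.sum()),
            )
            if freq.sum() == 0:
                continue
            freq = freq / freq.sum()
        from .parameters import ParamKey

        for context in group.cpt_contexts(node):
            keys = [ParamKey(group.id, context, f"p({node.name}={v})") for v in node.domain]
            row_h = np.array([B_H.get(k) for k in keys])
            row = (1.0 - lam) * row_h + lam * freq
            row = row / row.sum()
            for k, v in zip(keys, row):
                out.set(k, v)
    out.active = np.abs(out.values - B_H.values) > 1e-12
    return out


def analyze(B_H: ParameterVector, B_C: ParameterVector) -> pd.DataFrame:
    """The Analyze step: parameters ranked by |beta_H - beta_C|, descending."""
    assert_same_structure(B_H, B_C)
    rows = [
        (k.label(), float(h), float(c), float(abs(h - c)))
        for k, h, c in zip(B_H.index, B_H.values, B_C.values)
    ]
    frame = pd.DataFrame(rows, columns=["parameter", "beta_H", "beta_C", "abs_diff"])
    return frame.sort_values("abs_diff", ascending=False, kind="stable").reset_index(drop=True)


@dataclass
class ConsistencyResults:
    """Estimates and diagnostics of one consistency analysis."""

    model: "ConsistencyAnalysis"
    params: ParameterVector  # B_C
    b_initial: ParameterVector
    initial_agreement: dict  # mode -> AgreementBreakdown
    final_agreement: dict
    analysis: pd.DataFrame
    nfev: int
    trace: list
    termination: str

    @property
    def active_parameters(self) -> list:
        return [k.label() for k, a in zip(self.params.index, self.params.active) if a]

    def improvement_percent(self, mode: str = "euclidean") -> float:
        return agr.relative_improvement(
            self.initial_agreement[mode].gCA, self.final_agreement[mode].gCA
        )

    def summary(self) -> str:
        lines = ["Consistency analysis", "=" * 20]
        lines.append(f"active parameters: {int(self.params.active.sum())} of {len(self.params)}")
        lines.append(f"objective evaluations: {self.nfev} ({self.termination})")
        for mode in self.initial_agreement:
            ini, fin = self.initial_agreement[mode], self.final_agreement[mode]
            lines.append(
                f"gCA[{mode}]: initial {ini.gCA:.4f} -> final {fin.gCA:.4f} "
                f"({self.improvement_percent(mode):+.1f}%)"
            )
            lines.append(
                f"  gS_grp={_f(fin.gS_grp)} gS_eco={_f(fin.gS_eco)} "
                f"gH={_f(fin.gH)} eH_grp={_f(fin.eH_grp)} eH_eco={_f(fin.eH_eco)}"
            )
        lines.append("largest hypothesis-vs-consistent differences:")
        for row in self.analysis.head(5).itertuples(index=False):
            lines.append(f"  {row.parameter}: {row.beta_H:.4f} -> {row.beta_C:.4f}")
        return "\n".join(lines)


def _f(x):
    return "n/a" if x is None else f"{x:.4f}"


class ConsistencyAnalysis:
    """Fits a political-ecological simulator to an observed actions history.

    Parameters
    ----------
    simulator : SimulatorSpec
    data : ActionsDataset
    b_h : ParameterVector
        Hypothesis parameter vector (the Specify step).
    settings : FitSettings, optional
    """

    def __init__(self, simulator: SimulatorSpec, data: ActionsDataset,
                 b_h: ParameterVector, settings: FitSettings | None = None):
        b_h.validate()
        self.simulator = simulator
        self.data = data
        self.b_h = b_h
        self.settings = settings or FitSettings()
        if self.settings.time_grid is not None:
            self.time_grid = np.asarray(self.settings.time_grid, dtype=float)
        else:
            starts = []
            if len(data.records):
                starts.append(float(data.records["time"].min()))
            if len(data.metrics):
                starts.append(float(data.metrics["time"].min()))
            if not starts:
                raise ValueError("cannot derive a time grid from an empty dataset")
            self.time_grid = make_time_grid(min(starts), data.T_D)

    # -- objective ---------------------------------------------------------
    def _simulate(self, B: ParameterVector, mc: int, decision_mc: int):
        return simulate(
            self.simulator, B, self.time_grid, mc_reals=mc,
            seed=self.settings.seed, decision_mc=decision_mc,
        )

    def _embed(self, x: np.ndarray, base: ParameterVector) -> ParameterVector:
        B = base.copy()
        pos = np.flatnonzero(base.active)
        B.values[pos] = x
        return project_rows(B, touched=pos)

    def _surrogate_objective(self, base: ParameterVector):
        s = self.settings

        def objective(x):
            B = self._embed(np.asarray(x, dtype=float), base)
            rec = self._simulate(B, s.eco_mc, s.decision_mc)
            gS = self._g_sample(rec)
            if s.cH == 0.0:
                return gS  # pure MSDE: the hypothesis term never enters
            from .distance import euclidean_agreement

            eH = euclidean_agreement(B, self.b_h, "grp") + euclidean_agreement(
                B, self.b_h, "eco"
            )
            return (1.0 - s.cH) * gS + s.cH * eH

        return objective

    def _g_sample(self, rec) -> float:
        parts = []
        try:
            parts.append(agr.g_sample_group(rec, self.data)[0])
        except ValueError:
            pass
        try:
            parts.append(agr.g_sample_eco(rec, self.data))
        except ValueError:
            pass
        if not parts:
            raise ValueError("gS undefined for this dataset")
        return float(np.mean(parts))

    def _breakdowns(self, B: ParameterVector) -> dict:
        s = self.settings
        rec = self._simulate(B, s.report_mc, min(s.report_mc, 1000))
        out = {}
        for mode in ("euclidean", "hellinger"):
            out[mode] = agr.g_ca(
                B, self.b_h, rec, self.data, self.simulator,
                cH=s.cH, mode=mode, settings=s.report,
            )
        return out

    # -- fit ---------------------------------------------------------------
    def fit(self, executor=None) -> ConsistencyResults:
        b_init = initialize(self.b_h, self.data, self.simulator, lam=self.settings.lam)
        return self.fit_from(b_init, executor=executor)

    def fit_from(self, b_init: ParameterVector, executor=None) -> ConsistencyResults:
        """The Maximize step from a pre-initialized vector (its active mask
        defines the search dimensions)."""
        s = self.settings
        active = np.flatnonzero(b_init.active)
        if len(active) == 0:
            logger.warning("no active parameters; returning B_initial unchanged")
            breakdowns = self._breakdowns(b_init)
            return ConsistencyResults(
                model=self, params=b_init, b_initial=b_init,
                initial_agreement=breakdowns, final_agreement=breakdowns,
                analysis=analyze(self.b_h, b_init), nfev=0, trace=[],
                termination="no_active_parameters",
            )
        objective = self._surrogate_objective(b_init)
        spec = SearchSpec(
            bounds=b_init.bounds[active],
            start=b_init.values[active],
            steps=s.steps,
            tol=s.tol,
            dims_ahead=s.dims_ahead,
            max_evals=s.max_evals,
            seed=s.seed,
        )
        res = mdas_maximize(objective, spec, executor=executor)
        b_c = self._embed(res.x, b_init)
        b_c.validate()
        return ConsistencyResults(
            model=self,
            params=b_c,
            b_initial=b_init,
            initial_agreement=self._breakdowns(b_init),
            final_agreement=self._breakdowns(b_c),
            analysis=analyze(self.b_h, b_c),
            nfev=res.nfev,
            trace=res.trace,
            termination=res.termination,
        )


def maximize(
    b_initial: ParameterVector,
    b_h: ParameterVector,
    observed: ActionsDataset,
    spec: SimulatorSpec,
    cH: float = 0.99,
    settings: FitSettings | None = None,
    executor=None,
) -> ConsistencyResults:
    """Functional form of the Maximize step for a pre-initialized vector."""
    settings = replace(settings or FitSettings(), cH=cH)
    model = ConsistencyAnalysis(spec, observed, b_h, settings)
    return model.fit_from(b_initial, executor=executor)
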