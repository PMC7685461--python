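"""Agreement functions for consistency analysis.

``gS`` measures agreement between simulator output and an observed actions
data set: its group part is the fraction of observed out-combinations the
simulator reproduces, its ecosystem part one minus the mean range-normalized
absolute metric error.  ``gH`` measures agreement between the simulator's
distribution at a trial parameter vector and at the hypothesis vector, via
per-conditioning-combination Hellinger distances.  The composite objective is

    gCA(B) = (1 - cH) gS(B) + cH gH(B),

where cH in (0, 1) is the manager's priority on staying near the hypothesis
distribution; cH = 0 reduces the estimator to a pure minimum simulated
distance estimator.  Inside optimization loops ``gH`` may be replaced by the
smooth Euclidean surrogate ``eH`` (negative distance to the hypothesis
values, reported blockwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import distance as dist
from .data import ActionsDataset
from .influence import SimulationRecord, SimulatorSpec
from .influence import enumerate_conditioning_combinations
from .parameters import ParameterVector, assert_same_structure

logger = logging.getLogger(__name__)


@dataclass
class HellingerSettings:
    """Monte-Carlo settings for gH evaluation.

    ``exact="auto"`` uses enumerated joints (closed-form finite sums) for
    purely discrete IDs and Monte-Carlo design-point estimation otherwise.
    """

    n_design: int = 1000
    n_draws: int = 1000
    seed: int = 0
    exact: str = "auto"  # "auto" | "always" | "never"


@dataclass
class AgreementBreakdown:
    """All agreement components entering one gCA evaluation."""

    gS_grp: float | None
    gS_eco: float | None
    gS: float | None
    gH: float | None
    gH_per_id: dict = field(default_factory=dict)
    eH_grp: float | None = None
    eH_eco: float | None = None
    cH: float = 0.99
    mode: str = "hellinger"  # "hellinger" | "euclidean"
    gCA: float = None
    match_table: pd.DataFrame = None

    def hypothesis_term(self) -> float:
        return self.gH if self.mode == "hellinger" else (self.eH_grp or 0.0) + (self.eH_eco or 0.0)


# ---------------------------------------------------------------------------
# Sample agreement
# ---------------------------------------------------------------------------

def _snap_indices(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Nearest-grid-point assignment of observation times."""
    idx = np.searchsorted(grid, times)
    idx = np.clip(idx, 1, len(grid) - 1)
    left = grid[idx - 1]
    right = grid[idx]
    return np.where(np.abs(times - left) <= np.abs(right - times), idx - 1, idx)


def match_counts(simulated: SimulationRecord, observed: ActionsDataset) -> pd.DataFrame:
    """Per-group observation/match counts and fractions.

    A cell matches iff both action and target match a simulated posting of
    that group at the observation's (nearest) time step; action-only and
    target-only matches are tallied as auxiliary columns.  Multiple observed
    postings per time point count with multiplicity.
    """
    grid = np.asarray(simulated.times)
    rec = observed.records
    counts: dict = {}
    if len(rec):
        steps = _snap_indices(rec["time"].to_numpy(), grid)
        for (t_idx, group), rows in rec.groupby([steps, "group"], sort=False):
            sim_ocs = [oc for g, oc in simulated.postings[int(t_idx)] if g == group]
            sim_actions = {oc.output_action for oc in sim_ocs}
            sim_targets = {oc.target for oc in sim_ocs}
            sim_pairs = {(oc.output_action, oc.target) for oc in sim_ocs}
            c = counts.setdefault(group, [0, 0, 0, 0])
            for row in rows.itertuples(index=False):
                c[0] += 1
                c[1] += (row.action, row.target) in sim_pairs
                c[2] += row.action in sim_actions
                c[3] += row.target in sim_targets
    rows = []
    for group in sorted(counts):
        n_obs, n_match, n_act, n_trg = counts[group]
        rows.append(
            (group, n_obs, n_match, match_fraction(n_obs, n_match),
             n_act, match_fraction(n_obs, n_act),
             n_trg, match_fraction(n_obs, n_trg))
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n_obs", "n_match", "match_fraction",
                 "n_actmatch", "action_match_fraction",
                 "n_trgtmatch", "target_match_fraction"],
    )


def match_fraction(n_obs: int, n_match: int) -> float:
    """Fraction of observed out-combinations matched by the simulator."""
    if n_obs < 0 or n_match < 0 or n_match > n_obs:
        raise ValueError("need 0 <= n_match <= n_obs")
    return 0.0 if n_obs == 0 else n_match / n_obs


def g_sample_group(simulated: SimulationRecord, observed: ActionsDataset):
    """Group-side sample agreement: overall fraction of observed
    (group, time) cells whose out-combination the simulator reproduces.
    Only groups with at least one observation enter."""
    table = match_counts(simulated, observed)
    if not len(table):
        raise ValueError("gS_grp undefined: observed data set has no group records")
    n_obs = int(table["n_obs"].sum())
    n_match = int(table["n_match"].sum())
    return match_fraction(n_obs, n_match), table


def g_sample_eco(simulated: SimulationRecord, observed: ActionsDataset) -> float:
    """Ecosystem-side sample agreement: one minus the mean range-normalized
    absolute error between observed metric series and simulated metric
    means.  Zero-range metrics are excluded (logged) since their term is
    undefined."""
    names = [m for m in observed.metric_names() if m in simulated.metric_names]
    grid = np.asarray(simulated.times)
    terms = []
    used = 0
    for m in names:
        series = observed.metric_series(m)
        if len(series) < 2:
            continue
        z = series["value"].to_numpy()
        R = float(z.max() - z.min())
        if R == 0:
            logger.warning("metric %r has zero observed range; excluded from gS_eco", m)
            continue
        idx = _snap_indices(series["time"].to_numpy(), grid)
        zhat = simulated.metric_means[idx, list(simulated.metric_names).index(m)]
        terms.append(np.abs(z - zhat) / R)
        used += 1
    if used == 0:
        raise ValueError("gS_eco undefined: no usable ecosystem metric series")
    return 1.0 - float(np.mean(np.concatenate(terms)))


# ---------------------------------------------------------------------------
# Hypothesis agreement
# ---------------------------------------------------------------------------

def g_hypothesis(
    B: ParameterVector,
    B_H: ParameterVector,
    spec: SimulatorSpec,
    settings: HellingerSettings | None = None,
):
    """gH(B): mean over IDs of one minus the mean per-conditioning-combination
    Hellinger distance between the ID's distribution at ``B`` and at ``B_H``.

    Returns ``(overall, per_id)``.  Both distributions are evaluated on the
    same design points and, in Monte-Carlo mode, with the same random
    substream, so gH(B_H) = 1 holds exactly in discrete-exact mode and up to
    bandwidth pairing otherwise.
    """
    assert_same_structure(B, B_H)
    settings = settings or HellingerSettings()
    per_id = {}
    for i, sub in enumerate(spec.submodels):
        combos = enumerate_conditioning_combinations(sub)
        exact = settings.exact == "always" or (
            settings.exact == "auto" and dist.is_discrete_exact(sub)
        )
        distances = []
        for j, combo in enumerate(combos):
            if exact:
                p1 = dist.exact_pdpf(sub, B, combo)
                p2 = dist.exact_pdpf(sub, B_H, combo)
                distances.append(dist.hellinger_exact(p1, p2))
            else:
                sub_seed = (settings.seed * 1000003 + i * 1009 + j) & 0x7FFFFFFF
                design = dist.draw_design_points(sub, settings.n_design, seed=sub_seed)
                d1 = dist.submodel_draws(sub, B, combo, settings.n_draws, seed=sub_seed + 1)
                d2 = dist.submodel_draws(sub, B_H, combo, settings.n_draws, seed=sub_seed + 1)
                pf1 = dist.estimate_pdpf(d1, design)
                pf2 = dist.estimate_pdpf(d2, design)
                distances.append(dist.hellinger(pf1, pf2))
        per_id[sub.id] = 1.0 - float(np.mean(distances))
    overall = float(np.mean(list(per_id.values())))
    return overall, per_id


def g_hypothesis_block(
    B: ParameterVector,
    B_H: ParameterVector,
    spec: SimulatorSpec,
    block: str,
    settings: HellingerSettings | None = None,
) -> float:
    """gH restricted to the group or ecosystem IDs (used by the political
    feasibility index)."""
    overall, per_id = g_hypothesis(B, B_H, spec, settings)
    if block == "grp":
        ids = [g.id for g in spec.groups]
    elif block == "eco":
        ids = [spec.ecosystem.id] if spec.ecosystem is not None else []
    else:
        return overall
    if not ids:
        raise ValueError(f"no submodels in block {block!r}")
    return float(np.mean([per_id[i] for i in ids]))


# ---------------------------------------------------------------------------
# Composite
# ---------------------------------------------------------------------------

def g_ca(
    B: ParameterVector,
    B_H: ParameterVector,
    simulated: SimulationRecord,
    observed: ActionsDataset,
    spec: SimulatorSpec,
    cH: float = 0.99,
    mode: str = "hellinger",
    settings: HellingerSettings | None = None,
) -> AgreementBreakdown:
    """The composite consistency-analysis objective

        gCA(B) = (1 - cH) gS(B) + cH {gH(B) or eH(B)},

    with gS the mean of its defined components (a component with no usable
    observations is dropped, logged)."""
    if not (0.0 <= cH <= 1.0):
        raise ValueError("cH must lie in [0, 1]")
    gS_grp = gS_eco = None
    table = None
    try:
        gS_grp, table = g_sample_group(simulated, observed)
    except ValueError as e:
        logger.warning("%s", e)
    try:
        gS_eco = g_sample_eco(simulated, observed)
    except ValueError as e:
        logger.warning("%s", e)
    parts = [x for x in (gS_grp, gS_eco) if x is not None]
    if not parts:
        raise ValueError("gS undefined: neither group nor ecosystem agreement computable")
    gS = float(np.mean(parts))

    gH = None
    per_id: dict = {}
    eH_grp = eH_eco = None
    if mode == "hellinger":
        gH, per_id = g_hypothesis(B, B_H, spec, settings)
        hyp = gH
    elif mode == "euclidean":
        eH_grp = dist.euclidean_agreement(B, B_H, "grp")
        eH_eco = dist.euclidean_agreement(B, B_H, "eco")
        hyp = eH_grp + eH_eco
    else:
        raise ValueError(f"unknown mode {mode!r}")
    gCA = (1.0 - cH) * gS + cH * hyp
    return AgreementBreakdown(
        gS_grp=gS_grp, gS_eco=gS_eco, gS=gS, gH=gH, gH_per_id=per_id,
        eH_grp=eH_grp, eH_eco=eH_eco, cH=cH, mode=mode, gCA=float(gCA),
        match_table=table,
    )


def relative_improvement(initial: float, final: float) -> float:
    """Percent improvement of a fit: 100 (final - initial) / |initial|."""
    if initial == 0:
        raise ValueError("relative improvement undefined for a zero initial value")
    return 100.0 * (final - initial) / abs(initial)
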