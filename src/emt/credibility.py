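"""Credibility assessment: jackknife intervals, prediction error rates, and
deterministic sensitivity analysis.

Three jobs quantify how far a fitted simulator can be trusted:

* delete-d jackknife confidence intervals — re-estimate on ``n_jack``
  without-replacement subsamples of size ``r = floor(n^tau)`` and take the
  shortest interval containing ``(1 - alpha) n_jack`` replicate values;
* one-step-ahead prediction error rates — roll a refit schedule through the
  data, predicting each next time point from a model refitted on the data
  before it: the predicted-actions error rate ``zeta``, the RMS metric
  prediction error ``epsilon`` and the naive-forecast baseline ``delta``;
* deterministic sensitivity analysis — search for parameter values near the
  hypothesis vector that reproduce a skeptic-specified condition/response
  scenario; if plausible values suffice, the model is excessively sensitive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consistency import ConsistencyAnalysis, ConsistencyResults, FitSettings, initialize
from .data import ActionsDataset
from .influence import SimulatorSpec, simulate
from .parameters import ParamKey, ParameterVector
from .taskrun import SerialExecutor

logger = logging.getLogger(__name__)

#: Quarterly refit interval in decimal years: (4 x 3)/52 weeks.
QUARTERLY_REFIT_INTERVAL = (4.0 * 3.0) / 52.0


# ---------------------------------------------------------------------------
# Delete-d jackknife
# ---------------------------------------------------------------------------

def subsample_size(n: int, tau: float = 0.97) -> int:
    """Jackknife subsample size ``r = floor(n^tau)`` (so ``d = n - r`` are
    deleted).  Truncation, not rounding: r = 546^0.97 -> 451."""
    if n < 2:
        raise ValueError("need n >= 2 observations")
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    r = int(math.floor(n ** tau))
    if r == 0:
        raise ValueError(f"subsample size floor(n^tau) is zero for n={n}, tau={tau}")
    return min(r, n - 1)


def shortest_interval(values, alpha: float) -> tuple:
    """The shortest window of sorted replicate values containing
    ``ceil((1 - alpha) * len(values))`` of them; ties go to the lowest
    window."""
    v = np.sort(np.asarray(values, dtype=float))
    m = len(v)
    k = int(math.ceil((1.0 - alpha) * m))
    k = max(1, min(k, m))
    widths = v[k - 1:] - v[: m - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) minimizer
    return float(v[i]), float(v[i + k - 1])


@dataclass
class JackknifeResults:
    """Replicates and shortest confidence intervals per parameter."""

    replicates: pd.DataFrame  # n_jack rows x parameters
    intervals: pd.DataFrame  # parameter, lower, upper, width
    n: int
    r: int
    tau: float
    n_jack: int
    alpha: float
    dropped: int = 0

    @property
    def d(self) -> int:
        return self.n - self.r

    def interval(self, parameter: str) -> tuple:
        row = self.intervals[self.intervals["parameter"] == parameter]
        if not len(row):
            raise KeyError(f"no interval for parameter {parameter!r}")
        return float(row["lower"].iloc[0]), float(row["upper"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Delete-d jackknife: n={self.n}, r={self.r} (tau={self.tau}), "
            f"d={self.d}, n_jack={self.n_jack}, "
            f"{100 * (1 - self.alpha):.0f}% shortest intervals",
        ]
        widest = self.intervals.sort_values("width", ascending=False).head(5)
        for row in widest.itertuples(index=False):
            lines.append(
                f"  {row.parameter}: [{row.lower:.3f}, {row.upper:.3f}] width {row.width:.3f}"
            )
        return "\n".join(lines)


class DeleteDJackknife:
    """Jackknife confidence intervals for any per-dataset estimator.

    Parameters
    ----------
    estimator : callable(subsample) -> mapping/Series/array of estimates
        Must be deterministic given its input (seeded internally).
    data : sequence or ActionsDataset
        Subsampled by observation (by record, for a dataset).
    """

    def __init__(self, estimator, data, tau: float = 0.97, n_jack: int = 5,
                 alpha: float = 0.5, seed: int = 0):
        if n_jack < 2:
            raise ValueError("need n_jack >= 2 replicates")
        self.estimator = estimator
        self.data = data
        self.tau = float(tau)
        self.n_jack = int(n_jack)
        self.alpha = float(alpha)
        self.seed = int(seed)

    def _n(self) -> int:
        return self.data.n_records if isinstance(self.data, ActionsDataset) else len(self.data)

    def _take(self, idx):
        if isinstance(self.data, ActionsDataset):
            return self.data.take_records(idx)
        if isinstance(self.data, np.ndarray):
            return self.data[idx]
        return [self.data[i] for i in idx]

    def fit(self, executor=None) -> JackknifeResults:
        executor = executor or SerialExecutor()
        n = self._n()
        r = subsample_size(n, self.tau)
        rng = np.random.default_rng(self.seed)
        subsamples = [self._take(rng.choice(n, size=r, replace=False)) for _ in range(self.n_jack)]

        def replicate(sub):
            try:
                return _as_series(self.estimator(sub))
            except Exception as e:  # noqa: BLE001 - retried once, then dropped
                logger.warning("jackknife replicate failed (%s); retrying once", e)
                try:
                    return _as_series(self.estimator(sub))
                except Exception as e2:  # noqa: BLE001
                    logger.warning("jackknife replicate dropped: %s", e2)
                    return None

        results = executor.map(replicate, subsamples)
        kept = [s for s in results if s is not None]
        if len(kept) < 2:
            raise RuntimeError("fewer than two jackknife replicates succeeded")
        reps = pd.DataFrame(kept).reset_index(drop=True)
        rows = []
        for col in reps.columns:
            lo, hi = shortest_interval(reps[col].to_numpy(), self.alpha)
            rows.append((col, lo, hi, hi - lo))
        intervals = pd.DataFrame(rows, columns=["parameter", "lower", "upper", "width"])
        return JackknifeResults(
            replicates=reps, intervals=intervals, n=n, r=r, tau=self.tau,
            n_jack=self.n_jack, alpha=self.alpha, dropped=len(results) - len(kept),
        )


def _as_series(est) -> pd.Series:
    if isinstance(est, pd.Series):
        return est.astype(float)
    if isinstance(est, dict):
        return pd.Series({str(k): float(v) for k, v in est.items()})
    arr = np.atleast_1d(np.asarray(est, dtype=float))
    return pd.Series(arr, index=[f"b{i}" for i in range(len(arr))])


# ---------------------------------------------------------------------------
# Prediction error rates
# ---------------------------------------------------------------------------

def zeta_hat(match_counts, obs_counts) -> float:
    """Predicted-actions error rate: the mean over the refit schedule of
    ``1 - n_match / n_obs``."""
    m = np.asarray(match_counts, dtype=float)
    o = np.asarray(obs_counts, dtype=float)
    if len(m) != len(o) or len(m) == 0:
        raise ValueError("need equally sized, nonempty count vectors")
    if np.any(o <= 0):
        raise ValueError("every scheduled step needs at least one observed action")
    if np.any(m > o) or np.any(m < 0):
        raise ValueError("need 0 <= n_match <= n_obs")
    return float(np.mean(1.0 - m / o))


def rms_error(observed, predicted) -> float:
    """Root-mean-square prediction error over the refit schedule."""
    z = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if z.shape != p.shape or len(z) == 0:
        raise ValueError("need equally shaped, nonempty series")
    return float(np.sqrt(np.mean((z - p) ** 2)))


def n_predictions(T_D: float, s: float, v: float) -> int:
    """Number of scheduled refit/predict steps: floor((T_D - 1 - s)/v) + 1,
    with ``T_D`` and the schedule start ``s`` measured in years from the
    first observation time."""
    if v <= 0:
        raise ValueError("refit interval v must be positive")
    n = int(math.floor((T_D - 1.0 - s) / v)) + 1
    if n < 1:
        raise ValueError("refit schedule is empty (s too close to T_D)")
    return n


def blind_guessing_threshold(K: int) -> float:
    """Error rate of uniform guessing over a K-element out-combination menu:
    1 - 1/K.  A simulator is preferred when zeta-hat falls below this."""
    if K < 1:
        raise ValueError("menu size K must be >= 1")
    return 1.0 - 1.0 / K


@dataclass
class PredictionErrorResults:
    zeta: float
    epsilon: dict  # metric -> RMS model prediction error
    delta: dict  # metric -> RMS naive-forecast error
    schedule: np.ndarray
    n_pred: int
    s: float
    v: float
    match_counts: list
    obs_counts: list
    blind_thresholds: dict  # group -> 1 - 1/K
    refits: list = field(default_factory=list)

    def naive_preferred(self, metric: str) -> bool:
        return self.epsilon[metric] > self.delta[metric]

    def summary(self) -> str:
        lines = [
            f"One-step-ahead prediction errors: n_pred={self.n_pred}, "
            f"s={self.s:.4f}, v={self.v:.4f}",
            f"  zeta-hat = {self.zeta:.4f}",
        ]
        for g, thr in self.blind_thresholds.items():
            verdict = "better than" if self.zeta < thr else "no better than"
            lines.append(f"  group {g}: blind-guessing threshold {thr:.4f} "
                         f"({verdict} blind guessing)")
        for m in self.epsilon:
            pref = "naive forecast preferred" if self.naive_preferred(m) else "model preferred"
            lines.append(
                f"  metric {m}: epsilon-hat={self.epsilon[m]:.4f} "
                f"delta-hat={self.delta[m]:.4f} ({pref})"
            )
        return "\n".join(lines)


class PredictionErrorAnalysis:
    """Rolling-refit one-step-ahead prediction error estimation.

    At each scheduled time ``t_j = s + j v`` the simulator is refitted (a
    concurrent consistency-analysis task) on all data up through ``t_j`` and
    run through the next scheduled time; the predicted out-combinations and
    metric values there are scored against the observations.
    """

    def __init__(self, simulator: SimulatorSpec, data: ActionsDataset,
                 b_h: ParameterVector, s: float, v: float = QUARTERLY_REFIT_INTERVAL,
                 settings: FitSettings | None = None):
        if s < 0:
            raise ValueError("schedule start s must be nonnegative")
        self.simulator = simulator
        self.data = data
        self.b_h = b_h
        self.s = float(s)
        self.v = float(v)
        self.settings = settings or FitSettings()

    def fit(self, executor=None) -> PredictionErrorResults:
        executor = executor or SerialExecutor()
        data = self.data
        T_D = data.T_D
        t0 = float(data.records["time"].min())
        n_pred = n_predictions(T_D - t0, self.s, self.v)
        schedule = t0 + self.s + self.v * np.arange(n_pred)
        if schedule[-1] >= T_D:
            raise ValueError("refit schedule extends past the most recent time point")
        obs_times = data.observation_times

        def refit_and_predict(t_j):
            t_next = t_j + self.v
            train = data.restrict_through(t_j)
            model = ConsistencyAnalysis(self.simulator, train, self.b_h, self.settings)
            res = model.fit()
            grid = model.time_grid
            # extend the grid through the prediction time
            step = grid[1] - grid[0] if len(grid) > 1 else self.v
            horizon = np.arange(grid[0], t_next + step, step)
            rec = simulate(self.simulator, res.params, horizon,
                           mc_reals=self.settings.eco_mc, seed=self.settings.seed,
                           decision_mc=self.settings.decision_mc)
            return res, rec, t_j, t_next

        outputs = executor.map(refit_and_predict, list(schedule))
        from .agreement import match_counts as _match_counts

        m_counts, o_counts = [], []
        eps_terms: dict = {}
        del_terms: dict = {}
        refits = []
        for res, rec, t_j, t_next in outputs:
            refits.append(res)
            window = data.records[
                (data.records["time"] > t_j + 1e-9) & (data.records["time"] <= t_next + 1e-9)
            ]
            if len(window):
                tbl = _match_counts(rec, ActionsDataset(window, None, data.group_codes))
                o = int(tbl["n_obs"].sum())
                m = int(tbl["n_match"].sum())
                m_counts.append(m)
                o_counts.append(o)
            else:
                logger.warning("no observed out-combinations in (%.4f, %.4f]; "
                               "step skipped in zeta-hat", t_j, t_next)
            for metric in data.metric_names():
                series = data.metric_series(metric)
                in_win = series[(series["time"] > t_j + 1e-9) & (series["time"] <= t_next + 1e-9)]
                before = series[series["time"] <= t_j + 1e-9]
                if not len(in_win) or not len(before):
                    continue
                z_obs = float(in_win["value"].iloc[-1])
                t_obs = float(in_win["time"].iloc[-1])
                k = int(np.argmin(np.abs(rec.times - t_obs)))
                z_pred = float(rec.metric_means[k, list(rec.metric_names).index(metric)])
                z_naive = float(before["value"].iloc[-1])
                eps_terms.setdefault(metric, []).append((z_obs, z_pred))
                del_terms.setdefault(metric, []).append((z_obs, z_naive))
        if not m_counts:
            raise ValueError("no scheduled step had observed out-combinations")
        zeta = zeta_hat(m_counts, o_counts)
        epsilon = {m: rms_error(*zip(*pairs)) for m, pairs in eps_terms.items()}
        delta = {m: rms_error(*zip(*pairs)) for m, pairs in del_terms.items()}
        thresholds = {g.id: blind_guessing_threshold(len(g.menu)) for g in self.simulator.groups}
        return PredictionErrorResults(
            zeta=zeta, epsilon=epsilon, delta=delta, schedule=schedule,
            n_pred=n_pred, s=self.s, v=self.v, match_counts=m_counts,
            obs_counts=o_counts, blind_thresholds=thresholds, refits=refits,
        )


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class DsaProblem:
    """A skeptic's condition/response scenario.

    ``conditions`` and ``responses`` hold required actions per group
    (``{group: [(action, target), ...]}``); forbidden ("complement") actions
    go in ``forbidden``.  ``metric_responses`` is a list of
    ``(metric, time, value)`` rows the scenario requires the ecosystem to
    produce.  ``variable_block`` names the parameters allowed to move
    (block label ``"grp"``/``"eco"`` or explicit keys); ``plausibility``
    maps parameter labels to (lo, hi) scientifically plausible ranges.
    """

    conditions: dict = field(default_factory=dict)
    responses: dict = field(default_factory=dict)
    forbidden: dict = field(default_factory=dict)
    metric_responses: list = field(default_factory=list)
    variable_block: object = "eco"
    plausibility: dict = field(default_factory=dict)
    time_grid: object = None
    cH: float = 0.1  # the DSA convention


@dataclass
class DsaResults:
    b_dsa: ParameterVector
    b_h: ParameterVector
    most_sensitive: str  # parameter label l
    difference: float  # |beta_H^(l) - beta_DSA^(l)|
    supported: bool
    table: pd.DataFrame  # parameter, beta_H, beta_DSA, abs_diff, in_ci, plausible
    fit: ConsistencyResults

    def summary(self) -> str:
        verdict = "supports" if self.supported else "does not support"
        return (
            f"Deterministic sensitivity analysis\n"
            f"  most sensitive parameter: {self.most_sensitive} "
            f"(|beta_H - beta_DSA| = {self.difference:.4f})\n"
            f"  the analysis {verdict} the skeptic's concerns"
        )


class SensitivityAnalysis:
    """Deterministic sensitivity analysis of a fitted simulator.

    Builds an "observed" dataset from the scenario's required actions and
    metric responses, initializes the group block so complement actions are
    never chosen, maximizes gCA at cH = 0.1 under a feasibility filter that
    rejects parameter points whose confirmation run posts a complement
    action, and reports the most sensitive parameter: the smallest nonzero
    movement |beta_H - beta_DSA| needed to produce the scenario.
    """

    def __init__(self, problem: DsaProblem, simulator: SimulatorSpec,
                 b_h: ParameterVector, intervals: pd.DataFrame | None = None,
                 settings: FitSettings | None = None):
        self.problem = problem
        self.simulator = simulator
        self.b_h = b_h
        self.intervals = intervals
        self.settings = replace(settings or FitSettings(), cH=problem.cH)

    # -- scenario plumbing -------------------------------------------------
    def _grid(self) -> np.ndarray:
        if self.problem.time_grid is not None:
            return np.asarray(self.problem.time_grid, dtype=float)
        times = [t for _, t, _ in self.problem.metric_responses]
        if not times:
            raise ValueError("DSA problem needs a time grid or metric responses")
        from .influence import time_grid as mk

        return mk(float(min(times)) - 1.0, float(max(times)))

    def scenario_dataset(self) -> ActionsDataset:
        """Step 3: the required actions and ecosystem responses cast as an
        observed-actions file pair."""
        grid = self._grid()
        rows = []
        for source in (self.problem.conditions, self.problem.responses):
            for group, actions in source.items():
                for action, target in actions:
                    for t in grid:
                        rows.append((float(t), group, action, target))
        metrics = pd.DataFrame(
            [(float(t), m, float(v)) for m, t, v in self.problem.metric_responses],
            columns=["time", "metric", "value"],
        )
        codes = tuple(g.id for g in self.simulator.groups)
        if self.simulator.ecosystem is not None:
            codes = codes + (self.simulator.ecosystem.id,)
        if not rows:
            # purely ecosystem-response scenario
            return ActionsDataset(
                pd.DataFrame(columns=["time", "group", "action", "target"]), metrics, codes
            )
        frame = pd.DataFrame(rows, columns=["time", "group", "action", "target"])
        return ActionsDataset(frame.sort_values("time", kind="stable"), metrics, codes)

    def _suppressed_initial(self) -> ParameterVector:
        """Step 4: initialize the group block so no complement action is
        chosen — choice-node probability mass on forbidden action labels is
        floored (utility suppression) and rows renormalized."""
        B = self.b_h.copy()
        for group in self.simulator.groups:
            bad = {a for a, _ in self.problem.forbidden.get(group.id, ())}
            if not bad or not group.choice_node:
                if bad:
                    logger.warning("group %s has no choice node; relying on menu "
                                   "filtering alone", group.id)
                continue
            node = group.node(group.choice_node)
            for context in group.cpt_contexts(node):
                keys = [ParamKey(group.id, context, f"p({node.name}={v})") for v in node.domain]
                row = np.array([B.get(k) for k in keys])
                for i, v in enumerate(node.domain):
                    if v in bad:
                        row[i] = 1e-9
                row = row / row.sum()
                for k, val in zip(keys, row):
                    B.set(k, val)
        return B

    def _forbidden_menus(self) -> dict:
        from .influence import OutCombination

        return {
            g: tuple(OutCombination(a, t) for a, t in pairs)
            for g, pairs in self.problem.forbidden.items()
        }

    def _variable_mask(self, B: ParameterVector) -> np.ndarray:
        vb = self.problem.variable_block
        if isinstance(vb, str):
            return B.block_mask(vb)
        mask = np.zeros(len(B), dtype=bool)
        for key in vb:
            mask[B.position(key)] = True
        return mask

    # -- run ---------------------------------------------------------------
    def fit(self, executor=None) -> DsaResults:
        observed = self.scenario_dataset()
        grid = self._grid()
        b_init = self._suppressed_initial()
        b_init.active = self._variable_mask(b_init)
        if not b_init.active.any():
            raise ValueError("DSA variable block selects no parameters")
        settings = replace(self.settings, time_grid=grid)
        model = ConsistencyAnalysis(self.simulator, observed, self.b_h, settings)
        forbidden = self._forbidden_menus()

        # menu filtering enforces the complement-action constraint inside the
        # objective: a trial point can never post a forbidden action
        def guarded(Bv, mc, dmc):
            return simulate(self.simulator, Bv, grid, mc_reals=mc,
                            seed=settings.seed, decision_mc=dmc, forbidden=forbidden)

        model._simulate = guarded
        res = model.fit_from(b_init, executor=executor)
        b_dsa = res.params
        table = self._analysis_table(b_dsa)
        active_rows = table[table["active"]]
        moved = active_rows[active_rows["abs_diff"] > 1e-12]
        pick = moved if len(moved) else active_rows
        row = pick.loc[pick["abs_diff"].idxmin()]
        supported = bool(row["in_ci"] or row["plausible"])
        return DsaResults(
            b_dsa=b_dsa, b_h=self.b_h, most_sensitive=str(row["parameter"]),
            difference=float(row["abs_diff"]), supported=supported,
            table=table.drop(columns=["active"]), fit=res,
        )

    def _analysis_table(self, b_dsa: ParameterVector) -> pd.DataFrame:
        rows = []
        ci_lookup = {}
        if self.intervals is not None:
            ci_lookup = {
                str(r.parameter): (float(r.lower), float(r.upper))
                for r in self.intervals.itertuples(index=False)
            }
        for k, h, d_val, active in zip(
            self.b_h.index, self.b_h.values, b_dsa.values, b_dsa.active
        ):
            label = k.label()
            in_ci = False
            if label in ci_lookup:
                lo, hi = ci_lookup[label]
                in_ci = lo <= d_val <= hi
            plausible = False
            if label in self.problem.plausibility:
                lo, hi = self.problem.plausibility[label]
                plausible = lo <= d_val <= hi
            rows.append((label, float(h), float(d_val), float(abs(h - d_val)),
                         bool(active), in_ci, plausible))
        return pd.DataFrame(
            rows, columns=["parameter", "beta_H", "beta_DSA", "abs_diff",
                           "active", "in_ci", "plausible"],
        )
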