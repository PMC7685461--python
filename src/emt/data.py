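"""Observed-actions histories and ecosystem-metric series.

The on-disk dialect is two tab-separated files: an actions file with header
``time<TAB>group<TAB>action<TAB>target`` (time in decimal years) and an
optional companion metrics file with header ``time<TAB>metric<TAB>value``.
Multiple postings at one time point are allowed.  Dialect version 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .influence import SimulatorSpec, SimulationRecord, simulate
from .parameters import ParameterVector

DIALECT_VERSION = 1

#: Group codes of the East-African cheetah case organism: per-country
#: presidential offices, environmental protection agencies, rural residents
#: and pastoralists, plus the NGO bloc and the ecosystem itself.
DEFAULT_GROUP_CODES = (
    "kpr", "kep", "krr", "kpa",
    "tpr", "tep", "trr", "tpa",
    "upr", "uep", "urr", "upa",
    "ngo", "ecosys",
)

ACTIONS_COLUMNS = ("time", "group", "action", "target")
METRICS_COLUMNS = ("time", "metric", "value")


class ActionsFormatError(ValueError):
    pass


@dataclass
class ActionsDataset:
    """Observed out-combinations over a time grid plus continuous
    ecosystem-metric series."""

    records: pd.DataFrame
    metrics: pd.DataFrame = None
    group_codes: tuple = DEFAULT_GROUP_CODES

    def __post_init__(self):
        rec = pd.DataFrame(self.records, columns=list(ACTIONS_COLUMNS)).copy()
        rec["time"] = rec["time"].astype(float)
        for c in ("group", "action", "target"):
            rec[c] = rec[c].astype(str)
        self.records = rec.reset_index(drop=True)
        if self.metrics is None:
            self.metrics = pd.DataFrame(columns=list(METRICS_COLUMNS))
        met = pd.DataFrame(self.metrics, columns=list(METRICS_COLUMNS)).copy()
        met["time"] = met["time"].astype(float)
        met["metric"] = met["metric"].astype(str)
        met["value"] = met["value"].astype(float)
        self.metrics = met.reset_index(drop=True)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        t = self.records["time"].to_numpy()
        if len(t) and np.any(np.diff(t) < 0):
            raise ActionsFormatError("record times must be nondecreasing")
        bad = ~self.records["group"].isin(self.group_codes)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ActionsFormatError(
                f"record {i}: unknown group code {self.records['group'].iloc[i]!r}"
            )

    # -- derived quantities ------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def observation_times(self) -> np.ndarray:
        return np.unique(self.records["time"].to_numpy())

    @property
    def T(self) -> int:
        """Number of time points at which out-combinations are observed."""
        return len(self.observation_times)

    @property
    def T_D(self) -> float:
        """The most recent time point in the data set."""
        times = [self.records["time"].max()] if len(self.records) else []
        if len(self.metrics):
            times.append(self.metrics["time"].max())
        if not times:
            raise ValueError("empty dataset has no T_D")
        return float(max(times))

    def observed_groups(self) -> tuple:
        """The ``m_O`` set: groups with at least one observed out-combination."""
        return tuple(sorted(self.records["group"].unique()))

    def metric_series(self, name: str) -> pd.DataFrame:
        out = self.metrics[self.metrics["metric"] == name]
        return out.sort_values("time").reset_index(drop=True)

    def metric_names(self) -> tuple:
        return tuple(sorted(self.metrics["metric"].unique()))

    def restrict_through(self, t: float) -> "ActionsDataset":
        """Records and metric rows observed up through time ``t``."""
        return ActionsDataset(
            self.records[self.records["time"] <= t + 1e-9],
            self.metrics[self.metrics["time"] <= t + 1e-9],
            self.group_codes,
        )

    def take_records(self, idx) -> "ActionsDataset":
        """Subset by record positions (jackknife subsampling); metric series
        are kept whole."""
        sub = self.records.iloc[sorted(idx)]
        return ActionsDataset(sub, self.metrics, self.group_codes)

    def equals(self, other: "ActionsDataset") -> bool:
        a, b = self.records, other.records
        if len(a) != len(b) or len(self.metrics) != len(other.metrics):
            return False
        if not np.allclose(a["time"], b["time"], atol=1e-9):
            return False
        for c in ("group", "action", "target"):
            if not (a[c].to_numpy() == b[c].to_numpy()).all():
                return False
        ma, mb = self.metrics, other.metrics
        if len(ma):
            if not np.allclose(ma["time"], mb["time"], atol=1e-9):
                return False
            if not (ma["metric"].to_numpy() == mb["metric"].to_numpy()).all():
                return False
            if not np.allclose(ma["value"], mb["value"], rtol=1e-12, atol=1e-12):
                return False
        return True


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # repr of a float is the shortest string that round-trips exactly
    return repr(float(x))


def read_actions(path, metrics_path=None, group_codes=DEFAULT_GROUP_CODES) -> ActionsDataset:
    """Read an actions history (and optional metrics file); malformed rows
    are reported with their line numbers."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ActionsFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if tuple(header) != ACTIONS_COLUMNS:
        raise ActionsFormatError(
            f"{path}:1: bad header {header!r}; expected {list(ACTIONS_COLUMNS)}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ActionsFormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
        try:
            t = float(parts[0])
        except ValueError:
            raise ActionsFormatError(f"{path}:{lineno}: bad time value {parts[0]!r}") from None
        if group_codes is not None and parts[1] not in group_codes:
            raise ActionsFormatError(f"{path}:{lineno}: unknown group code {parts[1]!r}")
        rows.append((t, parts[1], parts[2], parts[3]))
    if not rows:
        raise ActionsFormatError(f"{path}: no data rows")
    metrics = None
    if metrics_path is not None:
        metrics = _read_metrics(metrics_path)
    codes = tuple(group_codes) if group_codes is not None else tuple(sorted({r[1] for r in rows}))
    return ActionsDataset(pd.DataFrame(rows, columns=list(ACTIONS_COLUMNS)), metrics, codes)


def _read_metrics(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ActionsFormatError(f"{path}: empty file")
    if tuple(lines[0].split("\t")) != METRICS_COLUMNS:
        raise ActionsFormatError(f"{path}:1: bad metrics header")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ActionsFormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
        try:
            rows.append((float(parts[0]), parts[1], float(parts[2])))
        except ValueError:
            raise ActionsFormatError(f"{path}:{lineno}: bad numeric value") from None
    return pd.DataFrame(rows, columns=list(METRICS_COLUMNS))


def write_actions(ds: ActionsDataset, path, metrics_path=None) -> None:
    """Write a dataset in the tab-separated dialect; ``read_actions`` of the
    result reproduces the dataset field for field."""
    ds.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ACTIONS_COLUMNS) + "\n")
        for row in ds.records.itertuples(index=False):
            fh.write(f"{_fmt(row.time)}\t{row.group}\t{row.action}\t{row.target}\n")
    if metrics_path is not None:
        with open(metrics_path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(METRICS_COLUMNS) + "\n")
            for row in ds.metrics.itertuples(index=False):
                fh.write(f"{_fmt(row.time)}\t{row.metric}\t{_fmt(row.value)}\n")


# ---------------------------------------------------------------------------
# Synthetic histories
# ---------------------------------------------------------------------------

@dataclass
class SyntheticHistory:
    """An "observed" dataset generated from a simulator with known true
    parameters, kept alongside for recovery tests."""

    dataset: ActionsDataset
    b_true: ParameterVector
    simulation: SimulationRecord


def generate_synthetic_history(
    spec: SimulatorSpec,
    B_true: ParameterVector,
    time_grid,
    seed: int = 0,
    decision_mc: int = 1,
    mc_reals: int = 200,
) -> SyntheticHistory:
    """Run the simulator at ``B_true`` and emit its postings and metric means
    as an observed-actions dataset.

    ``decision_mc`` defaults to a single Monte-Carlo realization per
    decision: with common random numbers across the menu this makes each
    posted action a draw from the group's choice distribution, giving the
    behavioural variability real histories show.
    """
    rec = simulate(spec, B_true, time_grid, mc_reals=mc_reals, seed=seed,
                   decision_mc=decision_mc)
    records = rec.postings_frame()
    metric_rows = [
        (float(t), m, float(rec.metric_means[i, j]))
        for i, t in enumerate(rec.times)
        for j, m in enumerate(rec.metric_names)
    ]
    metrics = pd.DataFrame(metric_rows, columns=list(METRICS_COLUMNS))
    codes = tuple(g.id for g in spec.groups)
    if spec.ecosystem is not None:
        codes = codes + (spec.ecosystem.id,)
    ds = ActionsDataset(records, metrics, codes)
    return SyntheticHistory(ds, B_true.copy(), rec)
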