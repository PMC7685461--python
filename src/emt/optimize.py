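"""Multiple-dimensions-ahead search (MDAS).

A batch-synchronous, derivative-free coordinate pattern search in the
Hooke–Jeeves family, for (possibly stochastic) objectives under box bounds
and an optional feasibility predicate.  The search walks the dimensions in
blocks of ``M``: for the current block it proposes +/- step moves along each
block dimension, evaluates the whole batch (through the task executor, so
workers can run in parallel), and accepts the best strict improvement.  A
block is searched repeatedly until it yields no improvement, then the search
moves to the next block; when a full pass over all blocks yields no
improvement the steps shrink globally.  Termination: all steps below the
convergence tolerance, or the evaluation budget is exhausted.

Because batches are synchronous and the best improvement is selected in a
documented deterministic order, the result is identical under the serial and
process-pool executors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .taskrun import SerialExecutor


@dataclass
class SearchSpec:
    """Configuration of one MDAS run.

    ``tol`` and ``steps`` may be scalars (interpreted as fractions of each
    bound range) or per-dimension arrays of absolute sizes.
    """

    bounds: np.ndarray  # (k, 2)
    start: np.ndarray
    steps: object = 0.1  # initial step: fraction of range (scalar) or array
    dims_ahead: int = 3  # M
    shrink: float = 0.5
    tol: object = 1e-6  # convergence: fraction of range (scalar) or array
    max_evals: int = 100000
    feasibility: object = None  # point -> bool, or None
    seed: int = 0
    checkpoint_path: object = None

    def __post_init__(self):
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(-1, 2)
        self.start = np.asarray(self.start, dtype=float)
        k = len(self.start)
        if self.bounds.shape != (k, 2):
            raise ValueError("bounds/start dimension mismatch")
        if np.any(self.start < self.bounds[:, 0] - 1e-12) or np.any(
            self.start > self.bounds[:, 1] + 1e-12
        ):
            raise ValueError("start point outside bounds")
        if self.dims_ahead < 1:
            raise ValueError("dims_ahead (M) must be >= 1")
        if not (0.0 < self.shrink < 1.0):
            raise ValueError("shrink factor must lie in (0, 1)")
        rng = self.bounds[:, 1] - self.bounds[:, 0]
        # unbounded dimensions: scale steps by the start magnitude instead
        ref = np.where(np.isfinite(rng), rng, np.maximum(1.0, np.abs(self.start)))
        self.steps = (
            np.full(k, float(self.steps)) * ref
            if np.isscalar(self.steps)
            else np.asarray(self.steps, dtype=float).copy()
        )
        self.tol = (
            np.full(k, float(self.tol)) * ref
            if np.isscalar(self.tol)
            else np.asarray(self.tol, dtype=float).copy()
        )
        if np.any(self.tol <= 0):
            raise ValueError("convergence tolerance must be positive")


@dataclass
class OptimResult:
    x: np.ndarray
    fun: float
    nfev: int
    trace: list = field(default_factory=list)  # (eval index, point, value) improvements
    termination: str = ""

    def __post_init__(self):
        if self.trace and self.fun < max(v for _, _, v in self.trace) - 1e-15:
            raise ValueError("best value below an improvement in the trace")


def propose_batch(point: np.ndarray, block, steps: np.ndarray, bounds: np.ndarray) -> list:
    """Axial +/- step trial points for the block's dimensions, clipped to the
    bounds, in documented order (+d0, -d0, +d1, -d1, ...), with duplicates
    (including clip-induced copies of the incumbent) removed."""
    if len(block) == 0:
        raise ValueError("empty dimension block")
    out = []
    seen = {tuple(point)}
    for d in block:
        for sign in (+1.0, -1.0):
            trial = point.copy()
            trial[d] = np.clip(trial[d] + sign * steps[d], bounds[d, 0], bounds[d, 1])
            key = tuple(trial)
            if key not in seen:
                seen.add(key)
                out.append(trial)
    return out


def mdas_maximize(objective, spec: SearchSpec, executor=None) -> OptimResult:
    """Maximize ``objective`` with MDAS.  Never returns an infeasible or
    out-of-bounds point; the incumbent value is nondecreasing over the
    improvement trace."""
    executor = executor or SerialExecutor()
    if spec.feasibility is not None and not spec.feasibility(spec.start):
        raise ValueError("infeasible start point")
    x = spec.start.copy()
    fx = float(objective(x))
    if not np.isfinite(fx):
        raise ValueError("objective is non-finite at the start point")
    nfev = 1
    trace = [(nfev, x.copy(), fx)]
    _checkpoint(spec, nfev, x, fx)
    steps = spec.steps.copy()
    k = len(x)
    blocks = [list(range(i, min(i + spec.dims_ahead, k))) for i in range(0, k, spec.dims_ahead)]
    termination = "max_evals"
    while nfev < spec.max_evals:
        improved_pass = False
        for block in blocks:
            while nfev < spec.max_evals:
                proposals = propose_batch(x, block, steps, spec.bounds)
                if spec.feasibility is not None:
                    proposals = [p for p in proposals if spec.feasibility(p)]
                if not proposals:
                    break
                proposals = proposals[: spec.max_evals - nfev]
                values = executor.map(objective, proposals)
                nfev += len(proposals)
                best_i = None
                best_v = fx
                for i, v in enumerate(values):
                    v = float(v)
                    if np.isfinite(v) and v > best_v:  # strict: first-in-order tie-break
                        best_i, best_v = i, v
                if best_i is None:
                    break
                x = proposals[best_i].copy()
                fx = best_v
                trace.append((nfev, x.copy(), fx))
                _checkpoint(spec, nfev, x, fx)
                improved_pass = True
        if not improved_pass:
            steps *= spec.shrink
            if np.all(steps < spec.tol):
                termination = "converged"
                break
    return OptimResult(x=x, fun=fx, nfev=nfev, trace=trace, termination=termination)


def _checkpoint(spec: SearchSpec, nfev: int, x: np.ndarray, fx: float) -> None:
    if spec.checkpoint_path is None:
        return
    with open(spec.checkpoint_path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps({"nfev": nfev, "x": list(map(float, x)), "value": fx}) + "\n")


def resume_incumbent(checkpoint_path) -> tuple | None:
    """Best (point, value) recorded in an MDAS checkpoint file, or None."""
    best = None
    try:
        with open(checkpoint_path, "r", encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                if best is None or rec["value"] > best[1]:
                    best = (np.array(rec["x"]), float(rec["value"]))
    except FileNotFoundError:
        return None
    return best


def bukin_f4(x: float, y: float) -> float:
    """The Bukin F4 benchmark, 100 y^2 + 0.01 |x + 10|; global minimum 0 at
    (-10, 0) on x in [-15, -5], y in [-3, 3]."""
    return 100.0 * y * y + 0.01 * abs(x + 10.0)


def minimize_bukin_f4(executor=None, max_evals: int = 20000) -> OptimResult:
    """Minimize Bukin F4 (via negation) from the standard start (-6, 2) under
    the default MDAS settings.  Returns the result with ``fun`` negated back
    to the minimization scale."""
    spec = SearchSpec(
        bounds=np.array([[-15.0, -5.0], [-3.0, 3.0]]),
        start=np.array([-6.0, 2.0]),
        max_evals=max_evals,
    )
    res = mdas_maximize(lambda p: -bukin_f4(p[0], p[1]), spec, executor=executor)
    res.fun = -res.fun
    res.trace = [(i, p, -v) for i, p, v in res.trace]
    return res
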