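"""Bag-of-tasks master–worker execution.

Each statistical job decomposes into batches of pure, loosely coupled tasks
(objective evaluations, jackknife replicates, rolling refits).  The master
posts a batch, waits until every task in it has completed, and only then
posts the next batch.  Two backends implement the worker side: a serial
in-process loop and a local process pool; both return identical results for
pure tasks, so any job can be developed serially and scaled out unchanged.

Fault tolerance: tasks are retried up to a limit, and completed task results
are appended to a checkpoint file so a rerun of an interrupted batch skips
finished tasks and reproduces the same final result map.
"""

from __future__ import annotations

import base64
import hashlib
import logging
import pickle
import warnings
from concurrent.futures import ProcessPoolExecutor as _PoolExecutor
from dataclasses import dataclass

import json

logger = logging.getLogger(__name__)

_REGISTRY: dict = {}


def register_task(func, name: str | None = None):
    """Register a pure function so batches (and worker processes) can
    reference it by name."""
    name = name or f"{func.__module__}.{func.__qualname__}"
    _REGISTRY[name] = func
    return func


def task(name: str | None = None):
    """Decorator form of :func:`register_task`."""

    def wrap(func):
        register_task(func, name)
        return func

    return wrap


def _resolve(name: str):
    if name in _REGISTRY:
        return _REGISTRY[name]
    # registered-by-default: importable module-level callables
    mod, _, attr = name.rpartition(".")
    if mod:
        import importlib

        try:
            func = getattr(importlib.import_module(mod), attr)
            _REGISTRY[name] = func
            return func
        except (ImportError, AttributeError):
            pass
    raise KeyError(f"task function {name!r} is not registered")


@dataclass(frozen=True)
class Task:
    id: str
    func: str  # registered name
    args: tuple = ()
    kwargs: tuple = ()  # ((key, value), ...)


@dataclass
class TaskBatch:
    tasks: list
    retry_limit: int = 3
    checkpoint_path: object = None

    def __post_init__(self):
        ids = [t.id for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise ValueError("task ids must be unique within a batch")


class TaskError(RuntimeError):
    pass


def _run_task(name: str, args: tuple, kwargs: tuple):
    return _resolve(name)(*args, **dict(kwargs))


# ---------------------------------------------------------------------------
# Executors
# ---------------------------------------------------------------------------

class SerialExecutor:
    """In-process, ordered execution (the reference backend)."""

    backend = "serial"

    def map(self, func, items) -> list:
        return [func(it) for it in items]

    def run_tasks(self, tasks, retry_limit: int) -> dict:
        out = {}
        for t in tasks:
            out[t.id] = _attempt(lambda t=t: _run_task(t.func, t.args, t.kwargs),
                                  t.id, retry_limit)
        return out


class ProcessPoolBackend:
    """Local process-pool workers (bag-of-tasks master on this process)."""

    backend = "process"

    def __init__(self, workers: int = 2):
        self.workers = int(workers)

    def map(self, func, items) -> list:
        with _PoolExecutor(max_workers=self.workers) as pool:
            return list(pool.map(func, items))

    def run_tasks(self, tasks, retry_limit: int) -> dict:
        out = {}
        with _PoolExecutor(max_workers=self.workers) as pool:
            futures = {t.id: pool.submit(_run_task, t.func, t.args, t.kwargs) for t in tasks}
            retry = []
            for t in tasks:
                try:
                    out[t.id] = futures[t.id].result()
                except Exception as e:  # noqa: BLE001 - retried below
                    logger.warning("task %s failed (%s); retrying", t.id, e)
                    retry.append(t)
        for t in retry:
            out[t.id] = _attempt(lambda t=t: _run_task(t.func, t.args, t.kwargs),
                                  t.id, retry_limit - 1)
        return out


def _attempt(thunk, task_id: str, retry_limit: int):
    err = None
    for attempt in range(max(retry_limit, 1)):
        try:
            return thunk()
        except Exception as e:  # noqa: BLE001 - bounded retries
            err = e
            logger.warning("task %s attempt %d failed: %s", task_id, attempt + 1, e)
    raise TaskError(f"task {task_id!r} exhausted its retries") from err


def get_executor(backend: str = "serial", workers: int = 2):
    if backend == "serial":
        return SerialExecutor()
    if backend == "process":
        return ProcessPoolBackend(workers)
    raise ValueError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# Batch driver with checkpointing
# ---------------------------------------------------------------------------

def _encode(result) -> dict:
    blob = pickle.dumps(result, protocol=4)
    return {
        "digest": hashlib.sha256(blob).hexdigest(),
        "blob": base64.b64encode(blob).decode("ascii"),
    }


def _decode(rec: dict):
    return pickle.loads(base64.b64decode(rec["blob"]))


def _load_checkpoint(path) -> dict:
    done = {}
    try:
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rec = json.loads(line)
                    done[rec["task_id"]] = _decode(rec)
    except FileNotFoundError:
        pass
    return done


def run_batch(
    batch: TaskBatch,
    backend: str = "serial",
    workers: int = 2,
    verify_purity: bool = False,
) -> dict:
    """Execute every task of the batch, returning a map task id -> result.

    Completed results are checkpointed (append-only) so rerunning an
    interrupted batch skips finished tasks.  With ``verify_purity`` each
    task runs twice and differing results raise a warning.
    """
    executor = backend if hasattr(backend, "run_tasks") else get_executor(backend, workers)
    done = _load_checkpoint(batch.checkpoint_path) if batch.checkpoint_path else {}
    pending = [t for t in batch.tasks if t.id not in done]
    results = dict(done)
    if pending:
        fresh = executor.run_tasks(pending, batch.retry_limit)
        if verify_purity:
            again = executor.run_tasks(pending, batch.retry_limit)
            for t in pending:
                if _encode(fresh[t.id])["digest"] != _encode(again[t.id])["digest"]:
                    warnings.warn(
                        f"task {t.id!r} returned differing results on identical reruns "
                        "(non-pure task?)",
                        stacklevel=2,
                    )
        if batch.checkpoint_path:
            with open(batch.checkpoint_path, "a", encoding="utf-8") as fh:
                for t in pending:
                    rec = {"task_id": t.id, **_encode(fresh[t.id])}
                    fh.write(json.dumps(rec) + "\n")
        results.update(fresh)
    return {t.id: results[t.id] for t in batch.tasks}
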