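"""Hellinger distance between influence-diagram distributions.

The distance between two parameterizations of an ID is estimated by Monte
Carlo: draw design points uniformly over the ID's chance nodes, estimate the
mixed discrete/continuous joint density (the "probability density probability
function", PDPF) of each distribution at those points with a product kernel
(exact frequency match on discrete coordinates, Gaussian kernel with
Silverman bandwidth on continuous ones), and form

    Dhat^2 = (1/2) sum_j w_j (sqrt(f1(u_j)) - sqrt(f2(u_j)))^2,

with importance weights w_j = 1/(n q(u_j)) for the uniform sampling density
q, so the sum is a consistent estimate of the Hellinger integral and the
result stays in [0, 1].  For purely discrete IDs the joint can be enumerated
exactly and the distance computed as a finite sum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .influence import SubmodelSpec, sample_nodes
from .parameters import ParameterVector, assert_same_structure

logger = logging.getLogger(__name__)

MIN_BANDWIDTH = 1e-6


@dataclass
class DesignSample:
    """Uniform design points over an ID's chance nodes.

    ``columns`` maps node name -> array of n coordinate values; ``q`` is the
    (constant) uniform sampling density over the product of the declared
    node domains/ranges.
    """

    columns: dict
    kinds: dict  # node name -> "discrete" | "continuous"
    q: float
    seed: int

    @property
    def n(self) -> int:
        return len(next(iter(self.columns.values())))

    def matches(self, other: "DesignSample") -> bool:
        if self.kinds != other.kinds or self.n != other.n:
            return False
        for k, col in self.columns.items():
            oc = other.columns[k]
            if col.dtype.kind == "f":
                if not np.array_equal(col, oc):
                    return False
            elif not all(a == b for a, b in zip(col, oc)):
                return False
        return True


@dataclass
class PdpfEstimate:
    """Nonparametric PDPF values at design points."""

    values: np.ndarray
    design: DesignSample
    bandwidths: dict
    n_draws: int

    def __post_init__(self):
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("PDPF estimates must be finite and nonnegative")


def draw_design_points(spec: SubmodelSpec, n: int, seed: int = 0) -> DesignSample:
    """Draw ``n`` design points uniformly over the ID's chance nodes:
    discrete coordinates uniform over their domains, continuous ones uniform
    over their declared ranges."""
    if n < 1:
        raise ValueError("need at least one design point")
    rng = np.random.default_rng(seed)
    columns: dict = {}
    kinds: dict = {}
    q = 1.0
    for node in spec.pdpf_nodes():
        if node.kind == "discrete":
            dom = tuple(node.domain)
            columns[node.name] = rng.choice(np.array(dom, dtype=object), size=n)
            kinds[node.name] = "discrete"
            q /= len(dom)
        else:
            if not node.range or len(node.range) != 2:
                raise ValueError(
                    f"continuous node {node.name!r} has no declared finite range"
                )
            lo, hi = map(float, node.range)
            if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
                raise ValueError(f"continuous node {node.name!r}: invalid range {node.range}")
            columns[node.name] = rng.uniform(lo, hi, size=n)
            kinds[node.name] = "continuous"
            q /= hi - lo
    if not columns:
        raise ValueError(f"submodel {spec.id!r} has no chance nodes")
    return DesignSample(columns, kinds, q, int(seed))


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth; falls back to a declared minimum
    for (near) zero-variance draws."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        logger.warning("zero-variance continuous coordinate; using minimum bandwidth")
        return MIN_BANDWIDTH
    return 1.06 * spread * len(x) ** (-0.2)


def estimate_pdpf(model_draws: dict, design: DesignSample, chunk: int = 512) -> PdpfEstimate:
    """Product-kernel PDPF estimate at the design points.

    ``model_draws`` maps node name -> array of N sampled values.  Discrete
    coordinates contribute exact frequency-match indicators; continuous
    coordinates a Gaussian kernel with Silverman bandwidth.
    """
    names = list(design.columns)
    if not names:
        raise ValueError("empty design sample")
    n_draws = len(np.asarray(model_draws[names[0]]))
    if n_draws == 0:
        raise ValueError("model_draws is empty")
    n = design.n
    bandwidths = {}
    values = np.zeros(n)
    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        weight = np.ones((sl.stop - sl.start, n_draws))
        for name in names:
            draws = np.asarray(model_draws[name])
            pts = design.columns[name][sl]
            if design.kinds[name] == "discrete":
                weight *= pts[:, None] == draws[None, :]
            else:
                if name not in bandwidths:
                    bandwidths[name] = max(silverman_bandwidth(draws), MIN_BANDWIDTH)
                h = bandwidths[name]
                z = (pts[:, None].astype(float) - draws[None, :].astype(float)) / h
                weight *= inv_sqrt2pi * np.exp(-0.5 * z * z) / h
        values[sl] = weight.mean(axis=1)
    return PdpfEstimate(values, design, bandwidths, n_draws)


def hellinger(pf1: PdpfEstimate, pf2: PdpfEstimate) -> float:
    """Estimated Hellinger distance between two PDPFs sharing one design
    sample.  Clamped into [0, 1] (Monte-Carlo noise can push the raw value
    marginally outside; clamping is logged)."""
    if pf1.design is not pf2.design and not pf1.design.matches(pf2.design):
        raise ValueError("PDPF estimates use different design samples")
    design = pf1.design
    # uniform sampling density => constant importance weight 1/(n q)
    sq = (np.sqrt(pf1.values) - np.sqrt(pf2.values)) ** 2
    d2 = 0.5 * float(np.sum(sq)) / (design.n * design.q)
    if d2 > 1.0:
        logger.info("Hellinger^2 estimate %.4f > 1; clamping", d2)
        d2 = 1.0
    return float(np.sqrt(max(d2, 0.0)))


# ---------------------------------------------------------------------------
# Exact mode for purely discrete IDs
# ---------------------------------------------------------------------------

def is_discrete_exact(spec: SubmodelSpec) -> bool:
    return all(n.kind == "discrete" for n in spec.pdpf_nodes())


def exact_pdpf(spec: SubmodelSpec, B: ParameterVector, conditioning: dict) -> dict:
    """Exact joint probabilities of a purely discrete ID's chance nodes under
    one conditioning combination: maps value tuples -> probability."""
    nodes = spec.pdpf_nodes()
    if not is_discrete_exact(spec):
        raise ValueError(f"submodel {spec.id!r} has continuous chance nodes")
    from .parameters import ParamKey

    names = [n.name for n in nodes]
    out = {}
    for combo in itertools.product(*[n.domain for n in nodes]):
        assignment = dict(zip(names, combo))
        assignment.update(conditioning)
        p = 1.0
        for node in nodes:
            context = tuple((par, assignment[par]) for par in node.parents)
            p *= B.get(ParamKey(spec.id, context, f"p({node.name}={assignment[node.name]})"))
        out[combo] = p
    return out


def hellinger_exact(p1: dict, p2: dict) -> float:
    """Hellinger distance between two finite distributions given as
    support -> probability maps (finite-sum closed form)."""
    support = set(p1) | set(p2)
    d2 = 0.5 * sum(
        (np.sqrt(p1.get(s, 0.0)) - np.sqrt(p2.get(s, 0.0))) ** 2 for s in support
    )
    return float(np.sqrt(min(max(d2, 0.0), 1.0)))


def submodel_draws(
    spec: SubmodelSpec,
    B: ParameterVector,
    conditioning: dict,
    n_draws: int,
    seed: int = 0,
) -> dict:
    """Sample the ID's chance nodes ``n_draws`` times under one conditioning
    combination (for PDPF estimation)."""
    rng = np.random.default_rng(seed)
    uniforms = rng.random((int(n_draws), len(spec.topo_nodes)))
    vals = sample_nodes(spec, B, conditioning, uniforms)
    return {n.name: vals[n.name] for n in spec.pdpf_nodes()}


# ---------------------------------------------------------------------------
# Euclidean surrogate
# ---------------------------------------------------------------------------

def euclidean_agreement(B: ParameterVector, B_H: ParameterVector, block: str = "all") -> float:
    """The smooth surrogate used inside optimization loops: the negative of
    the Euclidean distance between the active parameters of ``block`` at
    their hypothesis values and at the trial point.  Zero iff equal."""
    assert_same_structure(B, B_H)
    mask = B.block_mask(block) & B.active
    diff = B.values[mask] - B_H.values[mask]
    return -float(np.linalg.norm(diff))
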