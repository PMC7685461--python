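"""On-disk model specifications.

A simulator is stored as a directory of YAML documents: one per submodel
(structure plus its hypothesis parameter values — the "hypothesis parameter
file") and one ``master.yaml`` wiring the submodels together.  Schema
version 1; see the repository documentation for the field-by-field layout.
"""

from __future__ import annotations

import os

import yaml

from .influence import (
    ChanceNodeSpec,
    EcoBinding,
    InputNodeSpec,
    OutCombination,
    SimulatorSpec,
    SubmodelSpec,
    build_parameter_vector,
)
from .parameters import ParamKey, ParameterVector

SCHEMA_VERSION = 1


def _node_to_dict(node: ChanceNodeSpec) -> dict:
    out = {"name": node.name, "kind": node.kind}
    if node.parents:
        out["parents"] = list(node.parents)
    if node.domain:
        out["domain"] = list(node.domain)
    if node.range:
        out["range"] = [float(node.range[0]), float(node.range[1])]
    if node.table:
        out["table"] = [[list(k), float(v)] for k, v in node.table]
    return out


def _node_from_dict(d: dict) -> ChanceNodeSpec:
    return ChanceNodeSpec(
        name=d["name"],
        kind=d["kind"],
        parents=tuple(d.get("parents", ())),
        domain=tuple(d.get("domain", ())),
        range=tuple(d.get("range", ())),
        table=tuple((tuple(k), v) for k, v in d.get("table", ())),
    )


def _input_to_dict(node: InputNodeSpec) -> dict:
    out = {"name": node.name, "kind": node.kind}
    if node.domain:
        out["domain"] = list(node.domain)
    if node.discretization:
        out["discretization"] = [float(x) for x in node.discretization]
    return out


def submodel_to_dict(spec: SubmodelSpec, B: ParameterVector | None = None) -> dict:
    out = {
        "schema": SCHEMA_VERSION,
        "id": spec.id,
        "role": spec.role,
        "input_nodes": [_input_to_dict(n) for n in spec.input_nodes],
        "nodes": [_node_to_dict(n) for n in spec.nodes],
    }
    if spec.menu:
        out["menu"] = [[m.output_action, m.target] for m in spec.menu]
    if spec.value_node:
        out["value_node"] = spec.value_node
    if spec.choice_node:
        out["choice_node"] = spec.choice_node
    if spec.output_metrics:
        out["output_metrics"] = list(spec.output_metrics)
    if B is not None:
        out["parameters"] = _parameters_to_dict(spec, B)
    return out


def _parameters_to_dict(spec: SubmodelSpec, B: ParameterVector) -> dict:
    params: dict = {}
    for node in spec.nodes:
        if node.kind == "discrete":
            rows = []
            for context in spec.cpt_contexts(node):
                probs = [
                    B.get(ParamKey(spec.id, context, f"p({node.name}={v})"))
                    for v in node.domain
                ]
                rows.append({"context": [[p, v] for p, v in context], "probs": probs})
            params[node.name] = {"rows": rows}
        elif node.kind == "continuous":
            params[node.name] = {
                "b0": B.get(ParamKey(spec.id, (), f"{node.name}.b0")),
                "b": {
                    p: B.get(ParamKey(spec.id, (), f"{node.name}.b[{p}]"))
                    for p in node.parents
                },
                "scale": B.get(ParamKey(spec.id, (), f"{node.name}.scale")),
            }
    return params


def submodel_from_dict(d: dict) -> tuple:
    """Returns ``(SubmodelSpec, hypothesis dict or None)``."""
    spec = SubmodelSpec(
        id=d["id"],
        role=d["role"],
        input_nodes=tuple(
            InputNodeSpec(
                name=n["name"], kind=n.get("kind", "discrete"),
                domain=tuple(n.get("domain", ())),
                discretization=tuple(n.get("discretization", ())),
            )
            for n in d.get("input_nodes", ())
        ),
        nodes=tuple(_node_from_dict(n) for n in d.get("nodes", ())),
        menu=tuple(OutCombination(a, t) for a, t in d.get("menu", ())),
        value_node=d.get("value_node", ""),
        choice_node=d.get("choice_node", ""),
        output_metrics=tuple(d.get("output_metrics", ())),
    )
    hypothesis = None
    if "parameters" in d:
        hypothesis = {}
        for node in spec.nodes:
            if node.kind == "discrete":
                rows = d["parameters"][node.name]["rows"]
                if len(rows) == 1 and not rows[0]["context"]:
                    hypothesis[node.name] = tuple(rows[0]["probs"])
                else:
                    hypothesis[node.name] = {
                        tuple(v for _, v in row["context"]): tuple(row["probs"])
                        for row in rows
                    }
            elif node.kind == "continuous":
                p = d["parameters"][node.name]
                hypothesis[node.name] = {
                    "b0": float(p["b0"]),
                    "b": {k: float(v) for k, v in p.get("b", {}).items()},
                    "scale": float(p["scale"]),
                }
            else:
                hypothesis[node.name] = None
    return spec, hypothesis


def save_simulator(spec: SimulatorSpec, B: ParameterVector, dirpath) -> None:
    """Write one YAML document per submodel plus the master file."""
    os.makedirs(dirpath, exist_ok=True)
    files = []
    for sub in spec.submodels:
        fname = f"{sub.id}.yaml"
        files.append(fname)
        with open(os.path.join(dirpath, fname), "w", encoding="utf-8") as fh:
            yaml.safe_dump(submodel_to_dict(sub, B), fh, sort_keys=False)
    master = {
        "schema": SCHEMA_VERSION,
        "submodels": files,
        "ecosystem": spec.ecosystem.id if spec.ecosystem is not None else None,
        "routes": [[s, r] for s, r in spec.routes],
        "eco_bindings": [
            {"node": b.node, "kind": b.kind, "ref": b.ref} for b in spec.eco_bindings
        ],
        "metric_init": {m: float(v) for m, v in spec.metric_init},
    }
    with open(os.path.join(dirpath, "master.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(master, fh, sort_keys=False)


def load_simulator(dirpath) -> tuple:
    """Read a simulator directory back into ``(SimulatorSpec, B_H)``."""
    with open(os.path.join(dirpath, "master.yaml"), "r", encoding="utf-8") as fh:
        master = yaml.safe_load(fh)
    if master.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {master.get('schema')!r}")
    groups = []
    ecosystem = None
    hypothesis = {}
    for fname in master["submodels"]:
        with open(os.path.join(dirpath, fname), "r", encoding="utf-8") as fh:
            sub, hyp = submodel_from_dict(yaml.safe_load(fh))
        if hyp is None:
            raise ValueError(f"{fname}: submodel document lacks hypothesis parameters")
        hypothesis[sub.id] = hyp
        if sub.id == master.get("ecosystem") or (
            master.get("ecosystem") is None and sub.role == "ecosystem"
        ):
            ecosystem = sub
        else:
            groups.append(sub)
    spec = SimulatorSpec(
        groups=tuple(groups),
        ecosystem=ecosystem,
        routes=tuple((s, r) for s, r in master.get("routes", ())),
        eco_bindings=tuple(
            EcoBinding(b["node"], b["kind"], b["ref"])
            for b in master.get("eco_bindings", ())
        ),
        metric_init=tuple(master.get("metric_init", {}).items()),
    )
    return spec, build_parameter_vector(spec.submodels, hypothesis)
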