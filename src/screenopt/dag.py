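"""Multiplex DAG turning input files plus config into candidate parameterizations.

Docking engines are configured by a set of "dockfiles" derived from a
receptor structure, a ligand structure and a config.  The derivation is
modeled as a directed acyclic graph whose root nodes are the input files,
whose intermediate nodes are derived files, and whose leaf nodes are the
final dockfiles.  An edge is a dependency: a step consumes its input nodes
and produces its output nodes, and a child node can be materialized only
once every parent exists.  A step may declare a *variation* — one
parameter with a pool of values — which fans the graph out; the Cartesian
product of all variation pools enumerates every candidate
parameterization.

The graph structure, node hashes and parameterization ids are pure
functions of the config and root-file contents, so identical inputs always
rebuild the identical DAG.  The step *transforms* registered here are toy
file-stamping functions (the real receptor-preparation chemistry is a
different program's job); the graph contract — ordering, fan-out,
content-hash idempotence, per-branch failure isolation — is the part the
pipeline depends on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "FileNode",
    "DagStep",
    "Parameterization",
    "DAG",
    "build_dag",
    "enumerate_parameterizations",
    "execute_dag",
    "parameterization_id",
]


def _stable_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def parameterization_id(bindings: dict, sphere_provenance: str = "base") -> str:
    """Deterministic id from canonically ordered bindings plus sphere lineage."""
    return _stable_hash({"bindings": {k: bindings[k] for k in sorted(bindings)},
                         "spheres": sphere_provenance})[:16]


@dataclass(frozen=True)
class Parameterization:
    """One complete assignment of searchable parameters plus a sphere set."""

    bindings: dict
    sphere_set: object | None = None  # SphereSet or None
    lineage: tuple = ()

    @property
    def sphere_provenance(self) -> str:
        return self.sphere_set.provenance if self.sphere_set is not None else "base"

    @property
    def id(self) -> str:
        return parameterization_id(self.bindings, self.sphere_provenance)

    def with_spheres(self, sphere_set) -> "Parameterization":
        return Parameterization(bindings=self.bindings, sphere_set=sphere_set,
                                lineage=self.lineage)

    def with_bindings(self, **updates) -> "Parameterization":
        return Parameterization(bindings={**self.bindings, **updates},
                                sphere_set=self.sphere_set, lineage=self.lineage)


@dataclass(frozen=True)
class FileNode:
    name: str
    kind: str  # root | intermediate | leaf
    param_bindings: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DagStep:
    """A named transform consuming input nodes and producing output nodes."""

    name: str
    inputs: frozenset
    outputs: frozenset
    variation: tuple | None = None  # (param name, tuple of values) causing fan-out

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", frozenset(self.inputs))
        object.__setattr__(self, "outputs", frozenset(self.outputs))
        if self.variation is not None:
            name, pool = self.variation
            if len(pool) == 0:
                raise ValueError(f"step {self.name}: variation pool must be non-empty")
            object.__setattr__(self, "variation", (name, tuple(pool)))


def _default_transform(node: str, bindings: dict, parent_contents: dict) -> str:
    """Toy materialization: stamp the node name, accumulated bindings and parent hashes."""
    parent_digest = {k: hashlib.sha256(v.encode()).hexdigest()[:12]
                     for k, v in sorted(parent_contents.items())}
    return json.dumps({"node": node, "bindings": {k: bindings[k] for k in sorted(bindings)},
                       "parents": parent_digest}, sort_keys=True) + "\n"


class DAG:
    """Built blaster-style graph: nodes, steps, root contents and transforms."""

    def __init__(self, steps: list[DagStep], root_contents: dict[str, str]):
        self.steps = {s.name: s for s in steps}
        self.root_contents = dict(root_contents)
        self.transforms: dict[str, callable] = {}
        self.graph = nx.DiGraph()
        produced: dict[str, str] = {}
        for s in steps:
            for out in s.outputs:
                if out in produced:
                    raise ValueError(f"node {out!r} produced by both {produced[out]!r} and {s.name!r}")
                produced[out] = s.name
        for s in steps:
            for inp in s.inputs:
                for out in s.outputs:
                    self.graph.add_edge(inp, out, step=s.name)
        for root in root_contents:
            self.graph.add_node(root)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("cyclic step declaration: the dependency graph must be acyclic")
        self.produced_by = produced
        for node in self.graph.nodes:
            if node not in produced and node not in root_contents:
                raise ValueError(f"node {node!r} consumed by a step but never produced nor a root")

    def node_kind(self, node: str) -> str:
        if node in self.root_contents:
            return "root"
        return "leaf" if self.graph.out_degree(node) == 0 else "intermediate"

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.node_kind(n) == "leaf")

    def node_params(self, node: str) -> tuple[str, ...]:
        """Parameters accumulated along the ancestry of a node (inclusive)."""
        nodes = nx.ancestors(self.graph, node) | {node}
        params = set()
        for n in nodes:
            step_name = self.produced_by.get(n)
            if step_name is not None:
                v = self.steps[step_name].variation
                if v is not None:
                    params.add(v[0])
        return tuple(sorted(params))

    def structure_hash(self) -> str:
        payload = {
            "nodes": sorted(self.graph.nodes),
            "edges": sorted(map(list, self.graph.edges)),
            "variations": {s.name: s.variation for s in self.steps.values()},
            "roots": {k: hashlib.sha256(v.encode()).hexdigest()
                      for k, v in self.root_contents.items()},
        }
        return _stable_hash(payload)


def build_dag(config: dict, roots: dict[str, str | Path]) -> DAG:
    """Derive the full candidate graph from a config and root input files.

    ``config['parameters']`` maps each searchable parameter to its value
    pool (list, or {'values': [...]}); each multivalued parameter becomes
    one fan-out step.  ``roots`` maps root node names (receptor, ligand,
    matching_spheres, ...) to file paths whose contents seed the hashes; a
    missing file contributes its path string instead.  The same config and
    root contents always produce a structurally identical DAG.
    """
    params = {}
    for name, spec in (config.get("parameters") or {}).items():
        pool = spec.get("values") if isinstance(spec, dict) else spec
        if pool is None:
            raise ValueError(f"parameter {name!r}: no value pool declared")
        params[name] = tuple(pool)

    root_contents = {}
    for name, path in roots.items():
        p = Path(path)
        root_contents[name] = p.read_text() if p.is_file() else str(path)

    custom = config.get("custom_steps")
    if custom:
        steps = [
            DagStep(
                name=s["name"],
                inputs=frozenset(s["inputs"]),
                outputs=frozenset(s["outputs"]),
                variation=(s["variation"]["param"], tuple(params[s["variation"]["param"]]))
                if s.get("variation")
                else None,
            )
            for s in custom
        ]
        used = {s.variation[0] for s in steps if s.variation is not None}
        unused = set(params) - used
        if unused:
            raise ValueError(f"parameters referenced by no step: {sorted(unused)}")
    else:
        site_inputs = frozenset(roots) or frozenset({"receptor", "ligand"})
        steps = [DagStep(name="prepare_site", inputs=site_inputs, outputs={"site"})]
        param_files = []
        for name in sorted(params):
            out = f"file_{name}"
            steps.append(DagStep(name=f"vary_{name}", inputs={"site"}, outputs={out},
                                 variation=(name, params[name])))
            param_files.append(out)
        steps.append(DagStep(name="assemble_dockfiles",
                             inputs=frozenset(param_files) | {"site"},
                             outputs={"dockfiles"}))
    return DAG(steps=steps, root_contents=root_contents)


def enumerate_parameterizations(dag: DAG) -> list[Parameterization]:
    """All valid leaf combinations: the Cartesian product of variation pools."""
    import itertools

    variations = [(s.name, *s.variation) for s in
                  sorted(dag.steps.values(), key=lambda s: s.name) if s.variation]
    if not variations:
        return [Parameterization(bindings={}, lineage=())]
    names = [v[1] for v in variations]
    pools = [v[2] for v in variations]
    out = []
    for combo in itertools.product(*pools):
        bindings = dict(zip(names, combo))
        lineage = tuple((v[0], c) for v, c in zip(variations, combo))
        out.append(Parameterization(bindings=bindings, lineage=lineage))
    return out


def execute_dag(
    dag: DAG,
    workdir: str | Path,
    parameterizations: list[Parameterization] | None = None,
    executor=None,
    transforms: dict | None = None,
    fail_on: callable = None,
):
    """Materialize every node of every parameterization under ``workdir``.

    Files land in ``workdir/<parameterization-id>/<node>.txt``.  Nodes are
    processed in topological generations, so each node is written only
    after all its parents; within a generation, work items are deduplicated
    by their (node, relevant-bindings) content key and may run in any order
    through ``executor``.  A node whose content already exists on disk
    (same content hash) is skipped.  If a transform raises, only the
    parameterizations depending on that branch are marked failed; sibling
    branches complete.

    Returns ``(status, order)``: per-parameterization status dict
    ("ok"/"failed: ...") and the node materialization order actually used.
    """
    from screenopt.executor import LocalExecutor

    workdir = Path(workdir)
    if parameterizations is None:
        parameterizations = enumerate_parameterizations(dag)
    executor = executor or LocalExecutor()
    transforms = {**{}, **(transforms or {})}

    status = {p.id: "ok" for p in parameterizations}
    order: list[tuple[str, str]] = []  # (node, content key)
    # content cache keyed by (node, relevant bindings); shared across branches
    contents: dict[tuple, str | Exception] = {}

    generations = list(nx.topological_generations(dag.graph))
    for gen in generations:
        jobs = {}
        for p in parameterizations:
            if status[p.id] != "ok":
                continue
            for node in sorted(gen):
                relevant = dag.node_params(node)
                key = (node, tuple((k, p.bindings.get(k)) for k in relevant))
                if key in contents or key in jobs:
                    continue
                if dag.node_kind(node) == "root":
                    contents[key] = dag.root_contents[node]
                    continue
                step = dag.produced_by[node]
                parent_keys = {
                    parent: (parent, tuple((k, p.bindings.get(k))
                                           for k in dag.node_params(parent)))
                    for parent in dag.graph.predecessors(node)
                }
                bindings = {k: p.bindings.get(k) for k in relevant}
                jobs[key] = (node, step, bindings, parent_keys)

        def _run(item):
            key, (node, step, bindings, parent_keys) = item
            parent_contents = {}
            for parent, pkey in parent_keys.items():
                pc = contents[pkey]
                if isinstance(pc, Exception):
                    return key, pc
                parent_contents[parent] = pc
            fn = transforms.get(step, _default_transform)
            try:
                if fail_on is not None and fail_on(node, bindings):
                    raise RuntimeError(f"step {step} failed at node {node}")
                return key, fn(node, bindings, parent_contents)
            except Exception as exc:  # noqa: BLE001 — branch isolation contract
                return key, exc

        for key, result in executor.map(_run, sorted(jobs.items())):
            contents[key] = result
            order.append((key[0], _stable_hash(key)[:8]))

    # persist per-parameterization files and roll up failures
    for p in parameterizations:
        branch_dir = workdir / p.id
        for node in dag.graph.nodes:
            relevant = dag.node_params(node)
            key = (node, tuple((k, p.bindings.get(k)) for k in relevant))
            content = contents.get(key)
            if content is None:
                continue
            if isinstance(content, Exception):
                status[p.id] = f"failed: {content}"
                continue
            branch_dir.mkdir(parents=True, exist_ok=True)
            path = branch_dir / f"{node}.txt"
            if path.exists() and hashlib.sha256(path.read_bytes()).hexdigest() == hashlib.sha256(
                content.encode()
            ).hexdigest():
                continue  # unchanged: idempotent rerun
            path.write_text(content)
    return status, order
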