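"""Node-graph workflow engine.

Workflows are typed directed graphs: nodes belong to one of eight
categories (data input, preprocessing, feature extraction, coupling,
machine learning, statistical analysis, plotting, general) and expose named
ports carrying registered port types.  Before execution a graph must pass
two checks: the DAG rule (no cycles, via Kahn's algorithm) and the node
connection rules (every edge's source/target port-type pair must appear in
the NCR table, and every entry node must be a data-input node).  Execution
runs nodes in topological order, fans each output out to its consumers
unchanged, skips everything downstream of a failure, and records an
execution log.  ``debug_run`` binds simulator-generated inputs to every
data-input node so a graph can be verified without real data.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ParameterError, SchemaError, WorkflowError

CATEGORIES = ("data_input", "preprocessing", "feature_extraction", "coupling",
              "machine_learning", "statistical_analysis", "plotting",
              "general")


@dataclass
class NodeSpec:
    id: str
    category: str
    op: str
    params: dict = field(default_factory=dict)
    in_ports: dict = field(default_factory=dict)   # name -> port type
    out_ports: dict = field(default_factory=dict)  # name -> port type

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise SchemaError(f"unknown node category {self.category!r}")


@dataclass
class WorkflowGraph:
    nodes: list[NodeSpec] = field(default_factory=list)
    edges: list[tuple[str, str, str, str]] = field(default_factory=list)

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise WorkflowError(f"no node with id {node_id!r}")

    def __post_init__(self):
        seen = set()
        for n in self.nodes:
            if n.id in seen:
                raise SchemaError(f"duplicate node id {n.id!r}")
            seen.add(n.id)


class NCRTable:
    """Node-connection rules: which source port type may feed which target.

    The default table ships as an editable JSON asset; ``rules`` maps each
    source port type to the list of target port types it may connect to,
    and ``entry_category`` names the only category allowed at in-degree 0.
    """

    def __init__(self, port_types, rules, entry_category="data_input"):
        self.port_types = set(port_types)
        self.rules = {k: set(v) for k, v in rules.items()}
        self.entry_category = entry_category
        mentioned = set(self.rules) | set().union(*self.rules.values()) \
            if self.rules else set(self.rules)
        unknown = mentioned - self.port_types
        if unknown:
            raise SchemaError(f"NCR rules mention unregistered port types: "
                              f"{sorted(unknown)}")

    @classmethod
    def default(cls) -> "NCRTable":
        text = resources.files("neurofuse").joinpath("assets/ncr.json") \
            .read_text()
        payload = json.loads(text)
        return cls(payload["port_types"], payload["rules"],
                   payload.get("entry_category", "data_input"))

    def allows(self, src_type: str, dst_type: str) -> bool:
        for t in (src_type, dst_type):
            if t not in self.port_types:
                raise WorkflowError(f"unknown port type {t!r}")
        return dst_type in self.rules.get(src_type, set())


@dataclass
class LogEntry:
    node_id: str
    status: str          # ok | failed | skipped
    start: float = 0.0
    end: float = 0.0
    params: dict = field(default_factory=dict)
    error: str = ""


class ExecutionLog(list):
    """Per-node log entries in execution (topological) order."""

    def entry(self, node_id: str) -> LogEntry:
        for e in self:
            if e.node_id == node_id:
                return e
        raise KeyError(node_id)

    @property
    def all_ok(self) -> bool:
        return all(e.status == "ok" for e in self)

    def signature(self) -> list[tuple]:
        """Timestamp-free view, for determinism checks."""
        return [(e.node_id, e.status, e.error) for e in self]


# ---------------------------------------------------------------------------
# Validation


def _check_structure(graph: WorkflowGraph) -> None:
    ids = {n.id for n in graph.nodes}
    for src, sport, dst, dport in graph.edges:
        if src not in ids or dst not in ids:
            raise WorkflowError(
                f"edge ({src}->{dst}) references a missing node")
        if sport not in graph.node(src).out_ports:
            raise WorkflowError(f"node {src!r} has no out port {sport!r}")
        if dport not in graph.node(dst).in_ports:
            raise WorkflowError(f"node {dst!r} has no in port {dport!r}")


def validate_dag(graph: WorkflowGraph) -> list[str]:
    """Kahn's algorithm; returns [] if acyclic, else one cycle as node ids.

    Structural problems (dangling edge endpoints, unknown ports) raise
    :class:`WorkflowError` before the cycle check.
    """
    _check_structure(graph)
    indeg = {n.id: 0 for n in graph.nodes}
    succ = {n.id: [] for n in graph.nodes}
    for src, _, dst, _ in graph.edges:
        indeg[dst] += 1
        succ[src].append(dst)
    queue = [nid for nid, d in indeg.items() if d == 0]
    removed = 0
    while queue:
        nid = queue.pop()
        removed += 1
        for nxt in succ[nid]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                queue.append(nxt)
    if removed == len(graph.nodes):
        return []
    # leftover nodes include cycle members plus their descendants; peel off
    # nodes with no leftover successor until only cycle members remain
    leftover = {nid for nid, d in indeg.items() if d > 0}
    while True:
        dead = {nid for nid in leftover
                if not any(s in leftover for s in succ[nid])}
        if not dead:
            break
        leftover -= dead
    start = sorted(leftover)[0]
    path, seen = [start], {start}
    cur = start
    while True:
        nxt = next(s for s in succ[cur] if s in leftover)
        if nxt in seen:
            return path[path.index(nxt):]
        path.append(nxt)
        seen.add(nxt)
        cur = nxt


def topological_order(graph: WorkflowGraph) -> list[str]:
    cycle = validate_dag(graph)
    if cycle:
        raise WorkflowError(f"workflow contains a cycle: {cycle}")
    indeg = {n.id: 0 for n in graph.nodes}
    succ = {n.id: [] for n in graph.nodes}
    for src, _, dst, _ in graph.edges:
        indeg[dst] += 1
        succ[src].append(dst)
    order, queue = [], sorted(nid for nid, d in indeg.items() if d == 0)
    while queue:
        nid = queue.pop(0)
        order.append(nid)
        for nxt in succ[nid]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                queue.append(nxt)
        queue.sort()
    return order


def validate_connections(graph: WorkflowGraph,
                         ncr: NCRTable | None = None) -> list[str]:
    """Check every edge against the NCR table and the entry rule.

    Returns a list of human-readable violations (empty = ok).
    """
    ncr = ncr or NCRTable.default()
    cycle = validate_dag(graph)
    if cycle:
        raise WorkflowError(f"graph must be a DAG first (cycle: {cycle})")
    violations = []
    for src, sport, dst, dport in graph.edges:
        s_type = graph.node(src).out_ports[sport]
        d_type = graph.node(dst).in_ports[dport]
        if not ncr.allows(s_type, d_type):
            violations.append(
                f"edge {src}.{sport} -> {dst}.{dport}: port type "
                f"{s_type!r} may not feed {d_type!r}")
    targets = {dst for _, _, dst, _ in graph.edges}
    for n in graph.nodes:
        if n.id not in targets and n.category != ncr.entry_category:
            violations.append(
                f"entry node {n.id!r} has category {n.category!r}; a "
                f"workflow must begin with a {ncr.entry_category} node")
    return violations


# ---------------------------------------------------------------------------
# Operation registry


_OP_REGISTRY: dict[str, tuple] = {}


def register_op(name: str, category: str, fn) -> None:
    """Register a node operation.

    ``fn(inputs: dict[port, data], params: dict) -> dict[port, data]``.
    """
    if category not in CATEGORIES:
        raise ParameterError(f"unknown category {category!r}")
    _OP_REGISTRY[name] = (category, fn)


def get_op(name: str):
    if name not in _OP_REGISTRY:
        raise WorkflowError(f"operation {name!r} is not registered")
    return _OP_REGISTRY[name]


def _register_builtin_ops() -> None:
    from . import coupling as cpl
    from . import features as feat
    from . import io as fio
    from . import preprocess as prep

    def op_read_file(inputs, params):
        return {"out": fio.read_signals(params["path"], params["format"])}

    def op_bind(inputs, params):
        return {"out": inputs["out"]}

    def op_bandpass(inputs, params):
        spec = prep.FilterSpec("bandpass", params["low"], params["high"])
        return {"out": prep.filter_signal(inputs["in"], spec)}

    def op_notch(inputs, params):
        spec = prep.FilterSpec("notch", params.get("freq", 60.0))
        return {"out": prep.filter_signal(inputs["in"], spec)}

    def op_auto_pipeline(inputs, params):
        blk, report = prep.run_auto_pipeline(inputs["in"], params["profile"],
                                             seed=params.get("seed", 0))
        return {"out": blk, "report": report}

    def op_band_power(inputs, params):
        return {"out": feat.band_power(inputs["in"],
                                       relative=params.get("relative", False))}

    def op_band_power_timecourse(inputs, params):
        return {"out": feat.band_power_timecourse(
            inputs["in"], tuple(params.get("band", cpl.NVC_DEFAULT_BAND)),
            params.get("window_s", 2.0), params.get("step_s", 0.1))}

    def op_nvc_static(inputs, params):
        return {"out": cpl.nvc_static(inputs["power"], inputs["hb"])}

    def op_cmc(inputs, params):
        return {"out": cpl.cmc(inputs["eeg"], inputs["emg"],
                               tuple(params.get("band", (13.0, 30.0))),
                               params.get("segment_s", 2.0))}

    def op_paired_ttest(inputs, params):
        t, p, rej = cpl.compare_conditions(
            inputs["a"], inputs["b"], alpha=params.get("alpha", 0.05),
            correction=params.get("correction", "holm"))
        return {"out": {"t": t.tolist(), "p": p.tolist(),
                        "reject": rej.tolist()}}

    def op_plot_timeseries(inputs, params):
        data = inputs["in"]
        if params.get("path"):
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots()
            arr = data.data if hasattr(data, "data") else np.asarray(data)
            ax.plot(np.atleast_2d(arr).T)
            fig.savefig(params["path"])
            plt.close(fig)
        return {"out": data}  # pass-through, data never modified

    def op_identity(inputs, params):
        return {"out": inputs["in"]}

    def op_flatten_features(inputs, params):
        X = inputs["in"]
        X = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
        return {"out": X.reshape(1, -1)}

    def op_predict(inputs, params):
        import pickle
        with open(params["model_path"], "rb") as f:
            model = pickle.load(f)
        X = inputs["in"]
        X = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
        return {"out": model.predict(X).tolist()}

    register_op("read_file", "data_input", op_read_file)
    register_op("bind", "data_input", op_bind)
    register_op("bandpass_filter", "preprocessing", op_bandpass)
    register_op("notch_filter", "preprocessing", op_notch)
    register_op("auto_pipeline", "preprocessing", op_auto_pipeline)
    register_op("band_power", "feature_extraction", op_band_power)
    register_op("band_power_timecourse", "feature_extraction",
                op_band_power_timecourse)
    register_op("nvc_static", "coupling", op_nvc_static)
    register_op("cmc", "coupling", op_cmc)
    register_op("paired_ttest", "statistical_analysis", op_paired_ttest)
    register_op("plot_timeseries", "plotting", op_plot_timeseries)
    register_op("identity", "general", op_identity)
    register_op("flatten_features", "general", op_flatten_features)
    register_op("predict", "machine_learning", op_predict)


_register_builtin_ops()


# ---------------------------------------------------------------------------
# Execution


def execute(graph: WorkflowGraph, inputs: dict | None = None,
            ncr: NCRTable | None = None):
    """Run a validated workflow.

    ``inputs`` maps data-input node ids to their bound data (required for
    ``bind`` nodes).  Returns ``(outputs, log)`` where ``outputs`` maps node
    id to its port->data dict.  A failing node marks all its descendants
    ``skipped``; the log records every node in topological order.
    """
    inputs = inputs or {}
    violations = validate_connections(graph, ncr)
    if violations:
        raise WorkflowError("; ".join(violations))
    for n in graph.nodes:
        if n.category == "data_input" and n.op == "bind" and n.id not in inputs:
            raise WorkflowError(f"data_input node {n.id!r} is not bound")
    order = topological_order(graph)
    parents = {n.id: [] for n in graph.nodes}
    for src, sport, dst, dport in graph.edges:
        parents[dst].append((src, sport, dport))
    outputs: dict[str, dict] = {}
    log = ExecutionLog()
    failed_or_skipped = set()
    for nid in order:
        node = graph.node(nid)
        entry = LogEntry(node_id=nid, status="ok", params=dict(node.params))
        if any(src in failed_or_skipped for src, _, _ in parents[nid]):
            entry.status = "skipped"
            failed_or_skipped.add(nid)
            log.append(entry)
            continue
        node_inputs = {dport: outputs[src][sport]
                       for src, sport, dport in parents[nid]}
        if node.category == "data_input" and node.op == "bind":
            node_inputs = {"out": inputs[nid]}
        _, fn = get_op(node.op)
        entry.start = time.time()
        try:
            outputs[nid] = fn(node_inputs, node.params)
            entry.end = time.time()
        except Exception as exc:
            entry.end = time.time()
            entry.status = "failed"
            entry.error = f"{type(exc).__name__}: {exc}"
            failed_or_skipped.add(nid)
        log.append(entry)
    return outputs, log


# ---------------------------------------------------------------------------
# Debug runs with synthetic inputs


def _debug_synthesizers(seed: int) -> dict:
    from . import simulate as sim

    def eeg():
        return sim.sim_eeg(4, 10.0, 250.0, seed=seed)

    def eog():
        b = sim.sim_eeg(1, 10.0, 250.0, {"delta": 20.0}, seed=seed + 1)
        return b.copy(modality="eog", labels=["EOG1"])

    def emg():
        e, _, _ = sim.sim_emg_with_drive(None, 20.0, 1.0, 10.0, 500.0,
                                         seed=seed)
        return e

    def ecg():
        e, _ = sim.sim_ecg(10.0, 250.0, seed=seed)
        return e

    def fnirs_hb():
        eeg_b = sim.sim_eeg(1, 15.0, 250.0, seed=seed)
        hb, _ = sim.sim_coupled_fnirs(eeg_b, coupling=0.8, seed=seed)
        return hb

    def fnirs_intensity():
        from .preprocess import mbll_forward
        rng = np.random.default_rng(seed)
        n = 100
        hbo = 0.5 * np.sin(2 * np.pi * 0.1 * np.arange(n) / 10.0)
        hbr = -0.3 * hbo
        inten = mbll_forward(hbo, hbr, [1.0, 1.0], [760.0, 850.0])
        labels = ["S1-D1_760", "S1-D1_850"]
        return sim.SignalBlock("fnirs_intensity", inten, 10.0, labels)

    def power_series():
        b = sim.sim_eeg(1, 10.0, 250.0, seed=seed)
        from .features import band_power_timecourse
        return band_power_timecourse(b, (8.0, 30.0), 1.0, 0.5)

    def features_tab():
        rng = np.random.default_rng(seed)
        from .features import FeatureSet
        return FeatureSet(rng.standard_normal((10, 3)), ["f0", "f1", "f2"])

    return {"eeg_raw": eeg, "eog_raw": eog, "emg_raw": emg, "ecg_raw": ecg,
            "fnirs_hb": fnirs_hb, "fnirs_intensity": fnirs_intensity,
            "power_series": power_series, "features": features_tab}


def debug_run(graph: WorkflowGraph, seed: int = 0,
              ncr: NCRTable | None = None) -> ExecutionLog:
    """Execute the graph on simulator-generated inputs (10 s, 4 channels).

    Every ``bind`` data-input node is bound to synthetic data matching its
    declared output port type; a workflow that completes without errors is
    preliminarily verified.
    """
    synth = _debug_synthesizers(seed)
    inputs = {}
    for n in graph.nodes:
        if n.category == "data_input" and n.op == "bind":
            port_type = next(iter(n.out_ports.values()), None)
            if port_type not in synth:
                raise WorkflowError(
                    f"no debug synthesizer for port type {port_type!r}")
            inputs[n.id] = synth[port_type]()
    _, log = execute(graph, inputs, ncr)
    return log


# ---------------------------------------------------------------------------
# Persistence


def save_workflow(graph: WorkflowGraph, path) -> Path:
    payload = {
        "version": 1,
        "nodes": [{"id": n.id, "category": n.category, "op": n.op,
                   "params": n.params, "in_ports": n.in_ports,
                   "out_ports": n.out_ports} for n in graph.nodes],
        "edges": [list(e) for e in graph.edges],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_workflow(path) -> WorkflowGraph:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid workflow JSON at line {exc.lineno}: "
                          f"{exc.msg}") from exc
    for key in ("nodes", "edges"):
        if key not in payload:
            raise SchemaError(f"workflow JSON missing {key!r}")
    nodes = []
    for nd in payload["nodes"]:
        try:
            nodes.append(NodeSpec(nd["id"], nd["category"], nd["op"],
                                  nd.get("params", {}),
                                  nd.get("in_ports", {}),
                                  nd.get("out_ports", {})))
        except KeyError as exc:
            raise SchemaError(f"node entry missing field {exc}") from exc
    edges = [tuple(e) for e in payload["edges"]]
    return WorkflowGraph(nodes=nodes, edges=edges)


def workflow_hash(graph: WorkflowGraph) -> str:
    payload = {"nodes": [[n.id, n.category, n.op, sorted(n.params.items()),
                          sorted(n.in_ports.items()),
                          sorted(n.out_ports.items())] for n in graph.nodes],
               "edges": sorted(graph.edges)}
    return hashlib.sha256(json.dumps(payload, default=str).encode()) \
        .hexdigest()


# ---------------------------------------------------------------------------
# Application generation


_APP_TEMPLATE = '''\
"""Auto-generated application: {app_name}.

Runs a saved workflow on a named input file:
    python {script_name} <input.csv> <output.json>
Input: {input_label}.  Output: {output_label}.
"""
import json
import sys
from pathlib import Path

from neurofuse import io as fio
from neurofuse import workflow as wf


def main(argv):
    if len(argv) != 3:
        print(__doc__)
        return 2
    graph = wf.load_workflow(Path(__file__).with_name("{workflow_file}"))
    data = fio.read_signals(argv[1], "csv_sidecar")
    entry = next(n.id for n in graph.nodes if n.category == "data_input")
    outputs, log = wf.execute(graph, {{entry: data}})
    if not log.all_ok:
        print(json.dumps(log.signature(), indent=1))
        return 1
    sinks = [n.id for n in graph.nodes
             if not any(e[0] == n.id for e in graph.edges)]
    result = {{nid: _plain(outputs.get(nid, {{}})) for nid in sinks}}
    Path(argv[2]).write_text(json.dumps(result, indent=1, default=str))
    print(f"wrote {{argv[2]}}")
    return 0


def _plain(ports):
    out = {{}}
    for port, value in ports.items():
        out[port] = value if isinstance(value, (int, float, str, list, dict)) \\
            else str(value)
    return out


if __name__ == "__main__":
    raise SystemExit(main(sys.argv))
'''


def generate_app_script(graph: WorkflowGraph, ui_config: dict, outdir,
                        ncr: NCRTable | None = None):
    """Turn a validated workflow into a runnable script plus a manifest.

    ``ui_config`` needs ``app_name`` and may carry ``input_label`` /
    ``output_label``.  Machine-learning inference nodes must reference a
    trained model (``model_path`` param).  Returns
    ``(script path, manifest path)``.
    """
    if not ui_config.get("app_name"):
        raise ParameterError("ui_config must provide a non-empty app_name")
    violations = validate_connections(graph, ncr)
    if violations:
        raise WorkflowError("workflow fails connection rules: "
                            + "; ".join(violations))
    for n in graph.nodes:
        if n.category == "machine_learning" and not n.params.get("model_path"):
            raise WorkflowError(
                f"machine_learning node {n.id!r} has no trained model "
                "reference (model_path)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    app_name = ui_config["app_name"]
    script_path = outdir / f"{app_name}.py"
    if script_path.exists():
        raise ParameterError(f"name collision: {script_path} already exists")
    workflow_file = f"{app_name}_workflow.json"
    save_workflow(graph, outdir / workflow_file)
    script_path.write_text(_APP_TEMPLATE.format(
        app_name=app_name, script_name=script_path.name,
        workflow_file=workflow_file,
        input_label=ui_config.get("input_label", "input data"),
        output_label=ui_config.get("output_label", "workflow outputs")))
    manifest = {
        "app_name": app_name,
        "workflow_hash": workflow_hash(graph),
        "workflow_file": workflow_file,
        "inputs": [n.id for n in graph.nodes if n.category == "data_input"],
        "outputs": [n.id for n in graph.nodes
                    if not any(e[0] == n.id for e in graph.edges)],
        "input_label": ui_config.get("input_label", ""),
        "output_label": ui_config.get("output_label", ""),
    }
    manifest_path = outdir / f"{app_name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return script_path, manifest_path
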