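"""DAG validation, connection rules, execution, debug runs, app generation."""

import itertools
import json
import pickle
import subprocess
import sys

import numpy as np
import pytest

from neurofuse import workflow as wf
from neurofuse.errors import ParameterError, SchemaError, WorkflowError


def node(nid, category="general", op="identity", params=None,
         in_ports=None, out_ports=None):
    return wf.NodeSpec(nid, category, op, params or {},
                       in_ports if in_ports is not None else {"in": "any"},
                       out_ports if out_ports is not None else
                       {"out": "any"})


def source(nid="src", port_type="any"):
    return wf.NodeSpec(nid, "data_input", "bind", {}, {},
                       {"out": port_type})


def chain_graph():
    return wf.WorkflowGraph(
        nodes=[source("src", "eeg_raw"),
               node("filt", "preprocessing", "bandpass_filter",
                    {"low": 2.0, "high": 50.0}, {"in": "eeg_raw"},
                    {"out": "eeg_raw"}),
               node("bp", "feature_extraction", "band_power", {},
                    {"in": "eeg_raw"}, {"out": "features"})],
        edges=[("src", "out", "filt", "in"), ("filt", "out", "bp", "in")])


class TestValidateDag:
    def test_linear_chain_ok(self):
        g = wf.WorkflowGraph(nodes=[source("A"), node("B"), node("C")],
                             edges=[("A", "out", "B", "in"),
                                    ("B", "out", "C", "in")])
        assert wf.validate_dag(g) == []

    def test_two_cycle(self):
        g = wf.WorkflowGraph(nodes=[node("A"), node("B")],
                             edges=[("A", "out", "B", "in"),
                                    ("B", "out", "A", "in")])
        assert sorted(wf.validate_dag(g)) == ["A", "B"]

    def test_self_loop(self):
        g = wf.WorkflowGraph(nodes=[node("A")],
                             edges=[("A", "out", "A", "in")])
        assert wf.validate_dag(g) == ["A"]

    def test_dangling_edge_reported_first(self):
        g = wf.WorkflowGraph(nodes=[node("A")],
                             edges=[("A", "out", "ghost", "in")])
        with pytest.raises(WorkflowError):
            wf.validate_dag(g)

    def test_agrees_with_brute_force_enumeration(self):
        """Kahn's algorithm vs. exhaustive path enumeration on seeded
        random graphs of up to 8 nodes."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            n = int(rng.integers(2, 9))
            ids = [f"n{i}" for i in range(n)]
            edges = [(a, "out", b, "in")
                     for a, b in itertools.permutations(ids, 2)
                     if rng.random() < 0.25]
            g = wf.WorkflowGraph(
                nodes=[node(i, in_ports={"in": "any"},
                            out_ports={"out": "any"}) for i in ids],
                edges=edges)
            # brute force: does any node reach itself?
            succ = {i: {e[2] for e in edges if e[0] == i} for i in ids}

            def reaches(a, b, seen=None):
                seen = seen or set()
                for nxt in succ[a]:
                    if nxt == b:
                        return True
                    if nxt not in seen:
                        seen.add(nxt)
                        if reaches(nxt, b, seen):
                            return True
                return False

            has_cycle_brute = any(reaches(i, i) for i in ids)
            cycle = wf.validate_dag(g)
            assert bool(cycle) == has_cycle_brute
            if cycle:  # the reported cycle must be a real cycle
                for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                    assert b in succ[a]


class TestValidateConnections:
    def test_modality_mismatch_flagged(self):
        g = wf.WorkflowGraph(
            nodes=[source("s", "fnirs_hb"),
                   node("f", "preprocessing", "bandpass_filter",
                        {"low": 1.0, "high": 4.0}, {"in": "eeg_raw"},
                        {"out": "eeg_raw"})],
            edges=[("s", "out", "f", "in")])
        violations = wf.validate_connections(g)
        assert len(violations) == 1 and "fnirs_hb" in violations[0]

    def test_entry_must_be_data_input(self):
        g = wf.WorkflowGraph(
            nodes=[node("plot", "plotting", "plot_timeseries", {},
                        {"in": "any"}, {"out": "any"})],
            edges=[])
        violations = wf.validate_connections(g)
        assert len(violations) == 1 and "data_input" in violations[0]

    def test_matching_ports_pass(self):
        assert wf.validate_connections(chain_graph()) == []

    def test_unknown_port_type(self):
        g = wf.WorkflowGraph(
            nodes=[source("s", "martian"), node("t")],
            edges=[("s", "out", "t", "in")])
        with pytest.raises(WorkflowError):
            wf.validate_connections(g)


class TestExecute:
    def test_linear_chain_logs_in_order(self):
        from neurofuse.simulate import sim_eeg
        outs, log = wf.execute(chain_graph(),
                               {"src": sim_eeg(4, 10.0, 250.0, seed=0)})
        assert [e.node_id for e in log] == ["src", "filt", "bp"]
        assert log.all_ok
        assert outs["bp"]["out"].values.shape[0] == 4

    def test_failure_skips_downstream(self):
        wf.register_op("always_fail", "general",
                       lambda i, p: (_ for _ in ()).throw(RuntimeError("boom")))
        g = wf.WorkflowGraph(
            nodes=[source("s"), node("mid", op="always_fail"), node("end")],
            edges=[("s", "out", "mid", "in"), ("mid", "out", "end", "in")])
        _, log = wf.execute(g, {"s": 1.0})
        assert log.entry("mid").status == "failed"
        assert "boom" in log.entry("mid").error
        assert log.entry("end").status == "skipped"
        assert not log.all_ok

    def test_diamond_fan_in_once(self):
        calls = []

        def sink_op(inputs, params):
            calls.append(dict(inputs))
            return {"out": (inputs["a"], inputs["b"])}

        wf.register_op("pair_sink", "general", sink_op)
        g = wf.WorkflowGraph(
            nodes=[source("s"),
                   node("l", params={"tag": "l"}),
                   node("r", params={"tag": "r"}),
                   node("sink", op="pair_sink",
                        in_ports={"a": "any", "b": "any"})],
            edges=[("s", "out", "l", "in"), ("s", "out", "r", "in"),
                   ("l", "out", "sink", "a"), ("r", "out", "sink", "b")])
        outs, log = wf.execute(g, {"s": 42})
        assert log.all_ok and len(calls) == 1
        assert outs["sink"]["out"] == (42, 42)

    def test_unbound_input_rejected(self):
        with pytest.raises(WorkflowError):
            wf.execute(chain_graph(), {})

    def test_plot_node_passes_data_through_unchanged(self):
        from neurofuse.simulate import sim_eeg
        g = wf.WorkflowGraph(
            nodes=[source("s", "eeg_raw"),
                   node("plot", "plotting", "plot_timeseries", {},
                        {"in": "eeg_raw"}, {"out": "eeg_raw"}),
                   node("end", in_ports={"in": "eeg_raw"},
                        out_ports={"out": "eeg_raw"})],
            edges=[("s", "out", "plot", "in"), ("plot", "out", "end", "in")])
        data = sim_eeg(2, 5.0, 100.0, seed=0)
        outs, log = wf.execute(g, {"s": data})
        assert log.all_ok
        assert outs["plot"]["out"] is data  # byte-identical pass-through


class TestDebugRun:
    def test_valid_pipeline_all_ok(self):
        log = wf.debug_run(chain_graph(), seed=0)
        assert log.all_ok

    def test_bad_parameter_pinpoints_node(self):
        g = wf.WorkflowGraph(
            nodes=[source("src", "eeg_raw"),
                   node("filt", "preprocessing", "bandpass_filter",
                        {"low": 2.0, "high": 500.0},  # above Nyquist
                        {"in": "eeg_raw"}, {"out": "eeg_raw"})],
            edges=[("src", "out", "filt", "in")])
        log = wf.debug_run(g, seed=0)
        assert log.entry("filt").status == "failed"
        assert log.entry("src").status == "ok"

    def test_same_seed_identical_logs(self):
        g = chain_graph()
        assert wf.debug_run(g, seed=9).signature() == \
            wf.debug_run(g, seed=9).signature()

    def test_unsupported_port_type(self):
        g = wf.WorkflowGraph(nodes=[source("s", "model")], edges=[])
        with pytest.raises(WorkflowError):
            wf.debug_run(g, seed=0)


class TestPersistence:
    def test_round_trip(self, tmp_path):
        g = chain_graph()
        wf.save_workflow(g, tmp_path / "w.json")
        back = wf.load_workflow(tmp_path / "w.json")
        assert [n.__dict__ for n in back.nodes] == \
            [n.__dict__ for n in g.nodes]
        assert back.edges == g.edges

    def test_missing_edges_field(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps({"nodes": []}))
        with pytest.raises(SchemaError) as err:
            wf.load_workflow(tmp_path / "bad.json")
        assert "edges" in str(err.value)

    def test_unknown_category(self, tmp_path):
        payload = {"nodes": [{"id": "x", "category": "martian",
                              "op": "identity"}], "edges": []}
        (tmp_path / "bad.json").write_text(json.dumps(payload))
        with pytest.raises(SchemaError):
            wf.load_workflow(tmp_path / "bad.json")

    def test_random_graph_round_trips(self, tmp_path):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(1, 7))
            nodes = [node(f"n{i}", params={"p": float(rng.random())})
                     for i in range(n)]
            edges = [(f"n{i}", "out", f"n{j}", "in")
                     for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.3]
            g = wf.WorkflowGraph(nodes=nodes, edges=edges)
            wf.save_workflow(g, tmp_path / f"g{trial}.json")
            back = wf.load_workflow(tmp_path / f"g{trial}.json")
            assert back.edges == g.edges
            assert [b.__dict__ for b in back.nodes] == \
                [a.__dict__ for a in g.nodes]


class TestAppGeneration:
    def _inference_graph(self, tmp_path):
        """Train a toy classifier on band-power features, reference it from
        a predict node."""
        from sklearn.svm import SVC
        from neurofuse.features import band_power
        from neurofuse.simulate import sim_eeg
        rng = np.random.default_rng(0)
        X, y = [], []
        for i in range(20):
            amp = 5.0 if i % 2 else 20.0
            b = sim_eeg(2, 4.0, 100.0, {"alpha": amp}, seed=i)
            X.append(band_power(b).values.ravel())
            y.append(i % 2)
        model = SVC(kernel="linear").fit(np.array(X), y)
        model_path = tmp_path / "model.pkl"
        with open(model_path, "wb") as f:
            pickle.dump(model, f)

        return wf.WorkflowGraph(
            nodes=[source("src", "eeg_raw"),
                   node("bp", "feature_extraction", "band_power", {},
                        {"in": "eeg_raw"}, {"out": "features"}),
                   node("flat", "general", "flatten_features", {},
                        {"in": "features"}, {"out": "features"}),
                   node("clf", "machine_learning", "predict",
                        {"model_path": str(model_path)},
                        {"in": "features"}, {"out": "predictions"})],
            edges=[("src", "out", "bp", "in"), ("bp", "out", "flat", "in"),
                   ("flat", "out", "clf", "in")])

    def test_generated_script_runs_end_to_end(self, tmp_path):
        from neurofuse import io as fio
        from neurofuse.simulate import sim_eeg
        g = self._inference_graph(tmp_path)
        script, manifest = wf.generate_app_script(
            g, {"app_name": "mi_demo", "input_label": "EEG CSV"},
            tmp_path / "app")
        assert json.loads(manifest.read_text())["workflow_hash"]
        fixture = tmp_path / "input.csv"
        fio.write_signals(sim_eeg(2, 4.0, 100.0, {"alpha": 20.0}, seed=99),
                          fixture, "csv_sidecar")
        out_json = tmp_path / "pred.json"
        proc = subprocess.run([sys.executable, str(script), str(fixture),
                               str(out_json)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        result = json.loads(out_json.read_text())
        assert result["clf"]["out"] in ([0], [1])

    def test_invalid_graph_refused(self, tmp_path):
        g = wf.WorkflowGraph(
            nodes=[source("s", "fnirs_hb"),
                   node("f", "preprocessing", "bandpass_filter",
                        {"low": 1.0, "high": 4.0}, {"in": "eeg_raw"},
                        {"out": "eeg_raw"})],
            edges=[("s", "out", "f", "in")])
        with pytest.raises(WorkflowError):
            wf.generate_app_script(g, {"app_name": "x"}, tmp_path)

    def test_ml_node_without_model_refused(self, tmp_path):
        g = wf.WorkflowGraph(
            nodes=[source("s", "features"),
                   node("clf", "machine_learning", "predict", {},
                        {"in": "features"}, {"out": "predictions"})],
            edges=[("s", "out", "clf", "in")])
        with pytest.raises(WorkflowError):
            wf.generate_app_script(g, {"app_name": "x"}, tmp_path)

    def test_missing_app_name(self, tmp_path):
        with pytest.raises(ParameterError):
            wf.generate_app_script(chain_graph(), {}, tmp_path)
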