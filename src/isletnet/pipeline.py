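"""End-to-end pipeline: trace source → metrics → networks → topology → stats.

A single declarative config drives the run; a manifest (inputs, seeds,
package version, output files) is written alongside the results so the
run can be reproduced exactly. All randomness flows from the config's
top-level seed via deterministic per-islet derivation.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

import isletnet
from isletnet import io as iio
from isletnet.compare import (
    build_metabolic_network,
    comparison_probabilities,
    weighted_shortest_paths,
)
from isletnet.funcnet import identify_hubs, threshold_network, tune_threshold
from isletnet.islet import build_islet
from isletnet.metrics import correlate_params_with_duty, duty_cycles, pearson_matrix
from isletnet.simulate import SimulationConfig, simulate_islet
from isletnet.synth import SyntheticSpec, generate_traces
from isletnet.topology import er_null_ensemble, summarize_topology

log = logging.getLogger("isletnet.pipeline")

__all__ = ["PipelineError", "pipeline_run"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def pipeline_run(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages and write a results bundle.

    Returns the manifest dict. Partial outputs are preserved on failure;
    the raised :class:`PipelineError` names the failing stage.
    """
    if not isinstance(config, dict):
        config = iio.load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": isletnet.__version__,
        "config": config,
        "outputs": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def emit(name: str, writer, *args) -> None:
        path = out / name
        writer(path, *args)
        manifest["outputs"].append(name)

    seed = int(config.get("seed", 0))
    n_cells = int(config.get("islet", {}).get("n_cells", 64))
    model_tag = config.get("islet", {}).get("model_tag", "fast")
    source = config.get("source", "synthetic")

    stage = "islet"
    try:
        log.info("stage %s: building %d-cell %s islet (seed %d)", stage, n_cells, model_tag, seed)
        islet = build_islet(n_cells, model_tag=model_tag, seed=seed)
        emit("positions.csv", iio.write_positions_csv, islet.geometry)
        emit("parameters.csv", iio.write_parameters_csv, islet.params)
        emit("structural_edges.csv", iio.write_network_csv, islet.structure)
        emit("structural.graphml", iio.write_network_graphml, islet.structure)

        stage = "traces"
        if source == "synthetic":
            syn = config.get("synthetic", {})
            spec = SyntheticSpec(
                n_cells=n_cells,
                period_s=float(syn.get("period_s", 30.0)),
                duty=float(syn.get("duty", 0.4)),
                wave_speed=float(syn.get("wave_speed", 0.0)),
                noise_sd=float(syn.get("noise_sd", 0.1)),
                phase_jitter=float(syn.get("phase_jitter", 2.0)),
                duration_s=float(syn.get("duration_s", 400.0)),
                seed=seed,
            )
            traces, ground_truth = generate_traces(spec, islet.geometry)
            emit("ground_truth.json", iio.write_json, ground_truth)
        elif source == "simulated":
            sim = config.get("simulation", {})
            sim_config = SimulationConfig(
                duration=float(sim.get("duration", 500.0)),
                sampling_interval=float(sim.get("sampling_interval", 1.0)),
                dt=float(sim.get("dt", 0.02)),
                seed=seed,
            )
            traces = simulate_islet(islet, config=sim_config)
        else:
            raise PipelineError(f"unknown trace source {source!r}")
        emit("traces.csv", iio.write_traces_csv, traces)
        emit("traces.h5", iio.write_traces_hdf5, traces)

        stage = "metrics"
        R = pearson_matrix(traces)
        duty = duty_cycles(traces)
        param_r = correlate_params_with_duty(
            islet.params, duty, total_conductance=islet.structure.total_conductance
        )

        stage = "network"
        netcfg = config.get("network", {})
        if "threshold" in netcfg and netcfg["threshold"] != "tuned":
            R_th = float(netcfg["threshold"])
            tuning = None
        else:
            tuning = tune_threshold(R, k_avg_bounds=tuple(netcfg.get("k_avg_bounds", (5, 15))))
            R_th = tuning.R_th
        fnet = threshold_network(R, R_th)
        hubs = identify_hubs(fnet, method=netcfg.get("hub_method", "threshold60"))
        emit("functional_edges.csv", iio.write_network_csv, fnet)
        emit("hub_table.csv", iio.write_hub_table_csv, fnet, hubs)

        stage = "compare"
        comp = comparison_probabilities(fnet, islet.structure)
        compare_report = {"structural": comp.as_dict()}
        try:
            met = build_metabolic_network(islet.params, islet.geometry, fnet, islet.structure)
            compare_report["metabolic"] = comparison_probabilities(fnet, met).as_dict()
            compare_report["metabolic_calibration"] = met.calibration
        except Exception as exc:  # calibration can be infeasible on tiny islets
            compare_report["metabolic_error"] = str(exc)
        paths = weighted_shortest_paths(islet.structure, weight_source="g_coup")
        compare_report["mean_hops"] = float(paths.hops[paths.hops > 0].mean())
        emit("comparison.json", iio.write_json, compare_report)

        stage = "topology"
        topo = summarize_topology(fnet, islet.geometry)
        null_size = int(config.get("topology", {}).get("null_size", 200))
        report = {
            "R_th": R_th,
            "tuning": None if tuning is None else vars(tuning),
            "k_avg": topo.k_avg,
            "size_normalized_mean_degree": topo.size_normalized_mean_degree,
            "C_avg": topo.C_avg,
            "L_avg": topo.L_avg,
            "E_global": topo.E_global,
            "sync_distance": topo.sync_distance,
            "hub_fraction": hubs.hub_fraction,
            "duty_cycle_mean": float(duty.values.mean()),
            "param_duty_correlations": param_r,
        }
        if topo.k_avg > 0:
            null = er_null_ensemble(n_cells, topo.k_avg, size=null_size, seed=seed)
            report["er_null"] = null.quantiles()
        emit("topology.json", iio.write_json, report)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    iio.write_json(out / "manifest.json", manifest)
    log.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest
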