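"""File round-tripping for islets, traces, networks and reports.

CSV writers keep full float precision (``repr`` round-trip); trace sets
can also be stored in an HDF5 container with their metadata. Network
writers emit both edge-list CSV and GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from isletnet.funcnet import FunctionalNetwork, HubClassification
from isletnet.islet import CellParameters, IsletGeometry, StructuralNetwork
from isletnet.traces import CalciumTraceSet

__all__ = [
    "write_positions_csv",
    "read_positions_csv",
    "write_parameters_csv",
    "read_parameters_csv",
    "write_network_csv",
    "write_network_graphml",
    "write_hub_table_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_traces_hdf5",
    "read_traces_hdf5",
    "write_json",
    "load_config",
]

_FLOAT_FMT = "%.17g"


def write_positions_csv(path, geometry: IsletGeometry) -> None:
    df = pd.DataFrame(geometry.positions, columns=["x", "y", "z"])
    df.insert(0, "cell_id", np.arange(geometry.n_cells))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_positions_csv(path, coupling_cutoff: float = 2.35) -> IsletGeometry:
    df = pd.read_csv(path)
    return IsletGeometry(
        positions=df[["x", "y", "z"]].to_numpy(float), coupling_cutoff=coupling_cutoff
    )


def write_parameters_csv(path, params: CellParameters) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(params.n_cells),
            "k_glyc": params.k_glyc,
            "g_KATP": params.g_KATP,
            "g_coup_cell": params.g_coup_cell,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_parameters_csv(path, model_tag: str = "fast") -> CellParameters:
    df = pd.read_csv(path)
    return CellParameters(
        k_glyc=df["k_glyc"].to_numpy(float),
        g_KATP=df["g_KATP"].to_numpy(float),
        g_coup_cell=df["g_coup_cell"].to_numpy(float),
        model_tag=model_tag,
    )


def _edges_with_weights(net) -> list[tuple[int, int, float]]:
    adj = net.adjacency
    i, j = np.nonzero(np.triu(adj, 1))
    if isinstance(net, StructuralNetwork) and net.edge_conductance is not None:
        w = net.edge_conductance[i, j]
    else:
        w = np.ones(len(i))
    return list(zip(i.tolist(), j.tolist(), w.tolist()))


def write_network_csv(path, net) -> None:
    """Edge list CSV with columns i, j, weight (edge conductance when known)."""
    rows = _edges_with_weights(net)
    pd.DataFrame(rows, columns=["i", "j", "weight"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_network_graphml(path, net) -> None:
    G = nx.Graph()
    G.add_nodes_from(range(net.adjacency.shape[0]))
    G.add_weighted_edges_from(_edges_with_weights(net))
    nx.write_graphml(G, path)


def write_hub_table_csv(path, net: FunctionalNetwork, hubs: HubClassification) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(net.n_cells),
            "degree": net.degrees,
            "normalized_degree_pct": net.normalized_degree_pct,
            "is_hub": hubs.is_hub,
            "method": hubs.method,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_traces_csv(path, traces: CalciumTraceSet) -> None:
    """Wide CSV: one time column plus one column per cell."""
    df = pd.DataFrame(traces.traces.T, columns=[f"cell_{i}" for i in range(traces.n_cells)])
    df.insert(0, "time_s", traces.times)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traces_csv(path, analysis_window=None, provenance="experimental") -> CalciumTraceSet:
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(float)
    tr = df.drop(columns=["time_s"]).to_numpy(float).T
    if analysis_window is None:
        analysis_window = (float(times[0]), float(times[-1]))
    return CalciumTraceSet(
        traces=tr, times=times, analysis_window=analysis_window, provenance=provenance
    )


def write_traces_hdf5(path, traces: CalciumTraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces.traces)
        f.create_dataset("times", data=traces.times)
        f.attrs["analysis_window"] = list(traces.analysis_window)
        f.attrs["provenance"] = traces.provenance
        f.attrs["metadata_json"] = json.dumps(traces.metadata, default=float)


def read_traces_hdf5(path) -> CalciumTraceSet:
    with h5py.File(path, "r") as f:
        return CalciumTraceSet(
            traces=f["traces"][()],
            times=f["times"][()],
            analysis_window=tuple(f.attrs["analysis_window"]),
            provenance=str(f.attrs["provenance"]),
            metadata=json.loads(f.attrs["metadata_json"]),
        )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
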