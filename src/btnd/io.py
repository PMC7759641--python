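"""Serialization of pipeline artifacts.

Between stages, matrices travel as ``.npz`` archives with a JSON sidecar
carrying everything needed to re-run the stage (edge index, window
parameters, hyperparameters, seeds).  Human-facing exports are CSV
(edge-by-window FC, per-component edge lists, activation time courses)
and GraphML for the subgraphs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    ActivationProfiles,
    BTNDConfig,
    Decomposition,
    FusedLassoParams,
    SubgraphSet,
)
from .synthetic import PlantedModel
from .types import EdgeIndex, FCSeries, MultiSeizureDataset

# ---------------------------------------------------------------- FC dataset


def save_fc_dataset(X: MultiSeizureDataset, prefix: str | Path) -> None:
    prefix = Path(prefix)
    arrays = {f"seizure_{s}": fc.values for s, fc in enumerate(X.seizures)}
    np.savez(prefix.with_suffix(".npz"), **arrays)
    meta = {
        "n_channels": X.edge_index.n_channels,
        "seizures": [
            {
                "seizure_id": fc.seizure_id,
                "window_length_s": fc.window_length_s,
                "window_step_s": fc.window_step_s,
                "channel_labels": fc.channel_labels,
                "T": fc.T,
            }
            for fc in X.seizures
        ],
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_fc_dataset(prefix: str | Path) -> MultiSeizureDataset:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    arrays = np.load(prefix.with_suffix(".npz"))
    edge_index = EdgeIndex.from_n_channels(meta["n_channels"])
    seizures = [
        FCSeries(
            values=arrays[f"seizure_{s}"],
            edge_index=edge_index,
            window_length_s=m["window_length_s"],
            window_step_s=m["window_step_s"],
            seizure_id=m["seizure_id"],
            channel_labels=m["channel_labels"],
        )
        for s, m in enumerate(meta["seizures"])
    ]
    return MultiSeizureDataset(seizures=seizures)


def fc_to_csv(fc: FCSeries, path: str | Path) -> None:
    """Rows = edges (labeled ``"A1-A2|B3-B4"`` when labels exist), columns =
    window start times in seconds."""
    labels = (
        fc.edge_index.edge_labels(fc.channel_labels)
        if fc.channel_labels
        else [f"{i}|{j}" for i, j in fc.edge_index.pairs]
    )
    cols = [f"{t * fc.window_step_s:g}" for t in range(fc.T)]
    pd.DataFrame(fc.values, index=labels, columns=cols).to_csv(path)


# ------------------------------------------------------------- decomposition


def save_decomposition(dec: Decomposition, prefix: str | Path) -> None:
    prefix = Path(prefix)
    arrays = {"F": dec.subgraphs.weights}
    for s, act in enumerate(dec.activations):
        arrays[f"V_{s}"] = act.values
    np.savez(prefix.with_suffix(".npz"), **arrays)
    cfg = asdict(dec.config)
    meta = {
        "config": cfg,
        "n_channels": dec.subgraphs.edge_index.n_channels,
        "seizure_ids": [a.seizure_id for a in dec.activations],
        "objective_trace": dec.objective_trace,
        "restart_objectives": dec.restart_objectives,
        "selected_restart": dec.selected_restart,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_decomposition(prefix: str | Path) -> Decomposition:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    arrays = np.load(prefix.with_suffix(".npz"))
    cfg_d = meta["config"]
    cfg = BTNDConfig(
        K=cfg_d["K"],
        lam=cfg_d["lam"],
        base_fused=FusedLassoParams(**cfg_d["base_fused"]),
        per_seizure_fused=(
            [FusedLassoParams(**p) for p in cfg_d["per_seizure_fused"]]
            if cfg_d["per_seizure_fused"] is not None
            else None
        ),
        zeta=cfg_d["zeta"],
        n_restarts=cfg_d["n_restarts"],
        max_iter=cfg_d["max_iter"],
        rel_tol=cfg_d["rel_tol"],
        seed=cfg_d["seed"],
    )
    edge_index = EdgeIndex.from_n_channels(meta["n_channels"])
    subgraphs = SubgraphSet(weights=arrays["F"], edge_index=edge_index)
    activations = [
        ActivationProfiles(values=arrays[f"V_{s}"], seizure_id=sid)
        for s, sid in enumerate(meta["seizure_ids"])
    ]
    return Decomposition(
        subgraphs=subgraphs,
        activations=activations,
        config=cfg,
        objective_trace=meta["objective_trace"],
        restart_objectives=meta["restart_objectives"],
        selected_restart=meta["selected_restart"],
    )


# ------------------------------------------------------------------- exports


def _edge_endpoint_labels(
    edge_index: EdgeIndex, channel_labels: list[str] | None
) -> list[tuple[str, str]]:
    if channel_labels:
        return [(channel_labels[i], channel_labels[j]) for i, j in edge_index.pairs]
    return [(str(i), str(j)) for i, j in edge_index.pairs]


def subgraphs_to_csv(
    F: SubgraphSet,
    path: str | Path,
    channel_labels: list[str] | None = None,
) -> None:
    """Weighted edge list: contact_a, contact_b, weight, component."""
    ends = _edge_endpoint_labels(F.edge_index, channel_labels)
    rows = [
        {
            "contact_a": ends[l][0],
            "contact_b": ends[l][1],
            "weight": F.weights[l, k],
            "component": k,
        }
        for k in range(F.K)
        for l in range(F.L)
        if F.weights[l, k] != 0
    ]
    pd.DataFrame(rows, columns=["contact_a", "contact_b", "weight", "component"]).to_csv(
        path, index=False
    )


def subgraphs_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def subgraphs_to_graphml(
    F: SubgraphSet,
    path: str | Path,
    channel_labels: list[str] | None = None,
) -> None:
    """One graph holding every component; edge attributes ``weight_k<k>``."""
    ends = _edge_endpoint_labels(F.edge_index, channel_labels)
    g = nx.Graph()
    for l, (a, b) in enumerate(ends):
        attrs = {
            f"weight_k{k}": float(F.weights[l, k])
            for k in range(F.K)
            if F.weights[l, k] != 0
        }
        if attrs:
            g.add_edge(a, b, **attrs)
    nx.write_graphml(g, str(path))


def activations_to_csv(
    act: ActivationProfiles, path: str | Path, window_step_s: float = 1.0
) -> None:
    """Rows = windows with start times in seconds, columns = components."""
    df = pd.DataFrame(
        act.values, columns=[f"component_{k}" for k in range(act.K)]
    )
    df.insert(0, "time_s", np.arange(act.T) * window_step_s)
    df.to_csv(path, index=False)


# -------------------------------------------------------------- ground truth


def save_planted_model(truth: PlantedModel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    arrays = {"F_true": truth.true_subgraphs}
    for s, V in enumerate(truth.true_activations):
        arrays[f"V_true_{s}"] = V
    np.savez(prefix.with_suffix(".npz"), **arrays)
    meta = {
        "noise_sigma": truth.noise_sigma,
        "seed": truth.seed,
        "n_seizures": len(truth.true_activations),
        "supports": {f"{s},{k}": list(v) for (s, k), v in truth.supports.items()},
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_planted_model(prefix: str | Path) -> PlantedModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    arrays = np.load(prefix.with_suffix(".npz"))
    supports = {
        tuple(int(x) for x in key.split(",")): tuple(val)
        for key, val in meta["supports"].items()
    }
    return PlantedModel(
        true_subgraphs=arrays["F_true"],
        true_activations=[
            arrays[f"V_true_{s}"] for s in range(meta["n_seizures"])
        ],
        noise_sigma=meta["noise_sigma"],
        seed=meta["seed"],
        supports=supports,
    )
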