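"""File dialects: network YAML, rate-series CSV, decomposition CSV + JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import (
    ConnectionSpec,
    InputSchedule,
    NetworkSpec,
    NeuronParameters,
    PopulationSpec,
    SimulationResult,
    MN_POOLS,
)
from .decomposition import SynergyDecomposition
from .preprocessing import Recording

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "network_diagnostics",
    "save_rates",
    "load_recording",
    "save_decomposition",
]

_NEURON_FIELDS = (
    "v_rest", "delta_T", "v_thres", "tau", "v_spike", "v_reset",
    "t_refractory", "sigma_noise",
)


def network_to_dict(net: NetworkSpec) -> dict:
    return {
        "dt_ms": net.dt,
        "rate_sample_interval_ms": net.rate_sample_interval,
        "seed": net.seed,
        "populations": [
            {
                "name": p.name,
                "ensemble_size": p.ensemble_size,
                "neuron_params": {f: getattr(p.neuron_params, f) for f in _NEURON_FIELDS},
            }
            for p in net.populations
        ],
        "connections": [
            {
                "target": c.target,
                "source": c.source,
                "efficacy_mV": c.efficacy,
                "n_connections": c.n_connections,
                "delay_ms": c.delay,
                **({"rate_hz": c.rate_hz} if c.rate_hz is not None else {}),
            }
            for c in net.connections
        ],
        "inputs": [
            {"name": s.name, "breakpoints": [[t, r] for t, r in s.breakpoints]}
            for s in net.inputs
        ],
    }


def network_from_dict(doc: dict) -> NetworkSpec:
    pops = [
        PopulationSpec(
            p["name"],
            NeuronParameters(**p.get("neuron_params", {})),
            int(p.get("ensemble_size", 500)),
        )
        for p in doc["populations"]
    ]
    conns = [
        ConnectionSpec(
            target=c["target"],
            source=c["source"],
            efficacy=float(c["efficacy_mV"]),
            n_connections=float(c["n_connections"]),
            delay=float(c.get("delay_ms", 0.0)),
            rate_hz=(float(c["rate_hz"]) if c.get("rate_hz") is not None else None),
        )
        for c in doc["connections"]
    ]
    inputs = [
        InputSchedule(s["name"], tuple((float(t), float(r)) for t, r in s["breakpoints"]))
        for s in doc.get("inputs", [])
    ]
    return NetworkSpec(
        populations=pops,
        connections=conns,
        inputs=inputs,
        dt=float(doc.get("dt_ms", 0.1)),
        rate_sample_interval=float(doc.get("rate_sample_interval_ms", 2.0)),
        seed=int(doc.get("seed", 0)),
    )


def save_network(net: NetworkSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def load_network(path: str | Path) -> NetworkSpec:
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))


def network_diagnostics(doc: dict) -> list[str]:
    """Non-throwing schema/invariant checks on a network document.

    Returns one message per violation, naming the offending row.
    """
    out: list[str] = []
    pop_names = {p.get("name") for p in doc.get("populations", [])}
    input_names = {s.get("name") for s in doc.get("inputs", [])}
    if len(pop_names) != len(doc.get("populations", [])):
        out.append("duplicate population names")
    for p in doc.get("populations", []):
        if int(p.get("ensemble_size", 500)) < 1:
            out.append(f"population {p.get('name')}: ensemble_size must be >= 1")
        try:
            NeuronParameters(**p.get("neuron_params", {}))
        except (ValueError, TypeError) as e:
            out.append(f"population {p.get('name')}: {e}")
    for i, c in enumerate(doc.get("connections", [])):
        row = f"connection[{i}] {c.get('target')} <- {c.get('source')}"
        if float(c.get("delay_ms", 0.0)) < 0:
            out.append(f"{row}: delay must be >= 0")
        if float(c.get("efficacy_mV", 0.0)) == 0:
            out.append(f"{row}: efficacy must be nonzero")
        if float(c.get("n_connections", 0.0)) <= 0:
            out.append(f"{row}: n_connections must be > 0")
        if c.get("rate_hz") is not None and float(c["rate_hz"]) < 0:
            out.append(f"{row}: rate_hz must be >= 0")
        if c.get("target") not in pop_names:
            out.append(f"{row}: unknown target population")
        src = c.get("source")
        if src not in pop_names and src not in input_names and c.get("rate_hz") is None:
            out.append(f"{row}: unknown source population or input")
    for s in doc.get("inputs", []):
        ts = [t for t, _ in s.get("breakpoints", [])]
        rs = [r for _, r in s.get("breakpoints", [])]
        if not ts:
            out.append(f"input {s.get('name')}: empty schedule")
            continue
        if any(np.diff(ts) <= 0):
            out.append(f"input {s.get('name')}: times must be strictly increasing")
        if any(r < 0 for r in rs):
            out.append(f"input {s.get('name')}: rates must be >= 0")
    return out


def save_rates(
    result: SimulationResult,
    path: str | Path,
    include_interneurons: bool = False,
) -> None:
    """Rate series as CSV (``time_ms`` plus one column per population)."""
    names = list(result.rates) if include_interneurons else [
        n for n in result.rates if n in MN_POOLS
    ]
    result.to_frame(names).to_csv(path, index=False, float_format="%.6g")


def load_recording(path: str | Path) -> Recording:
    return Recording.from_frame(pd.read_csv(path))


def save_decomposition(dec: SynergyDecomposition, prefix: str | Path) -> None:
    """``<prefix>_W.csv``, ``<prefix>_C.csv`` and a ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    pd.DataFrame(
        dec.W, index=dec.channels,
        columns=[f"synergy{s + 1}" for s in range(dec.rank)],
    ).to_csv(prefix.with_name(prefix.name + "_W.csv"))
    pd.DataFrame(
        dec.C.T, columns=[f"synergy{s + 1}" for s in range(dec.rank)]
    ).to_csv(prefix.with_name(prefix.name + "_C.csv"), index=False, float_format="%.6g")
    sidecar = {
        "rank": dec.rank,
        "vaf_global": dec.vaf_global,
        "vaf_per_muscle": dict(zip(dec.channels, map(float, dec.vaf_per_muscle))),
        "converged": dec.converged,
        "normalized": dec.normalized,
        "meta": {k: v for k, v in dec.meta.items()
                 if isinstance(v, (str, int, float, bool, type(None)))},
    }
    with open(prefix.with_name(prefix.name + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
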