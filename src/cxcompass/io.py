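"""Serialization: weight matrices, spike rasters, configuration files,
and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_weight_matrix",
    "load_weight_matrix",
    "save_spike_raster",
    "load_spike_raster",
    "config_to_dict",
    "config_from_dict",
    "load_config_file",
    "save_config_file",
    "write_manifest",
]


def save_weight_matrix(
    W: np.ndarray, path, row_population: str = "epg", col_population: str = "ring"
) -> None:
    """Write a weight matrix as CSV with a header naming the populations
    (rows = postsynaptic, columns = presynaptic)."""
    W = np.asarray(W, dtype=float)
    cols = [f"{col_population}_{m}" for m in range(W.shape[1])]
    df = pd.DataFrame(W, columns=cols)
    df.insert(0, "post", [f"{row_population}_{n}" for n in range(W.shape[0])])
    df.to_csv(path, index=False, float_format="%.17g")


def load_weight_matrix(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["post"]).to_numpy(dtype=float)


def save_spike_raster(spikes: np.ndarray, dt: float, path) -> None:
    """Write a (T, N) binary spike record as sparse CSV (t, neuron_id)."""
    t_idx, n_idx = np.nonzero(np.asarray(spikes))
    pd.DataFrame({"t": t_idx * dt, "neuron_id": n_idx}).to_csv(
        path, index=False, float_format="%.6g"
    )


def load_spike_raster(path, n_neurons: int, n_steps: int, dt: float) -> np.ndarray:
    df = pd.read_csv(path)
    out = np.zeros((n_steps, n_neurons), dtype=bool)
    out[np.round(df["t"].to_numpy() / dt).astype(int), df["neuron_id"].to_numpy()] = True
    return out


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(config) -> dict:
    """ModelConfig (nested dataclasses) -> plain dict."""
    return _asdict(config)


def config_from_dict(d: dict):
    """Plain dict (e.g. parsed YAML) -> ModelConfig; unknown keys are a
    configuration error."""
    from .encoding import AngularVelocityEncoder, NoiseModel, RingTuningBank
    from .model import ModelConfig
    from .network import LIFParams
    from .plasticity import ErrorMinParams, HebbianParams, OfflineFitSpec

    d = dict(d)
    sub = {
        "lif": LIFParams,
        "bank": RingTuningBank,
        "av_enc": AngularVelocityEncoder,
        "noise": NoiseModel,
        "hebbian": HebbianParams,
        "errmin": ErrorMinParams,
        "offline": OfflineFitSpec,
    }
    kwargs = {}
    for key, cls in sub.items():
        if key in d:
            params = dict(d.pop(key))
            if key == "av_enc":
                params.pop("lif", None)
                kwargs[key] = cls(lif=kwargs.get("lif", LIFParams()), **params)
            else:
                kwargs[key] = cls(**params)
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(d)
    return ModelConfig(**kwargs)


def load_config_file(path):
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config_file(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def write_manifest(path, config, seed: int, extra: dict | None = None) -> None:
    """Reproducibility manifest: package version, seed, and a hash of the
    full configuration."""
    from . import __version__

    blob = yaml.safe_dump(config_to_dict(config), sort_keys=True).encode()
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
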