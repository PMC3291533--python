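"""Serialization of model parameters and run configuration.

Parameters are stored as a JSON metadata file plus an ``.npz`` array
container next to it; the round trip is bit exact.  A content hash over the
raw float64 bytes identifies a parameter set across platforms.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import MGSMParams

FORMAT_NAME = "mgsm-params"
FORMAT_VERSION = 1

_ARRAY_KEYS = ("C_c", "C_s", "C_cs", "priors")


class SchemaError(ValueError):
    pass


def params_hash(params: MGSMParams) -> str:
    h = hashlib.sha256()
    for key in _ARRAY_KEYS:
        h.update(np.ascontiguousarray(
            getattr(params, key), dtype=np.float64).tobytes())
    h.update(np.float64(params.rayleigh_scale).tobytes())
    h.update(np.float64(params.epsilon).tobytes())
    return h.hexdigest()


def save_params(params: MGSMParams, path) -> Path:
    """Write ``<path>.json`` + ``<path>.npz`` (``.json`` suffix optional)."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".json" else path
    np.savez(base.with_suffix(".npz"),
             **{k: np.asarray(getattr(params, k), dtype=np.float64)
                for k in _ARRAY_KEYS})
    meta = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "arrays": base.with_suffix(".npz").name,
        "rayleigh_scale": params.rayleigh_scale,
        "epsilon": params.epsilon,
        "forced_component": params.forced_component,
        "n_center": params.n_center,
        "n_groups": params.n_groups,
        "group_size": params.group_size,
        "hash": params_hash(params),
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return base.with_suffix(".json")


def load_params(path) -> MGSMParams:
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    with open(path) as fh:
        meta = json.load(fh)
    if meta.get("format") != FORMAT_NAME:
        raise SchemaError(f"not a {FORMAT_NAME} file: {path}")
    if meta.get("version") != FORMAT_VERSION:
        raise SchemaError(
            f"unsupported version {meta.get('version')} (expected {FORMAT_VERSION})")
    with np.load(path.parent / meta["arrays"]) as npz:
        arrays = {}
        for k in _ARRAY_KEYS:
            if k not in npz:
                raise SchemaError(f"missing array {k!r} in {meta['arrays']}")
            arrays[k] = npz[k]
    params = MGSMParams(**arrays, rayleigh_scale=meta["rayleigh_scale"],
                        epsilon=meta["epsilon"],
                        forced_component=meta.get("forced_component"))
    if meta.get("hash") and meta["hash"] != params_hash(params):
        raise SchemaError("parameter content does not match stored hash")
    return params


def covariance_summary(params: MGSMParams):
    """Per-component variances and center-surround covariances, tidy CSV-able.

    One row per (component, filter): the filter's variance under that
    component, and for surround filters the covariance with the center filter
    of the same orientation and phase.
    """
    import pandas as pd

    rows = []
    nk = params.n_center
    n_or = nk // 2
    for g in range(params.n_groups):
        C = params.C_cs[g]
        for j in range(C.shape[0]):
            is_center = j < nk
            ori = (j // 2) if is_center else g
            ph = j % 2
            partner = 2 * ori + ph if not is_center else None
            rows.append({
                "component": f"coassigned_{g}",
                "filter": "center" if is_center else "surround",
                "orientation_index": ori,
                "phase": "even" if ph == 0 else "odd",
                "position": -1 if is_center else (j - nk) // 2,
                "variance": C[j, j],
                "cov_with_center": np.nan if is_center else C[j, partner],
            })
    for j in range(nk):
        rows.append({"component": "independent", "filter": "center",
                     "orientation_index": j // 2,
                     "phase": "even" if j % 2 == 0 else "odd",
                     "position": -1, "variance": params.C_c[j, j],
                     "cov_with_center": np.nan})
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Reproducible description of a full run (training + experiments)."""

    seed: int = 0
    filterbank: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    experiments: dict = field(default_factory=dict)
    out_dir: str = "mgsm_out"

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
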