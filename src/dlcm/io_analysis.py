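"""Configuration files, snapshot/event-log writers, multi-trial
aggregation and summary metrics.

Snapshots and event logs are plain CSV with documented, stable column
orders and full-precision numbers, so equal seeds give byte-identical
outputs.  Configurations are YAML with one section per concern; unknown
keys are rejected and defaults are the experiment's standard parameter
sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, MetricsError
from .experiments import (DeltaNotchParams, NotchConfig, RelaxationConfig,
                          SlitConfig, TumourConfig, TumourParams)
from .grid import Grid

__all__ = [
    "load_config", "save_config", "config_to_dict",
    "average_density", "shape_metrics",
    "write_snapshot", "read_snapshot", "write_event_log", "read_event_log",
]

_EXPERIMENTS = {
    "relax": RelaxationConfig,
    "slit": SlitConfig,
    "notch": NotchConfig,
    "tumour": TumourConfig,
}
_PARAMS_CLS = {"notch": DeltaNotchParams, "tumour": TumourParams}
_TUPLE_FIELDS = {"extent", "snapshot_times"}


def load_config(path):
    """Load and validate an experiment configuration.

    The file is YAML with a required ``experiment`` key (``relax``,
    ``slit``, ``notch`` or ``tumour``); the remaining keys set fields of
    the corresponding configuration dataclass, with the experiment's
    standard parameter set as defaults.  Unknown keys, missing structure
    and out-of-range values raise :class:`ConfigurationError`.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except OSError as err:
        raise ConfigurationError(f"cannot read config {path}: {err}") from err
    except yaml.YAMLError as err:
        raise ConfigurationError(f"malformed YAML in {path}: {err}") from err
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict):
    raw = dict(raw)
    name = raw.pop("experiment", None)
    if name not in _EXPERIMENTS:
        raise ConfigurationError(
            f"missing or unknown experiment {name!r}; "
            f"expected one of {sorted(_EXPERIMENTS)}")
    cls = _EXPERIMENTS[name]
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys for {name}: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key == "params" and name in _PARAMS_CLS:
            if not isinstance(value, dict):
                raise ConfigurationError("params must be a mapping")
            pcls = _PARAMS_CLS[name]
            pfields = {f.name for f in dataclasses.fields(pcls)}
            bad = set(value) - pfields
            if bad:
                raise ConfigurationError(
                    f"unknown params keys: {sorted(bad)}")
            value = pcls(**value)
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigurationError(f"invalid {name} config: {err}") from err


def config_to_dict(config) -> dict:
    """Serializable dict form (inverse of :func:`config_from_dict`)."""
    for name, cls in _EXPERIMENTS.items():
        if isinstance(config, cls):
            break
    else:
        raise ConfigurationError(f"not an experiment config: {type(config)!r}")
    out = {"experiment": name}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            value = dataclasses.asdict(value)
        elif isinstance(value, tuple):
            value = list(value)
        out[f.name] = value
    return out


def save_config(config, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False))


def config_hash(config) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# aggregation and metrics

def average_density(snapshots) -> np.ndarray:
    """Per-voxel mean living-cell count over a collection of same-grid,
    same-time occupancy snapshots: ``mean(max(u, 0))``, values in [0, 2]."""
    arrays = [np.maximum(np.asarray(getattr(s, "u", s)), 0) for s in snapshots]
    if not arrays:
        raise MetricsError("empty snapshot collection")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise MetricsError("snapshots live on different grids")
    return np.mean(arrays, axis=0)


def shape_metrics(density: np.ndarray, grid: Grid) -> dict:
    """Mass-weighted shape summary of a nonnegative density field.

    ``effective_area`` is the measure covered by the population at the
    reference packing of one cell per voxel (``sum density * voxel
    measure``), ``equal_area_radius`` the radius of the circle (2D) or
    sphere (3D) with that measure, and ``anisotropy`` the max/min
    eigenvalue ratio of the central second-moment tensor minus one (zero
    for an isotropic cloud).
    """
    rho = np.asarray(density, dtype=float)
    if np.any(rho < 0):
        raise MetricsError("density field must be nonnegative")
    w = rho * grid.voxel_measure
    mass = w.sum()
    if mass <= 0:
        raise MetricsError("shape metrics undefined for an all-zero field")
    centroid = (w[:, None] * grid.centers).sum(axis=0) / mass
    dx = grid.centers - centroid
    tensor = (w[:, None, None] * dx[:, :, None] * dx[:, None, :]).sum(axis=0) / mass
    eig = np.linalg.eigvalsh(tensor)
    if grid.dim == 2:
        radius = math.sqrt(mass / math.pi)
    else:
        radius = (3.0 * mass / (4.0 * math.pi)) ** (1.0 / 3.0)
    return {
        "effective_area": float(mass),
        "equal_area_radius": float(radius),
        "centroid": centroid,
        "second_moment_tensor": tensor,
        "directional_second_moments": np.diag(tensor).copy(),
        "eigenvalues": eig,
        "anisotropy": float(eig[-1] / eig[0] - 1.0) if eig[0] > 0 else math.inf,
    }


# ---------------------------------------------------------------------------
# writers

def write_snapshot(snapshot, path, cells_path=None) -> None:
    """Write one snapshot as CSV.

    Per-voxel columns, in stable order: ``time, voxel, u, visited`` then
    one column per scalar field (sorted by name), numbers at full
    precision.  If ``cells_path`` is given and the snapshot carries
    per-cell internal states, a second CSV is written with
    ``time, cell_id, voxel, s0, s1, ...``.
    """
    n = snapshot.u.shape[0]
    data = {"time": np.full(n, snapshot.t), "voxel": np.arange(n),
            "u": snapshot.u, "visited": snapshot.visited.astype(int)}
    for name in sorted(snapshot.fields):
        data[name] = snapshot.fields[name]
    try:
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    except OSError as err:
        raise OSError(f"writing snapshot to {path}: {err}") from err
    if cells_path is not None and snapshot.internal:
        rows = []
        for cid in sorted(snapshot.internal):
            vec = snapshot.internal[cid]
            rows.append({"time": snapshot.t, "cell_id": cid,
                         "voxel": snapshot.cells.get(cid, -1),
                         **{f"s{k}": v for k, v in enumerate(vec)}})
        pd.DataFrame(rows).to_csv(cells_path, index=False,
                                  float_format="%.17g")


def read_snapshot(path):
    """Read a voxel snapshot CSV back: ``(t, u, visited, fields)``."""
    df = pd.read_csv(path)
    t = float(df["time"].iloc[0])
    u = df["u"].to_numpy(dtype=np.int8)
    visited = df["visited"].to_numpy(dtype=bool)
    fields = {c: df[c].to_numpy(dtype=float)
              for c in df.columns if c not in ("time", "voxel", "u", "visited")}
    return t, u, visited, fields


def write_event_log(events, path) -> None:
    """Write the applied-event log as CSV with columns
    ``time, kind, source, dest, cell_id`` (one row per applied event)."""
    with open(path, "w") as fh:
        fh.write("time,kind,source,dest,cell_id\n")
        for t, kind, i, j, cid in events:
            fh.write(f"{t!r},{kind},{i},{j},{cid}\n")


def read_event_log(path) -> pd.DataFrame:
    return pd.read_csv(path)
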