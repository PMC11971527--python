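"""Configuration and file I/O glue.

Conventions enforced here and assumed everywhere else:

* time series are delimited text with rows = time and columns = regions
  (T x N), TR carried in a JSON sidecar or supplied by the caller; an
  ``.npz`` container gives lossless binary round-trips;
* connectomes are square delimited-text matrices, optionally with a header
  row of region labels;
* run configurations are JSON or YAML mappings onto :class:`RunConfig`;
  unknown keys are rejected by name, and every run should serialize its
  resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .connectome import WeightedConnectome
from .exceptions import InvalidConfigurationError, InvalidInputError
from .fitting import FitConfig
from .simulate import DEFAULT_NOISE_SD, RegionalTimeSeries

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_timeseries",
    "write_timeseries",
    "read_connectome",
    "write_connectome",
]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved settings of a command-line run."""

    schema_version: int = SCHEMA_VERSION
    tr: float = 2.0
    band: tuple[float, float] = (0.01, 0.1)
    total_band: tuple[float, float] | None = None
    window_length: int = 30
    stride: int = 1
    max_iters: int = 300
    realizations_per_iter: int = 1
    learning_rate_mode: str = "fixed"
    learning_rate: float = 0.5
    normalization: str = "meanscale"
    g_grid: tuple[float, float, float] = (0.0, 2.0, 0.1)  # (start, stop, step)
    a0_grid: tuple[float, float, float] = (-0.05, 0.05, 0.01)
    beta: float = DEFAULT_NOISE_SD
    dt: float = 0.1
    burn_in: float = 60.0
    seed: int = 0
    trad_learning_rate: float = 2.0
    threshold_r: float = 0.05

    def fit_config(self) -> FitConfig:
        return FitConfig(
            max_iters=self.max_iters,
            realizations_per_iter=self.realizations_per_iter,
            learning_rate_mode=self.learning_rate_mode,
            learning_rate=self.learning_rate,
            normalization=self.normalization,
            window_length=self.window_length,
            stride=self.stride,
            band=tuple(self.band),
            total_band=tuple(self.total_band) if self.total_band else None,
            seed=self.seed,
            trad_learning_rate=self.trad_learning_rate,
            threshold_r=self.threshold_r,
        )

    def grid(self, which: str) -> np.ndarray:
        start, stop, step = getattr(self, f"{which}_grid")
        return np.round(np.arange(start, stop + step / 2, step), 10)


def load_config(path) -> RunConfig:
    """Load a JSON or YAML run configuration, validating keys.

    An empty file yields all defaults; unknown keys raise an error naming
    the offending key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise InvalidConfigurationError(f"config root must be a mapping, got {type(data)}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            raise InvalidConfigurationError(f"unknown configuration key {key!r}")
    if "schema_version" in data and data["schema_version"] != SCHEMA_VERSION:
        raise InvalidConfigurationError(
            f"unsupported schema_version {data['schema_version']}; expected {SCHEMA_VERSION}"
        )
    for key in ("band", "total_band", "g_grid", "a0_grid"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    """Serialize the resolved configuration as JSON."""
    d = dataclasses.asdict(cfg)
    Path(path).write_text(json.dumps(d, indent=2, default=list) + "\n")


def read_timeseries(path, tr: float | None = None) -> RegionalTimeSeries:
    """Read a T x N time series from delimited text or an ``.npz`` container.

    For text, a JSON sidecar ``<path>.json`` with ``{"tr": ...}`` supplies
    the TR unless given explicitly.  NaN cells and ragged rows are parse
    errors naming the line.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            values = z["values"]
            file_tr = float(z["tr"]) if "tr" in z else None
        use_tr = tr if tr is not None else file_tr
        if use_tr is None:
            raise InvalidInputError("TR missing: not in container and not supplied")
        return RegionalTimeSeries(values, use_tr)
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if any(not np.isfinite(v) for v in row):
                raise InvalidInputError(f"{path}:{lineno}: non-finite value")
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise InvalidInputError(
                    f"{path}:{lineno}: ragged row ({len(row)} columns, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise InvalidInputError(f"{path}: empty time-series file")
    if tr is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            tr = json.loads(sidecar.read_text()).get("tr")
    if tr is None:
        raise InvalidInputError("TR missing: pass tr= or provide a JSON sidecar")
    return RegionalTimeSeries(np.asarray(rows), tr)


def write_timeseries(ts: RegionalTimeSeries, path, sidecar: bool = True) -> None:
    """Write a time series as text (``.npz`` path for lossless binary)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, values=ts.values, tr=ts.tr)
        return
    np.savetxt(path, ts.values, fmt="%.9g", delimiter="\t")
    if sidecar:
        meta = {"tr": ts.tr}
        if ts.band is not None:
            meta["band"] = list(ts.band)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta) + "\n")


def read_connectome(path) -> WeightedConnectome:
    """Read a square connectivity matrix, optional header row of labels."""
    path = Path(path)
    labels: list[str] = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if not rows and not labels:
                try:
                    float(parts[0])
                except ValueError:
                    labels = parts
                    continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise InvalidInputError(f"{path}: empty connectome file")
    w = np.asarray(rows)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidInputError(f"{path}: matrix must be square, got {w.shape}")
    if np.any(w < 0):
        raise InvalidInputError(f"{path}: negative weights")
    return WeightedConnectome(w, labels)


def write_connectome(c: WeightedConnectome, path, header: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(c.labels) + "\n")
        np.savetxt(fh, c.weights, fmt="%.9g", delimiter="\t")
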