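"""File I/O: recordings containers, tabular series, and run configuration.

Recordings travel as a single ``.npz`` container (binary, lossless); ISA and
BOLD series as tab-separated text with a ``#``-prefixed metadata header.  Run
configuration is YAML with a fixed schema: unknown keys are rejected and
every missing key takes its documented default.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

from .experiment import Recordings

__all__ = [
    "save_recordings",
    "load_recordings",
    "write_series",
    "read_series",
    "SeriesFormatError",
    "ConfigError",
    "DEFAULT_CONFIG",
    "load_config",
    "dump_config",
]


class SeriesFormatError(ValueError):
    """A tabular series file is malformed; the message names the line."""


class ConfigError(ValueError):
    """A configuration file has unknown keys or mistyped values."""


# ---------------------------------------------------------------------------
# recordings container
# ---------------------------------------------------------------------------


def save_recordings(path: str | Path, rec: Recordings) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        dt_ms=rec.dt_ms,
        module_names=np.array(rec.module_names, dtype="U16"),
        host_names=np.array(list(rec.host_nodes), dtype="U16"),
        host_values=np.array(list(rec.host_nodes.values()), dtype=np.int64),
        lsnm_E=rec.lsnm_E,
        lsnm_I=rec.lsnm_I,
        tvb_E=rec.tvb_E,
        input_bin_ms=rec.input_bin_ms,
        in_units=rec.in_units,
        in_nodes=rec.in_nodes,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_recordings(path: str | Path) -> Recordings:
    with np.load(path) as z:
        return Recordings(
            dt_ms=float(z["dt_ms"]),
            module_names=[str(s) for s in z["module_names"]],
            host_nodes={
                str(k): int(v) for k, v in zip(z["host_names"], z["host_values"])
            },
            lsnm_E=z["lsnm_E"],
            lsnm_I=z["lsnm_I"],
            tvb_E=z["tvb_E"],
            input_bin_ms=float(z["input_bin_ms"]),
            in_units=z["in_units"],
            in_nodes=z["in_nodes"],
        )


# ---------------------------------------------------------------------------
# tabular series (ISA / BOLD)
# ---------------------------------------------------------------------------


def write_series(
    path: str | Path,
    series: dict[str, np.ndarray],
    interval_s: float,
    meta: dict[str, str] | None = None,
) -> Path:
    """Write named series sampled on a common grid as TSV with a header."""
    path = Path(path)
    names = list(series)
    lengths = {len(np.asarray(v)) for v in series.values()}
    if len(lengths) > 1:
        raise ValueError("all series must share one length")
    n = lengths.pop() if lengths else 0
    with open(path, "w") as fh:
        fh.write(f"# interval_s: {interval_s}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_s\t" + "\t".join(names) + "\n")
        for i in range(n):
            vals = "\t".join(f"{float(np.asarray(series[m])[i]):.10g}" for m in names)
            fh.write(f"{i * interval_s:.6g}\t{vals}\n")
    return path


def read_series(path: str | Path) -> tuple[dict[str, np.ndarray], float, dict[str, str]]:
    """Read a TSV series file; returns (series, interval_s, metadata)."""
    meta: dict[str, str] = {}
    names: list[str] | None = None
    rows: list[list[float]] = []
    interval = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise SeriesFormatError(f"line {ln}: malformed metadata")
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
                continue
            if names is None:
                names = line.split("\t")
                if not names or names[0] != "time_s":
                    raise SeriesFormatError(f"line {ln}: header must start with time_s")
                continue
            parts = line.split("\t")
            if len(parts) != len(names):
                raise SeriesFormatError(f"line {ln}: expected {len(names)} columns")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SeriesFormatError(f"line {ln}: non-numeric value") from exc
    if names is None:
        raise SeriesFormatError("file has no header line")
    if "interval_s" not in meta:
        raise SeriesFormatError("missing interval_s metadata")
    interval = float(meta.pop("interval_s"))
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(names))
    series = {name: data[:, j] for j, name in enumerate(names) if name != "time_s"}
    return series, interval, meta


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "connectome": {
        "n_nodes": 998,
        "density": 0.05,
        "decay_mm": 40.0,
        "weight_scale": 0.3,
        "seed": 0,
        "anchor_modules": True,  # pin nodes at the module target coordinates
    },
    "embedding": {
        "G": 0.05,
        "coupling_sd_frac": 0.1,
        "k_roi": 5,
        "on_collision": "next-nearest",
    },
    "dynamics": {
        "dt_ms": 5.0,
        "tvb_noise_sd": 0.02,
        "lsnm_noise_sd": 0.13,
        "conduction_speed": 3.0,
    },
    "experiment": {
        "n_blocks": 12,
        "attention_min": 0.24,
        "attention_max": 0.34,
        "ctl_attention": 0.05,
        "retention": 0.5,
        "n_subjects": 10,
        "min_accuracy": 60.0,
        "max_attempts": 50,
        "burn_in_s": 2.0,
    },
    "bold": {
        "tr_s": 2.0,
        "isa_window_ms": 50.0,
        "substeps": 1,
    },
    "stimulation": {
        "amplitude": 0.2,
    },
}


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            expected = type(defaults[key])
            if expected in (float, int) and isinstance(value, (int, float)) and not isinstance(value, bool):
                out[key] = expected(value)
            elif isinstance(value, expected):
                out[key] = value
            else:
                raise ConfigError(
                    f"config key {where}: expected {expected.__name__}, "
                    f"got {type(value).__name__}"
                )
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a YAML run configuration (defaults when omitted)."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        given = yaml.safe_load(fh) or {}
    if not isinstance(given, dict):
        raise ConfigError("configuration root must be a mapping")
    return _merge(DEFAULT_CONFIG, given)


def dump_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
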