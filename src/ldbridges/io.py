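"""File-format plumbing: TIFF images, CSV curves/tables, JSON results."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .bridge_kinetics import TimeCourse
from .frap import FrapCurve
from .tensiometry import DropSeries

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_timecourse_csv",
    "read_timecourse_csv",
    "write_frap_csv",
    "read_frap_csv",
    "write_drops_csv",
    "read_drops_csv",
    "write_result_json",
    "config_hash",
]


def write_field_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_field_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_timecourse_csv(path, tc: TimeCourse) -> None:
    pd.DataFrame({"t_min": tc.t_min, "intensity": tc.intensity}).to_csv(path, index=False)


def read_timecourse_csv(path) -> TimeCourse:
    df = pd.read_csv(path)
    return TimeCourse(t_min=df["t_min"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_frap_csv(path, curve: FrapCurve) -> None:
    df = pd.DataFrame({"t_s": curve.t_s, "intensity": curve.intensity})
    with open(path, "w") as fh:
        fh.write(
            f"# bleach_width_um={curve.bleach_width_um} bleach_depth={curve.bleach_depth}\n"
        )
        df.to_csv(fh, index=False)


def read_frap_csv(path, bleach_width_um: float | None = None, bleach_depth: float | None = None) -> FrapCurve:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, v = tok.split("=")
                meta[k] = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    width = bleach_width_um if bleach_width_um is not None else meta.get("bleach_width_um")
    depth = bleach_depth if bleach_depth is not None else meta.get("bleach_depth")
    if width is None or depth is None:
        raise ValueError("bleach_width_um and bleach_depth must be given or stored in the file")
    return FrapCurve(
        t_s=df["t_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        bleach_width_um=float(width),
        bleach_depth=float(depth),
    )


def write_drops_csv(path, series: DropSeries) -> None:
    df = pd.DataFrame({"drop_volume_uL": series.drop_volume_uL})
    with open(path, "w") as fh:
        fh.write(
            f"# tube_diameter_um={series.tube_diameter_um} "
            f"delta_rho_kg_m3={series.delta_rho_kg_m3} g_m_s2={series.g_m_s2}\n"
        )
        df.to_csv(fh, index=False)


def read_drops_csv(
    path,
    tube_diameter_um: float | None = None,
    delta_rho_kg_m3: float | None = None,
) -> DropSeries:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, v = tok.split("=")
                meta[k] = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    d = tube_diameter_um if tube_diameter_um is not None else meta.get("tube_diameter_um")
    rho = delta_rho_kg_m3 if delta_rho_kg_m3 is not None else meta.get("delta_rho_kg_m3")
    if d is None or rho is None:
        raise ValueError("tube diameter and density difference must be given or stored")
    return DropSeries(
        drop_volume_uL=df["drop_volume_uL"].to_numpy(),
        tube_diameter_um=float(d),
        delta_rho_kg_m3=float(rho),
        g_m_s2=float(meta.get("g_m_s2", 9.81)),
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result_json(path, payload: dict, config: dict | None = None) -> None:
    """Write a result bundle with a provenance block (version, config hash)."""
    out = {
        "provenance": {
            "package": "ldbridges",
            "version": __version__,
            "config_hash": config_hash(config or {}),
        },
        "results": _jsonable(payload),
    }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
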