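"""Readers/writers and run configuration.

CSV schemas
-----------
titration : ``f,activity,experiment[,field]``
traces    : ``time_s,intensity,label``
counts    : ``experiment,field,count``

Images travel as TIFF: either three single-channel files per cell with
filename suffixes ``_donor`` / ``_acceptor`` / ``_fret``, or one 3-page
multichannel TIFF with a page->role mapping.  Regions and masks use 0-based
row-major half-open index conventions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .assay_stats import FluorescenceTrace
from .pixel_fret import ChannelImage, FretImageSet
from .stoichiometry import TitrationCurve, TitrationPoint

__all__ = [
    "RunConfig",
    "read_titration_csv",
    "write_titration_csv",
    "read_trace_csv",
    "read_counts_csv",
    "read_fret_tiffs",
    "write_fret_tiffs",
    "write_nfret_tiff",
    "write_report",
    "load_config",
]

_CONFIG_KEYS = {
    "seed",
    "out_dir",
    "background_percentile",
    "blur_sigma",
    "sbt_kind",
    "low_intensity_cutoff",
    "min_intensity",
    "nfret_scale",
    "bin_width",
    "display_range",
    "max_components",
    "n_max",
    "init",
    "bounds",
    "verbosity",
}


@dataclass
class RunConfig:
    """Stage parameters with the pipeline's documented defaults."""

    seed: int = 0
    out_dir: str = "results"
    background_percentile: float = 50.0
    blur_sigma: float = 1.0
    sbt_kind: str = "exponential"
    low_intensity_cutoff: float = 50.0
    min_intensity: float = 5.0
    nfret_scale: float = 1.0
    bin_width: float = 10.0 / 256.0
    display_range: tuple = (0.0, 10.0)
    max_components: int = 4
    n_max: int = 20
    init: tuple = (5.0, 3.0)
    bounds: tuple = ((1.0, 30.0), (1.0, 100.0))
    verbosity: str = "info"

    def to_dict(self) -> dict:
        d = {}
        for k in sorted(_CONFIG_KEYS):
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    for k, v in raw.items():
        default = getattr(cfg, k)
        if isinstance(default, tuple):
            v = tuple(tuple(x) if isinstance(x, (list, tuple)) else x for x in v)
        setattr(cfg, k, v)
    return cfg


def read_titration_csv(path) -> TitrationCurve:
    """Read a ``f,activity,experiment[,field]`` table into a TitrationCurve.

    Malformed rows raise a parse error naming the offending row number
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    required = {"f", "activity", "experiment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    points = []
    for i, row in df.iterrows():
        try:
            points.append(
                TitrationPoint(
                    f=float(row["f"]),
                    activity=float(row["activity"]),
                    experiment_id=str(row["experiment"]),
                    field_id=str(row["field"]) if "field" in df.columns else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
    return TitrationCurve(points)


def write_titration_csv(curve: TitrationCurve, path) -> None:
    df = pd.DataFrame(
        {
            "f": [p.f for p in curve.points],
            "activity": [p.activity for p in curve.points],
            "experiment": [p.experiment_id for p in curve.points],
            "field": [p.field_id if p.field_id is not None else "" for p in curve.points],
        }
    )
    df.to_csv(path, index=False)


def read_trace_csv(path) -> list[FluorescenceTrace]:
    """Read ``time_s,intensity,label`` rows into one trace per label."""
    df = pd.read_csv(path)
    required = {"time_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = ""
    traces = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            FluorescenceTrace(
                time=grp["time_s"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
                label=str(label),
            )
        )
    return traces


def read_counts_csv(path) -> dict:
    """Read ``experiment,field,count`` rows into {experiment: [counts]}."""
    df = pd.read_csv(path)
    required = {"experiment", "field", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(exp): grp["count"].astype(int).tolist()
        for exp, grp in df.groupby("experiment", sort=False)
    }


_SUFFIX_ROLES = {"_donor": "donor", "_acceptor": "acceptor", "_fret": "fret"}


def write_fret_tiffs(imgset: FretImageSet, directory, stem: Optional[str] = None) -> list:
    """Write one set as three single-channel float32 TIFFs with role suffixes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or imgset.cell_id or "cell"
    paths = []
    for suffix, role in _SUFFIX_ROLES.items():
        ch: ChannelImage = getattr(imgset, role)
        p = directory / f"{stem}{suffix}.tif"
        tifffile.imwrite(p, ch.pixels.astype(np.float32))
        paths.append(p)
    return paths


def _set_from_channels(channels: dict, cell_id: str) -> FretImageSet:
    return FretImageSet(
        donor=channels["donor"],
        acceptor=channels["acceptor"],
        fret=channels["fret"],
        cell_id=cell_id,
    )


def read_fret_tiffs(
    source, channel_map: Optional[Mapping[int, str]] = None
) -> tuple[list[FretImageSet], list[dict]]:
    """Assemble FretImageSets from TIFF files.

    ``source`` is either a directory of single-channel files named
    ``<cell>_donor.tif`` / ``<cell>_acceptor.tif`` / ``<cell>_fret.tif``,
    or one multipage TIFF with ``channel_map`` giving {page: role}.  Cells
    with missing channels or mismatched dimensions are rejected
    individually; returns (sets, error_records).
    """
    source = Path(source)
    sets, errors = [], []
    if source.is_file():
        pages = tifffile.imread(source)
        if channel_map is None:
            channel_map = {0: "donor", 1: "acceptor", 2: "fret"}
        try:
            channels = {
                role: ChannelImage(np.asarray(pages[page], dtype=float), role)
                for page, role in channel_map.items()
            }
            sets.append(_set_from_channels(channels, source.stem))
        except (ValueError, IndexError) as exc:
            errors.append({"cell": source.stem, "reason": str(exc)})
        return sets, errors

    by_cell: dict = {}
    for p in sorted(source.glob("*.tif*")):
        for suffix, role in _SUFFIX_ROLES.items():
            if p.stem.endswith(suffix):
                cell = p.stem[: -len(suffix)]
                by_cell.setdefault(cell, {})[role] = p
                break
    for cell, role_paths in sorted(by_cell.items()):
        missing = set(_SUFFIX_ROLES.values()) - set(role_paths)
        if missing:
            errors.append({"cell": cell, "reason": f"missing channels: {sorted(missing)}"})
            continue
        try:
            channels = {
                role: ChannelImage(tifffile.imread(p).astype(float), role)
                for role, p in role_paths.items()
            }
            sets.append(_set_from_channels(channels, cell))
        except ValueError as exc:
            errors.append({"cell": cell, "reason": str(exc)})
    return sets, errors


def write_nfret_tiff(values: np.ndarray, path, display_range=(0.0, 10.0),
                     quantized: bool = False) -> None:
    """Write an NFRET image as float32, or 8-bit quantized over the range."""
    if quantized:
        lo, hi = display_range
        scaled = np.clip((values - lo) / (hi - lo) * 255.0, 0, 255)
        tifffile.imwrite(path, scaled.astype(np.uint8))
    else:
        tifffile.imwrite(path, values.astype(np.float32))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results, path, fmt: str = "json", config: Optional[RunConfig] = None) -> None:
    """Serialize results with stable key order, package version and config hash.

    JSON output is byte-identical for identical inputs and config.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = {
            "package_version": __version__,
            "config_hash": config.hash() if config is not None else None,
            "results": _jsonable(results),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        pd.DataFrame(results).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
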