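"""Delimited-text file formats for cine loops, Tur exports and configs.

No interchange standard exists for vector-flow cine data, so the package
defines a plain comma-separated format: ``#``-prefixed ``key=value`` header
lines followed by one record per (frame, grid point) with columns
``frame_index,x_mm,y_mm,vx_cm_s,vy_cm_s``.  The full grid is stored (points
outside the lumen carry zero velocity) and a write-read round trip preserves
velocities to better than 1e-9.  Per-frame Tur series are exported as CSV
with the ROI and acquisition metadata in the header, mirroring the
one-value-per-frame export of the scanner.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cine import CineLoop, TurSeries
from .simulate import CardiacWaveform, FlowConfig
from .turbulence import RoiSpec

__all__ = [
    "CineFormatError",
    "write_cine",
    "read_cine",
    "write_tur_export",
    "read_tur_export",
    "load_flow_config",
]

FORMAT_VERSION = "1"
_CINE_COLUMNS = ["frame_index", "x_mm", "y_mm", "vx_cm_s", "vy_cm_s"]


class CineFormatError(ValueError):
    """Raised for malformed cine or Tur-export files."""


def _read_header(path: Path) -> dict:
    header: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                raise CineFormatError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, value = body.partition("=")
            header[key.strip()] = value.strip()
    return header


def write_cine(loop: CineLoop, path: "Path | str") -> None:
    """Write a cine loop to the delimited-text format (one record per frame
    and grid point, full grid)."""
    path = Path(path)
    n_frames, ny, nx = loop.vx.shape
    header = {
        "format_version": FORMAT_VERSION,
        "n_frames": n_frames,
        "nx": nx,
        "ny": ny,
        "grid_spacing_mm": f"{loop.x[1] - loop.x[0]:.10g}" if nx > 1 else "0",
        "frame_rate_hz": f"{loop.frame_rate:.10g}",
        "heart_rate_bpm": f"{loop.heart_rate:.10g}",
        "vessel_diameter_mm": f"{loop.vessel_diameter:.10g}",
        "lumen_center_y_mm": f"{loop.lumen_center_y:.10g}",
        "stenosis_position_mm": (
            "none" if loop.stenosis_position is None else f"{loop.stenosis_position:.10g}"
        ),
        "config": json.dumps(loop.meta.get("config", {}), sort_keys=True),
    }
    xx, yy = np.meshgrid(loop.x, loop.y)
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(_CINE_COLUMNS) + "\n")
        for i in range(n_frames):
            block = np.column_stack(
                [
                    np.full(xx.size, i, dtype=float),
                    xx.ravel(),
                    yy.ravel(),
                    loop.vx[i].ravel(),
                    loop.vy[i].ravel(),
                ]
            )
            np.savetxt(fh, block, fmt=["%d", "%.10g", "%.10g", "%.12g", "%.12g"],
                       delimiter=",")


def read_cine(path: "Path | str") -> CineLoop:
    """Read a cine loop, validating header fields and record counts."""
    path = Path(path)
    header = _read_header(path)
    required = [
        "n_frames", "nx", "ny", "frame_rate_hz", "heart_rate_bpm",
        "vessel_diameter_mm", "lumen_center_y_mm",
    ]
    missing = [k for k in required if k not in header]
    if missing:
        raise CineFormatError(f"{path}: missing header field(s) {', '.join(missing)}")
    n_frames, nx, ny = (int(header[k]) for k in ("n_frames", "nx", "ny"))

    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises various parse errors
        raise CineFormatError(f"{path}: cannot parse records: {exc}") from exc
    if list(df.columns) != _CINE_COLUMNS:
        raise CineFormatError(
            f"{path}: expected columns {_CINE_COLUMNS}, found {list(df.columns)}"
        )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise CineFormatError(f"{path}: non-numeric record values: {exc}") from exc
    if not np.isfinite(df.to_numpy()).all():
        raise CineFormatError(f"{path}: non-finite record values")

    counts = df["frame_index"].value_counts()
    expected = nx * ny
    for frame in range(n_frames):
        got = int(counts.get(frame, 0))
        if got != expected:
            raise CineFormatError(
                f"{path}: frame {frame} has {got} records, expected {expected}"
            )
    if len(df) != n_frames * expected:
        raise CineFormatError(
            f"{path}: {len(df)} records total, expected {n_frames * expected}"
        )

    x = np.sort(df["x_mm"].unique())
    y = np.sort(df["y_mm"].unique())
    if x.size != nx or y.size != ny:
        raise CineFormatError(
            f"{path}: grid has {x.size} x {y.size} distinct coordinates, "
            f"header declares {nx} x {ny}"
        )
    dx = x[1] - x[0] if nx > 1 else 1.0
    dy = y[1] - y[0] if ny > 1 else 1.0
    ix = np.rint((df["x_mm"].to_numpy() - x[0]) / dx).astype(int)
    iy = np.rint((df["y_mm"].to_numpy() - y[0]) / dy).astype(int)
    fi = df["frame_index"].to_numpy(dtype=int)
    vx = np.zeros((n_frames, ny, nx))
    vy = np.zeros_like(vx)
    vx[fi, iy, ix] = df["vx_cm_s"].to_numpy()
    vy[fi, iy, ix] = df["vy_cm_s"].to_numpy()

    stenosis = header.get("stenosis_position_mm", "none")
    meta = {}
    if "config" in header:
        try:
            meta["config"] = json.loads(header["config"])
        except json.JSONDecodeError:
            meta["config"] = {}
    return CineLoop(
        x=x, y=y, vx=vx, vy=vy,
        frame_rate=float(header["frame_rate_hz"]),
        heart_rate=float(header["heart_rate_bpm"]),
        vessel_diameter=float(header["vessel_diameter_mm"]),
        lumen_center_y=float(header["lumen_center_y_mm"]),
        stenosis_position=None if stenosis == "none" else float(stenosis),
        meta=meta,
    )


def write_tur_export(series: TurSeries, path: "Path | str") -> None:
    """Export a per-frame Tur series as CSV (one value per frame)."""
    path = Path(path)
    roi = series.roi
    with open(path, "w") as fh:
        fh.write(f"# format_version={FORMAT_VERSION}\n")
        fh.write(f"# roi_center_x_mm={roi.center_x:.10g}\n")
        fh.write(f"# roi_width_mm={roi.width:.10g}\n")
        fh.write(f"# roi_top_y_mm={roi.top_y:.10g}\n")
        fh.write(f"# roi_bottom_y_mm={roi.bottom_y:.10g}\n")
        fh.write(f"# frame_rate_hz={series.frame_rate:.10g}\n")
        fh.write(f"# heart_rate_bpm={series.heart_rate:.10g}\n")
        fh.write("frame_index,tur_percent\n")
        for i, value in enumerate(series.values):
            fh.write(f"{i},{value:.12g}\n")


def read_tur_export(path: "Path | str") -> TurSeries:
    path = Path(path)
    header = _read_header(path)
    required = [
        "roi_center_x_mm", "roi_width_mm", "roi_top_y_mm", "roi_bottom_y_mm",
        "frame_rate_hz", "heart_rate_bpm",
    ]
    missing = [k for k in required if k not in header]
    if missing:
        raise CineFormatError(f"{path}: missing header field(s) {', '.join(missing)}")
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["frame_index", "tur_percent"]:
        raise CineFormatError(f"{path}: expected columns frame_index,tur_percent")
    roi = RoiSpec(
        center_x=float(header["roi_center_x_mm"]),
        width=float(header["roi_width_mm"]),
        top_y=float(header["roi_top_y_mm"]),
        bottom_y=float(header["roi_bottom_y_mm"]),
    )
    return TurSeries(
        values=df["tur_percent"].to_numpy(dtype=float),
        roi=roi,
        frame_rate=float(header["frame_rate_hz"]),
        heart_rate=float(header["heart_rate_bpm"]),
    )


def load_flow_config(path: "Path | str") -> tuple[FlowConfig, CardiacWaveform]:
    """Load a YAML flow configuration.

    Top-level keys are exactly the :class:`FlowConfig` field names; an
    optional ``waveform`` mapping holds :class:`CardiacWaveform` fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise CineFormatError(f"{path}: config must be a mapping")
    wf_raw = raw.pop("waveform", {}) or {}
    valid = set(FlowConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise CineFormatError(
            f"{path}: unknown config key(s) {', '.join(sorted(unknown))}"
        )
    wf_valid = set(CardiacWaveform.__dataclass_fields__)
    wf_unknown = set(wf_raw) - wf_valid
    if wf_unknown:
        raise CineFormatError(
            f"{path}: unknown waveform key(s) {', '.join(sorted(wf_unknown))}"
        )
    return FlowConfig(**raw), CardiacWaveform(**wf_raw)
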