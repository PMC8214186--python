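"""Readers and writers for the package's plain-text formats.

Channel series travel as CSV (columns ``t,red,green,blue``, seconds and
intensities) or JSON ({"nominal_rate": Hz, "t": [...], "red": [...], ...});
displacement tracks as CSV with a comment header declaring the dialect and
anchor (``# dialect=degrees anchor=32.8801,-117.2340``) and columns
``t,dx,dy``; GPX files with absolute track points are imported as a
convenience and converted to displacements.  Floats are written with 6
significant digits unless full precision is requested.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .gps import DisplacementTrack, absolute_to_displacements
from .errors import ValidationError
from .ppg import ChannelSeries, HrWindowEstimate


def _fmt(x: float, full_precision: bool = False) -> float:
    if full_precision or not isinstance(x, float) or not math.isfinite(x):
        return x
    return float(f"{x:.6g}")


def read_channel_series(path: str | Path, fmt: str | None = None,
                        nominal_rate: float | None = None) -> ChannelSeries:
    """Load a capture from CSV or JSON (format inferred from the suffix).

    For CSV input the nominal rate, if not given, is inferred from the
    median frame interval.  Validation failures (missing columns,
    non-monotone timestamps) raise ValidationError naming the offense.
    """
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = json.loads(path.read_text())
        try:
            rate = nominal_rate or float(payload["nominal_rate"])
            t = np.asarray(payload["t"], dtype=float)
            chans = {c: np.asarray(payload[c], dtype=float)
                     for c in ("red", "green", "blue")}
        except KeyError as exc:
            raise ValidationError(f"JSON capture missing key {exc}") from exc
    elif fmt == "csv":
        df = pd.read_csv(path, comment="#")
        missing = {"t", "red", "green", "blue"} - set(df.columns)
        if missing:
            raise ValidationError(f"CSV capture missing column(s) {sorted(missing)}")
        t = df["t"].to_numpy(dtype=float)
        chans = {c: df[c].to_numpy(dtype=float) for c in ("red", "green", "blue")}
        if nominal_rate is None:
            if t.size < 2:
                raise ValidationError("cannot infer nominal_rate from < 2 samples")
            rate = 1.0 / float(np.median(np.diff(t)))
        else:
            rate = nominal_rate
    else:
        raise ValidationError(f"unknown capture format {fmt!r}")
    return ChannelSeries(timestamps=t, nominal_rate=rate, **chans)


def write_channel_series(series: ChannelSeries, path: str | Path,
                         fmt: str | None = None, full_precision: bool = True) -> None:
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {
            "nominal_rate": series.nominal_rate,
            "t": [_fmt(v, full_precision) for v in series.timestamps.tolist()],
            "red": [_fmt(v, full_precision) for v in series.red.tolist()],
            "green": [_fmt(v, full_precision) for v in series.green.tolist()],
            "blue": [_fmt(v, full_precision) for v in series.blue.tolist()],
        }
        path.write_text(json.dumps(payload))
    else:
        df = pd.DataFrame({"t": series.timestamps, "red": series.red,
                           "green": series.green, "blue": series.blue})
        df.to_csv(path, index=False,
                  float_format=None if full_precision else "%.6g")


def window_report_frame(estimates: list[HrWindowEstimate]) -> pd.DataFrame:
    """Tabulate per-window estimates in the canonical report schema."""
    rows = []
    for e in estimates:
        rows.append({
            "window_start": e.window_start, "window_end": e.window_end,
            "hr_red": e.hr_bpm.get("red"), "conf_red": e.confidence.get("red"),
            "hr_green": e.hr_bpm.get("green"), "conf_green": e.confidence.get("green"),
            "hr_fused": e.fused_hr_bpm, "conf_fused": e.fused_confidence,
            "source_channel": e.source_channel, "valid": e.valid,
        })
    return pd.DataFrame(rows)


def write_window_report(estimates: list[HrWindowEstimate], path: str | Path,
                        full_precision: bool = False) -> None:
    path = Path(path)
    df = window_report_frame(estimates)
    if path.suffix.lower() == ".json":
        recs = df.to_dict(orient="records")
        if not full_precision:
            recs = [{k: _fmt(v) if isinstance(v, float) else v for k, v in r.items()}
                    for r in recs]
        path.write_text(json.dumps(recs, indent=2))
    else:
        df.to_csv(path, index=False,
                  float_format=None if full_precision else "%.6g")


def read_displacement_track(path: str | Path,
                            anchor: tuple[float, float] | None = None) -> DisplacementTrack:
    """Load a 1 Hz displacement record from annotated CSV.

    The first comment line may declare ``# dialect=<meters|degrees>
    anchor=<lat>,<lon>``; an anchor passed as argument overrides the header.
    """
    path = Path(path)
    dialect = "meters"
    header_anchor = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        for tok in first.lstrip("#").split():
            if tok.startswith("dialect="):
                dialect = tok.split("=", 1)[1]
            elif tok.startswith("anchor="):
                lat, lon = tok.split("=", 1)[1].split(",")
                header_anchor = (float(lat), float(lon))
    df = pd.read_csv(path, comment="#")
    missing = {"dx", "dy"} - set(df.columns)
    if missing:
        raise ValidationError(f"track CSV missing column(s) {sorted(missing)}")
    samples = df[["dx", "dy"]].to_numpy(dtype=float)
    return DisplacementTrack(dialect, samples, anchor=anchor or header_anchor)


def write_displacement_track(track: DisplacementTrack, path: str | Path) -> None:
    path = Path(path)
    header = f"# dialect={track.dialect}"
    if track.anchor is not None:
        header += f" anchor={track.anchor[0]:.7f},{track.anchor[1]:.7f}"
    df = pd.DataFrame({
        "t": np.arange(1, track.samples.shape[0] + 1) / track.rate,
        "dx": track.samples[:, 0], "dy": track.samples[:, 1],
    })
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_gpx(path: str | Path, dialect: str = "meters") -> DisplacementTrack:
    """Import absolute track points from a GPX file as a displacement track."""
    tree = ET.parse(path)
    root = tree.getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag.split("}")[0] + "}"
    pts = [
        (float(el.get("lat")), float(el.get("lon")))
        for el in root.iter(f"{ns}trkpt")
    ]
    if len(pts) < 2:
        raise ValidationError("GPX file contains fewer than 2 track points")
    return absolute_to_displacements(np.asarray(pts), dialect=dialect)
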