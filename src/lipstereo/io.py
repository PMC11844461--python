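"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain comma-separated UTF-8 text with a required
header row and '.' decimal separator, chosen for interoperability with the
spreadsheet/statistics tooling used downstream.  Writers emit the shortest
round-tripping float representation, so write→read→write is byte-stable.
Readers validate strictly and raise :class:`~lipstereo.errors.ParseError`
with the offending file and line.

Formats
-------
* landmark track CSV: ``frame,landmark_id,x_px,y_px`` (0-based frames, one
  file per camera; the frame rate travels in the config, not the file);
* calibration JSON: intrinsics/distortion/extrinsics for both cameras,
  units fixed to millimetres;
* aperture CSV: ``t_s,la_mm`` (also the articulograph-export dialect);
* 3D point CSV: ``frame,landmark_id,X_mm,Y_mm,Z_mm``;
* correspondence CSV: ``camera_id,X_mm,Y_mm,Z_mm,x_px,y_px``;
* report JSON: nested validation reports, floats fixed to 9 significant
  digits for byte-identical reruns;
* WAV audio via :mod:`scipy.io.wavfile` (PCM 16/24/32-bit and float; the
  first channel of multi-channel files).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.io.wavfile

from .errors import LipStereoError, ParseError
from .geometry import CameraModel, StereoRig
from .kinematics import ApertureSeries
from .landmarks import LandmarkTrack2D
from .sync import AudioTrack

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "read_calibration",
    "write_calibration",
    "read_aperture_csv",
    "write_aperture_csv",
    "read_points3d_csv",
    "write_points3d_csv",
    "read_correspondences_csv",
    "write_correspondences_csv",
    "read_wav",
    "write_wav",
    "write_report_json",
    "read_report_json",
    "round9",
]


def round9(x: float) -> float:
    """Round to 9 significant digits (report determinism convention)."""
    return float(f"{float(x):.9g}")


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_float(value: str, path, line: int, column: str) -> float:
    try:
        v = float(value)
    except ValueError:
        raise ParseError(f"non-numeric {column} value {value!r}", path, line) from None
    if not np.isfinite(v):
        raise ParseError(f"non-finite {column} value {value!r}", path, line)
    return v


def _check_header(row, expected, path):
    if row is None:
        raise ParseError("empty file, expected header " + ",".join(expected), path, 1)
    if [c.strip() for c in row] != list(expected):
        raise ParseError(
            f"malformed header {row!r}, expected {','.join(expected)}", path, 1
        )


# ---------------------------------------------------------------------------
# Landmark tracks


def write_track_csv(track: LandmarkTrack2D, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "landmark_id", "x_px", "y_px"])
        for f in range(track.n_frames):
            for j, lid in enumerate(track.ids):
                w.writerow([f, lid, _fmt(track.xy[f, j, 0]), _fmt(track.xy[f, j, 1])])


def read_track_csv(path, fps: float, t0: float = 0.0) -> LandmarkTrack2D:
    """Read a per-camera landmark track.

    Every frame must carry the identical landmark id set and frames must be
    consecutive from 0; violations name the frame concerned.
    """
    path = Path(path)
    frames: dict[int, dict[str, tuple[float, float]]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), ("frame", "landmark_id", "x_px", "y_px"), path)
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(f"expected 4 fields, got {len(row)}", path, ln)
            try:
                f = int(row[0])
            except ValueError:
                raise ParseError(f"non-integer frame {row[0]!r}", path, ln) from None
            if f < 0:
                raise ParseError(f"negative frame index {f}", path, ln)
            lid = row[1].strip()
            if not lid:
                raise ParseError("empty landmark id", path, ln)
            x = _parse_float(row[2], path, ln, "x_px")
            y = _parse_float(row[3], path, ln, "y_px")
            bucket = frames.setdefault(f, {})
            if lid in bucket:
                raise ParseError(f"duplicate landmark {lid!r} in frame {f}", path, ln)
            bucket[lid] = (x, y)
    if not frames:
        raise ParseError("track file contains no data rows", path)
    n = max(frames) + 1
    if sorted(frames) != list(range(n)):
        missing = sorted(set(range(n)) - set(frames))[0]
        raise ParseError(f"missing frame {missing}", path)
    ids = tuple(sorted(frames[0]))
    xy = np.empty((n, len(ids), 2))
    for f in range(n):
        if tuple(sorted(frames[f])) != ids:
            diff = set(ids).symmetric_difference(frames[f])
            raise ParseError(
                f"frame {f} has a different landmark set (difference: {sorted(diff)})",
                path,
            )
        for j, lid in enumerate(ids):
            xy[f, j] = frames[f][lid]
    return LandmarkTrack2D(ids=ids, xy=xy, fps=fps, t0=t0)


# ---------------------------------------------------------------------------
# Calibration


_CAM_KEYS = {"fx", "fy", "cx", "cy", "dist", "R", "t"}


def _cam_to_dict(cam: CameraModel) -> dict:
    return {
        "fx": round9(cam.fx),
        "fy": round9(cam.fy),
        "cx": round9(cam.cx),
        "cy": round9(cam.cy),
        "dist": [round9(d) for d in cam.dist],
        "R": [[round9(v) for v in row] for row in cam.R],
        "t": [round9(v) for v in cam.t],
    }


def _cam_from_dict(d: dict, path, side: str) -> CameraModel:
    if not isinstance(d, dict):
        raise ParseError(f"camera {side!r} must be an object", path)
    unknown = set(d) - _CAM_KEYS
    if unknown:
        raise ParseError(f"camera {side!r} has unknown keys {sorted(unknown)}", path)
    missing = _CAM_KEYS - set(d)
    if missing:
        raise ParseError(f"camera {side!r} lacks keys {sorted(missing)}", path)
    try:
        return CameraModel(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            dist=tuple(float(x) for x in d["dist"]),
            R=np.asarray(d["R"], dtype=float),
            t=np.asarray(d["t"], dtype=float),
        )
    except (LipStereoError, TypeError, ValueError) as e:
        raise ParseError(f"invalid camera {side!r}: {e}", path) from e


def write_calibration(rig: StereoRig, path) -> None:
    payload = {
        "left": _cam_to_dict(rig.left),
        "right": _cam_to_dict(rig.right),
        "units": "mm",
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_calibration(path) -> StereoRig:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON: {e}", path) from e
    if not isinstance(payload, dict):
        raise ParseError("calibration must be a JSON object", path)
    unknown = set(payload) - {"left", "right", "units"}
    if unknown:
        raise ParseError(f"unknown keys {sorted(unknown)}", path)
    if payload.get("units") != "mm":
        raise ParseError(f"units must be 'mm', got {payload.get('units')!r}", path)
    left = _cam_from_dict(payload.get("left"), path, "left")
    right = _cam_from_dict(payload.get("right"), path, "right")
    try:
        return StereoRig(left=left, right=right)
    except LipStereoError as e:
        raise ParseError(f"invalid rig: {e}", path) from e


# ---------------------------------------------------------------------------
# Aperture series


def write_aperture_csv(series: ApertureSeries, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_s", "la_mm"])
        for t, v in zip(series.timestamps, series.values):
            w.writerow([_fmt(t), _fmt(v)])


def read_aperture_csv(path) -> ApertureSeries:
    """Read an aperture series; the rate is inferred from the (uniform)
    timestamp column.  Articulograph exports use the same dialect."""
    path = Path(path)
    ts, vs = [], []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), ("t_s", "la_mm"), path)
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"expected 2 fields, got {len(row)}", path, ln)
            ts.append(_parse_float(row[0], path, ln, "t_s"))
            vs.append(_parse_float(row[1], path, ln, "la_mm"))
    if len(ts) < 2:
        raise ParseError("aperture series needs at least 2 samples", path)
    dt = np.diff(ts)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0] + 1e-12:
        raise ParseError("timestamps are not uniformly increasing", path)
    rate = 1.0 / float(np.mean(dt))
    # Snap to an integer rate when within float tolerance (e.g. 250 Hz).
    if abs(rate - round(rate)) < 1e-6:
        rate = float(round(rate))
    return ApertureSeries(np.asarray(vs), rate=rate, t0=ts[0])


# ---------------------------------------------------------------------------
# 3D points


def write_points3d_csv(points: dict[str, np.ndarray], path) -> None:
    """``points`` maps landmark id → (n_frames, 3) mm trajectories."""
    ids = sorted(points)
    n = {len(points[i]) for i in ids}
    if len(n) != 1:
        raise LipStereoError("all 3D trajectories must have the same length")
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "landmark_id", "X_mm", "Y_mm", "Z_mm"])
        for f in range(n.pop()):
            for lid in ids:
                p = points[lid][f]
                w.writerow([f, lid, _fmt(p[0]), _fmt(p[1]), _fmt(p[2])])


def read_points3d_csv(path) -> dict[str, np.ndarray]:
    path = Path(path)
    rows: dict[str, dict[int, tuple]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        _check_header(
            next(reader, None), ("frame", "landmark_id", "X_mm", "Y_mm", "Z_mm"), path
        )
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ParseError(f"expected 5 fields, got {len(row)}", path, ln)
            try:
                f = int(row[0])
            except ValueError:
                raise ParseError(f"non-integer frame {row[0]!r}", path, ln) from None
            xyz = tuple(
                _parse_float(row[k], path, ln, c)
                for k, c in ((2, "X_mm"), (3, "Y_mm"), (4, "Z_mm"))
            )
            rows.setdefault(row[1].strip(), {})[f] = xyz
    out = {}
    for lid, frames in rows.items():
        n = max(frames) + 1
        if sorted(frames) != list(range(n)):
            raise ParseError(f"landmark {lid!r} has missing frames", path)
        out[lid] = np.array([frames[f] for f in range(n)])
    if not out:
        raise ParseError("file contains no data rows", path)
    return out


# ---------------------------------------------------------------------------
# Correspondences


def write_correspondences_csv(path, camera_ids: Iterable[str], world, image) -> None:
    world = np.asarray(world, dtype=float)
    image = np.asarray(image, dtype=float)
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["camera_id", "X_mm", "Y_mm", "Z_mm", "x_px", "y_px"])
        for cid, X, x in zip(camera_ids, world, image):
            w.writerow(
                [cid, _fmt(X[0]), _fmt(X[1]), _fmt(X[2]), _fmt(x[0]), _fmt(x[1])]
            )


def read_correspondences_csv(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read resectioning data; returns camera_id → (world (n,3), image (n,2))."""
    path = Path(path)
    acc: dict[str, list] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        _check_header(
            next(reader, None),
            ("camera_id", "X_mm", "Y_mm", "Z_mm", "x_px", "y_px"),
            path,
        )
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise ParseError(f"expected 6 fields, got {len(row)}", path, ln)
            vals = [
                _parse_float(row[k], path, ln, c)
                for k, c in enumerate(("X_mm", "Y_mm", "Z_mm", "x_px", "y_px"), start=1)
            ]
            acc.setdefault(row[0].strip(), []).append(vals)
    if not acc:
        raise ParseError("file contains no data rows", path)
    return {
        cid: (np.array(v)[:, :3], np.array(v)[:, 3:]) for cid, v in acc.items()
    }


# ---------------------------------------------------------------------------
# Audio


def read_wav(path) -> AudioTrack:
    """Read a WAV file to a normalized mono :class:`AudioTrack`.

    Integer PCM is scaled by its type's full range; multi-channel audio
    keeps the first channel.
    """
    path = Path(path)
    try:
        rate, data = scipy.io.wavfile.read(path)
    except ValueError as e:
        raise ParseError(f"unreadable WAV: {e}", path) from e
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return AudioTrack(np.clip(samples, -1.0, 1.0), float(rate))


def write_wav(audio: AudioTrack, path) -> None:
    scipy.io.wavfile.write(
        Path(path), int(round(audio.rate)), audio.samples.astype(np.float32)
    )


# ---------------------------------------------------------------------------
# Reports


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (bool, int, str)) or obj is None:
        return obj
    if isinstance(obj, (float, np.floating)):
        return round9(float(obj))
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    raise LipStereoError(f"cannot serialize {type(obj).__name__} into a report")


def write_report_json(report: dict, path) -> None:
    """Write a nested report dict; floats are fixed to 9 significant digits
    so identical runs produce byte-identical files."""
    Path(path).write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n"
    )


def read_report_json(path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON: {e}", path) from e
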