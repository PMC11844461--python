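"""End-to-end pipeline composition, configuration and validation reports.

Two top-level runs mirror the two validation experiments:

* :func:`run_precision` — static-lip clips: triangulate the mid-sagittal
  lip landmarks from the two synchronized tracks, compute lip aperture per
  frame, and report its sample standard deviation (tracking precision).
* :func:`run_accuracy` — speech clips: the same front end followed by the
  full accuracy comparison against a 250 Hz reference stream (upsampling,
  two-stage temporal alignment, utterance segmentation, additive
  normalization, final RMSE).

Both are driven by a :class:`PipelineConfig` (YAML on disk) and emit
:class:`ValidationReport` objects that serialize to JSON with floats fixed
to 9 significant digits, so identical configs and seeds produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import LipStereoError
from .geometry import StereoRig, triangulate
from .kinematics import (
    ApertureSeries,
    accuracy_report,
    lip_aperture,
    precision_sd,
)
from .landmarks import LOWER_LIP_ID, UPPER_LIP_ID, LandmarkTrack2D
from . import io as lio
from .sync import compute_offset, synchronize_tracks

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "triangulate_tracks",
    "extract_aperture",
    "compute_precision",
    "run_precision",
    "run_accuracy",
]

logger = logging.getLogger("lipstereo")


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline in one validated, hashable record.

    Unknown keys in a YAML config are rejected; parameters are checked
    against their documented ranges at construction.
    """

    # --- paths
    tracks_left: str | None = None
    tracks_right: str | None = None
    calibration: str | None = None
    audio_left: str | None = None
    audio_right: str | None = None
    reference: str | None = None
    out_dir: str | None = None
    clip_id: str = "clip"

    # --- stage parameters
    fps: float = 60.0
    clap_threshold: float = 0.5
    n_init_frames: int = 5
    snap_radius_px: int = 5
    snap_grad_threshold: float = 0.1
    resample_rate_hz: float = 250.0
    align_max_shift: int = 50
    minima_prominence_mm: float = 1.0
    minima_separation_s: float = 0.1
    window_mode: str = "first-last"
    window_select: tuple[int, int] | None = None
    trim_start_s: float | None = None
    trim_end_s: float | None = None
    upper_id: str = UPPER_LIP_ID
    lower_id: str = LOWER_LIP_ID
    tracker: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.resample_rate_hz <= 0:
            raise LipStereoError("rates must be positive")
        if not (0 < self.clap_threshold <= 1):
            raise LipStereoError("clap_threshold must lie in (0, 1]")
        if self.n_init_frames < 1 or self.snap_radius_px < 1:
            raise LipStereoError("n_init_frames and snap_radius_px must be >= 1")
        if self.align_max_shift < 0:
            raise LipStereoError("align_max_shift must be nonnegative")
        if self.minima_prominence_mm <= 0 or self.minima_separation_s < 0:
            raise LipStereoError("minima parameters out of range")
        if self.window_mode not in ("first-last", "explicit"):
            raise LipStereoError(f"unknown window mode {self.window_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise LipStereoError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise LipStereoError(f"{path}: unknown config keys {sorted(unknown)}")
        if "window_select" in raw and raw["window_select"] is not None:
            raw["window_select"] = tuple(raw["window_select"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["window_select"] is not None:
            d["window_select"] = list(d["window_select"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ValidationReport:
    """Per-clip validation outcome (precision SD or accuracy RMSE)."""

    clip_id: str
    mode: str  # "precision" | "accuracy"
    metrics: dict
    params: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "clip_id": self.clip_id,
            "mode": self.mode,
            "metrics": self.metrics,
            "params": self.params,
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(
            clip_id=d["clip_id"],
            mode=d["mode"],
            metrics=d["metrics"],
            params=d.get("params", {}),
            version=d.get("version", ""),
        )

    def write(self, path) -> None:
        lio.write_report_json(self.to_dict(), path)

    @classmethod
    def read(cls, path) -> "ValidationReport":
        return cls.from_dict(lio.read_report_json(path))

    def summary_csv_row(self) -> str:
        """Flat per-clip line for plotting/statistics tooling."""
        m = self.metrics
        if self.mode == "precision":
            return f"{self.clip_id},precision,{lio.round9(m['sd_mm'])},,,\n"
        return (
            f"{self.clip_id},accuracy,,{m['lag_frames']},"
            f"{lio.round9(m['offset_mm'])},{lio.round9(m['rmse_mm'])}\n"
        )


SUMMARY_CSV_HEADER = "clip_id,mode,sd_mm,lag_frames,offset_mm,rmse_mm\n"


# ---------------------------------------------------------------------------
# In-memory pipeline stages


def triangulate_tracks(
    left: LandmarkTrack2D,
    right: LandmarkTrack2D,
    rig: StereoRig,
    ids: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Triangulate per-landmark 3D trajectories from two synchronized tracks."""
    if left.n_frames != right.n_frames:
        raise LipStereoError(
            f"frame-count mismatch between cameras: {left.n_frames} vs {right.n_frames}"
        )
    if ids is None:
        ids = tuple(i for i in left.ids if i in right.ids)
        if not ids:
            raise LipStereoError("the two tracks share no landmark ids")
    out = {}
    for lid in ids:
        out[lid] = triangulate(rig, left.get(lid), right.get(lid))
    return out


def extract_aperture(
    left: LandmarkTrack2D,
    right: LandmarkTrack2D,
    rig: StereoRig,
    upper_id: str = UPPER_LIP_ID,
    lower_id: str = LOWER_LIP_ID,
) -> ApertureSeries:
    """Triangulate the mid-sagittal pair and compute lip aperture (mm)."""
    pts = triangulate_tracks(left, right, rig, ids=(upper_id, lower_id))
    return lip_aperture(pts[upper_id], pts[lower_id], rate=left.fps, t0=left.t0)


def compute_precision(
    left: LandmarkTrack2D,
    right: LandmarkTrack2D,
    rig: StereoRig,
    upper_id: str = UPPER_LIP_ID,
    lower_id: str = LOWER_LIP_ID,
) -> tuple[float, ApertureSeries]:
    """Static-lip precision: sample SD of lip aperture across frames."""
    la = extract_aperture(left, right, rig, upper_id, lower_id)
    return precision_sd(la), la


# ---------------------------------------------------------------------------
# Config-driven runs


def _load_front_end(config: PipelineConfig):
    """Shared front end: calibration, tracks, clap sync, trimming."""
    t_start = time.perf_counter()
    for name in ("tracks_left", "tracks_right", "calibration"):
        if getattr(config, name) is None:
            raise LipStereoError(f"config is missing required path {name!r}")
    rig = lio.read_calibration(config.calibration)
    left = lio.read_track_csv(config.tracks_left, fps=config.fps)
    right = lio.read_track_csv(config.tracks_right, fps=config.fps)

    sync_info = None
    if config.audio_left and config.audio_right:
        a_l = lio.read_wav(config.audio_left)
        a_r = lio.read_wav(config.audio_right)
        res = compute_offset(a_l, a_r, config.clap_threshold, config.fps)
        left, right = synchronize_tracks(left, right, res.offset_frames)
        sync_info = {
            "offset_samples": res.offset_samples,
            "offset_frames": res.offset_frames,
            "residual_frames": res.residual_frames,
        }
        logger.debug("clap sync: %s", sync_info)
    elif left.n_frames != right.n_frames:
        raise LipStereoError(
            "tracks differ in length and no audio is configured for sync"
        )

    if config.trim_start_s is not None or config.trim_end_s is not None:
        a = int(round((config.trim_start_s or 0.0) * config.fps))
        b = (
            int(round(config.trim_end_s * config.fps)) + 1
            if config.trim_end_s is not None
            else left.n_frames
        )
        left = left.slice_frames(a, min(b, left.n_frames))
        right = right.slice_frames(a, min(b, right.n_frames))

    logger.debug(
        "front end: %d frames, %.1f ms", left.n_frames,
        1e3 * (time.perf_counter() - t_start),
    )
    return rig, left, right, sync_info


def run_precision(config: PipelineConfig) -> ValidationReport:
    """Config-driven precision run; writes nothing (caller persists)."""
    logger.info(
        "precision run: clip=%s config=%s seed=%d",
        config.clip_id, config.config_hash, config.seed,
    )
    rig, left, right, sync_info = _load_front_end(config)
    sd, la = compute_precision(left, right, rig, config.upper_id, config.lower_id)
    logger.debug("precision sd=%.6f mm over %d frames", sd, len(la))
    metrics = {
        "sd_mm": sd,
        "n_frames": len(la),
        "rate_hz": la.rate,
        "mean_la_mm": float(np.mean(la.values)),
    }
    if sync_info:
        metrics["sync"] = sync_info
    return ValidationReport(
        clip_id=config.clip_id,
        mode="precision",
        metrics=metrics,
        params=config.to_dict(),
    )


def run_accuracy(config: PipelineConfig) -> ValidationReport:
    """Config-driven accuracy run against the reference stream."""
    logger.info(
        "accuracy run: clip=%s config=%s seed=%d",
        config.clip_id, config.config_hash, config.seed,
    )
    if config.reference is None:
        raise LipStereoError("accuracy run requires a reference stream path")
    rig, left, right, sync_info = _load_front_end(config)
    reference = lio.read_aperture_csv(config.reference)

    t0 = time.perf_counter()
    la = extract_aperture(left, right, rig, config.upper_id, config.lower_id)
    logger.debug("aperture extraction: %.1f ms", 1e3 * (time.perf_counter() - t0))

    rep = accuracy_report(
        la,
        reference,
        max_shift=config.align_max_shift,
        min_prominence=config.minima_prominence_mm,
        min_separation=max(1, int(round(config.minima_separation_s * reference.rate))),
        window_mode=config.window_mode,
        window_select=config.window_select,
    )
    logger.debug(
        "accuracy: lag=%d offset=%.4f mm rmse=%.4f mm",
        rep.alignment.lag, rep.additive_offset_mm, rep.rmse_mm,
    )
    metrics = {
        "rmse_mm": rep.rmse_mm,
        "lag_frames": rep.alignment.lag,
        "coarse_lag_frames": rep.coarse_lag,
        "offset_mm": rep.additive_offset_mm,
        "window": [rep.window.onset_index, rep.window.offset_index],
        "rmse_at_alignment_mm": rep.alignment.rmse_at_lag,
        "n_overlap": rep.n_overlap,
        "rate_hz": rep.rate,
    }
    if sync_info:
        metrics["sync"] = sync_info
    return ValidationReport(
        clip_id=config.clip_id,
        mode="accuracy",
        metrics=metrics,
        params=config.to_dict(),
    )
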