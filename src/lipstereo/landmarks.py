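"""Landmark-track data model and conditioning of tracker output.

A neural landmark detector/tracker (external to this package) yields pixel
coordinates of named lip landmarks per frame and per camera.  This module
defines the in-memory track container, the conditioning steps applied to raw
detector output — averaging of the initial frames, vertical edge snapping of
the upper-lip point to the vermilion border, crop→original coordinate
mapping, censoring of bystander faces — and the adapter contract through
which any tracker (neural or synthetic) plugs into the pipeline.

Lip landmarks: ten ids including the two semantically required mid-sagittal
vermilion-border points ``"upper_mid"`` and ``"lower_mid"`` whose 3D distance
is the lip aperture.  The remaining ids are configurable; supporting points
are namespaced ``"support/..."``.
"""

from __future__ import annotations

import importlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import LipStereoError

__all__ = [
    "UPPER_LIP_ID",
    "LOWER_LIP_ID",
    "LandmarkTrack2D",
    "CropWindow",
    "TrackerAdapter",
    "PlaybackTracker",
    "get_tracker",
    "average_initial_landmarks",
    "snap_to_edge",
    "build_support_points",
    "map_crop_to_original",
    "map_original_to_crop",
    "censor_regions",
]

UPPER_LIP_ID = "upper_mid"
LOWER_LIP_ID = "lower_mid"


@dataclass(frozen=True)
class LandmarkTrack2D:
    """Per-frame pixel coordinates of a fixed set of named landmarks.

    Attributes
    ----------
    ids : tuple of str
        Landmark names; every frame carries exactly this set.
    xy : ndarray, shape (n_frames, n_ids, 2)
        Pixel coordinates (0-based, origin top-left, y downward).
    fps : float
        Video frame rate in Hz.
    t0 : float
        Wall-clock time of frame 0 in seconds (bookkeeping for sync).
    """

    ids: tuple[str, ...]
    xy: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self):
        ids = tuple(str(i) for i in self.ids)
        if len(set(ids)) != len(ids):
            raise LipStereoError("duplicate landmark ids")
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 3 or xy.shape[1] != len(ids) or xy.shape[2] != 2:
            raise LipStereoError(
                f"xy must have shape (n_frames, {len(ids)}, 2), got {xy.shape}"
            )
        if not np.all(np.isfinite(xy)):
            raise LipStereoError("track contains non-finite coordinates")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise LipStereoError("fps must be positive")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "xy", xy)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fps

    def index(self, landmark_id: str) -> int:
        try:
            return self.ids.index(landmark_id)
        except ValueError:
            raise LipStereoError(f"landmark id {landmark_id!r} not in track") from None

    def get(self, landmark_id: str) -> np.ndarray:
        """Trajectory of one landmark, shape (n_frames, 2)."""
        return self.xy[:, self.index(landmark_id), :]

    def frame(self, i: int) -> dict[str, np.ndarray]:
        """One frame as a mapping landmark id → (x, y)."""
        return {lid: self.xy[i, j] for j, lid in enumerate(self.ids)}

    def slice_frames(self, start: int, stop: int) -> "LandmarkTrack2D":
        if not (0 <= start < stop <= self.n_frames):
            raise LipStereoError(
                f"invalid frame slice [{start}, {stop}) for {self.n_frames} frames"
            )
        return replace(
            self, xy=self.xy[start:stop], t0=self.t0 + start / self.fps
        )


@dataclass(frozen=True)
class CropWindow:
    """A fixed crop of the original image, chosen once per clip.

    The tracker runs on a cropped view of the video to bound its compute;
    the window is determined from the face position on the first frame and
    held fixed.  Default size 704×512 px.
    """

    origin: tuple[float, float]
    width: int = 704
    height: int = 512
    image_width: int | None = None
    image_height: int | None = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise LipStereoError("crop window must have positive size")
        ox, oy = self.origin
        if not (np.isfinite(ox) and np.isfinite(oy)):
            raise LipStereoError("crop origin must be finite")
        if self.image_width is not None and (
            ox < 0 or oy < 0
            or ox + self.width > self.image_width
            or oy + self.height > self.image_height
        ):
            raise LipStereoError("crop window extends outside the image")


@runtime_checkable
class TrackerAdapter(Protocol):
    """Contract for point trackers.

    Given the initial per-landmark coordinates on frame 0 and the frame
    sequence, return a :class:`LandmarkTrack2D` covering every frame with
    exactly the input id set.  Neural trackers live behind this seam; tests
    use the synthetic playback tracker.
    """

    def track(
        self, initial: Mapping[str, Sequence[float]], frames: Sequence
    ) -> LandmarkTrack2D:
        ...


class PlaybackTracker:
    """Tracker adapter that replays a precomputed track.

    Wraps a :class:`LandmarkTrack2D` (typically simulator projections plus
    optional jitter) and serves it through the adapter contract, ignoring the
    frame images.  Restricts output to the requested id set.
    """

    def __init__(self, track: LandmarkTrack2D):
        self._track = track

    def track(self, initial, frames=None) -> LandmarkTrack2D:
        wanted = tuple(initial)
        missing = [i for i in wanted if i not in self._track.ids]
        if missing:
            raise LipStereoError(f"playback track lacks ids {missing}")
        cols = [self._track.index(i) for i in wanted]
        out = replace(self._track, ids=wanted, xy=self._track.xy[:, cols, :])
        if frames is not None and len(frames) != out.n_frames:
            raise LipStereoError(
                f"playback track has {out.n_frames} frames, {len(frames)} requested"
            )
        return out


def get_tracker(name: str, **kwargs) -> TrackerAdapter:
    """Resolve a tracker adapter by configuration name.

    ``"synthetic"`` builds a playback tracker from ``kwargs['track']``;
    ``"external:<module>"`` imports ``<module>`` and calls its
    ``make_tracker(**kwargs)`` factory.
    """
    if name == "synthetic":
        if "track" not in kwargs:
            raise LipStereoError("synthetic tracker requires a 'track' argument")
        return PlaybackTracker(kwargs["track"])
    if name.startswith("external:"):
        module = importlib.import_module(name.split(":", 1)[1])
        if not hasattr(module, "make_tracker"):
            raise LipStereoError(f"{module.__name__} defines no make_tracker()")
        return module.make_tracker(**kwargs)
    raise LipStereoError(f"unknown tracker {name!r}")


def average_initial_landmarks(detections, n_frames: int = 5) -> dict[str, np.ndarray]:
    """Average each landmark's coordinates over the first ``n_frames`` frames.

    Per-frame detectors place landmarks with appreciable frame-to-frame
    scatter; averaging the initial frames yields a steadier starting point
    for the tracker than any single frame.

    ``detections`` may be a :class:`LandmarkTrack2D` or a sequence of
    per-frame mappings id → (x, y).
    """
    if n_frames < 1:
        raise LipStereoError("n_frames must be >= 1")
    if isinstance(detections, LandmarkTrack2D):
        if detections.n_frames < n_frames:
            raise LipStereoError(
                f"need {n_frames} frames of detections, got {detections.n_frames}"
            )
        mean = detections.xy[:n_frames].mean(axis=0)
        return {lid: mean[j].copy() for j, lid in enumerate(detections.ids)}
    frames = list(detections)
    if len(frames) < n_frames:
        raise LipStereoError(f"need {n_frames} frames of detections, got {len(frames)}")
    ids = list(frames[0])
    for k, f in enumerate(frames[:n_frames]):
        if set(f) != set(ids):
            raise LipStereoError(f"frame {k} has a different landmark id set")
    return {
        lid: np.mean([np.asarray(f[lid], dtype=float) for f in frames[:n_frames]], axis=0)
        for lid in ids
    }


def _validate_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise LipStereoError("image must be a 2-D intensity array")
    if not np.all(np.isfinite(img)):
        raise LipStereoError("image contains non-finite values")
    return img


def snap_to_edge(
    image,
    p: Sequence[float],
    search_radius_px: int = 5,
    grad_threshold: float = 0.1,
) -> np.ndarray:
    """Snap a landmark vertically to the strongest nearby intensity edge.

    Per-frame detectors tend to place the upper-lip point slightly below the
    vermilion border; the border itself is a strong horizontal intensity
    edge.  This routine scans the pixel column of ``p`` over rows
    ``[y - r, y + r]``, computes the centered-difference vertical gradient,
    and moves the point to the row of maximum |gradient| provided that
    maximum reaches ``grad_threshold`` (intensity units per pixel).  Ties
    break to the row nearest the original y, then upward.  Below threshold
    the point is returned unchanged.
    """
    img = _validate_image(image)
    x, y = float(p[0]), float(p[1])
    col = int(round(x))
    row = int(round(y))
    r = int(search_radius_px)
    if r < 1:
        raise LipStereoError("search radius must be >= 1")
    # Centered differences need one extra row on each side of the window.
    if not (0 <= col < img.shape[1]) or row - r - 1 < 0 or row + r + 1 >= img.shape[0]:
        raise LipStereoError(
            f"point ({x}, {y}) too close to the border for radius {r}"
        )
    rows = np.arange(row - r, row + r + 1)
    grad = np.abs(img[rows + 1, col] - img[rows - 1, col]) / 2.0
    gmax = grad.max()
    if gmax < grad_threshold:
        return np.array([x, y])
    best = [rw for rw, g in zip(rows, grad) if g == gmax]
    best.sort(key=lambda rw: (abs(rw - y), rw))
    return np.array([x, float(best[0])])


def build_support_points(
    lip_points: Mapping[str, Sequence[float]],
    face_box: Sequence[float],
    grid_rows: int = 10,
    grid_cols: int = 10,
    margin: float = 1.5,
) -> dict[str, np.ndarray]:
    """Combine local lip points with a global lattice over the face.

    Joint trackers perform best with both local supporting points (the lip
    contour itself) and a coarse global grid over the face/background.  The
    grid has ``grid_rows x grid_cols`` points at the cell centers of the face
    box expanded by ``margin`` about its center; grid ids are namespaced
    ``"support/r{i}c{j}"`` and are disjoint from the lip ids.

    ``face_box`` is ``(x0, y0, width, height)`` in pixels.
    """
    x0, y0, w, h = (float(v) for v in face_box)
    if w <= 0 or h <= 0:
        raise LipStereoError("face box must have positive area")
    if grid_rows < 1 or grid_cols < 1 or margin <= 0:
        raise LipStereoError("grid dimensions and margin must be positive")
    cx, cy = x0 + w / 2.0, y0 + h / 2.0
    we, he = w * margin, h * margin
    xe, ye = cx - we / 2.0, cy - he / 2.0
    out: dict[str, np.ndarray] = {
        lid: np.asarray(p, dtype=float) for lid, p in lip_points.items()
    }
    for i in range(grid_rows):
        for j in range(grid_cols):
            out[f"support/r{i}c{j}"] = np.array(
                [xe + (j + 0.5) * we / grid_cols, ye + (i + 0.5) * he / grid_rows]
            )
    return out


def map_crop_to_original(p: Sequence[float], window: CropWindow) -> np.ndarray:
    """Crop-frame pixel coordinates → original-image coordinates."""
    x, y = float(p[0]), float(p[1])
    if not (0 <= x <= window.width and 0 <= y <= window.height):
        raise LipStereoError(
            f"point ({x}, {y}) outside crop window {window.width}x{window.height}"
        )
    return np.array([x + window.origin[0], y + window.origin[1]])


def map_original_to_crop(p: Sequence[float], window: CropWindow) -> np.ndarray:
    """Original-image pixel coordinates → crop-frame coordinates."""
    x = float(p[0]) - window.origin[0]
    y = float(p[1]) - window.origin[1]
    if not (0 <= x <= window.width and 0 <= y <= window.height):
        raise LipStereoError(f"point {tuple(p)} lies outside the crop window")
    return np.array([x, y])


def censor_regions(image, rectangles: Sequence[Sequence[float]]) -> np.ndarray:
    """Black out rectangular regions (bystander faces) of an image.

    ``rectangles`` are ``(x0, y0, width, height)`` in pixels.  Out-of-bounds
    rectangles are clipped with a warning rather than rejected.  Returns a
    new array; the input is untouched.
    """
    img = _validate_image(image).copy()
    nrows, ncols = img.shape
    for rect in rectangles:
        x0, y0, w, h = (float(v) for v in rect)
        if w < 0 or h < 0:
            raise LipStereoError(f"rectangle {rect} has negative size")
        c0, c1 = int(np.floor(x0)), int(np.ceil(x0 + w))
        r0, r1 = int(np.floor(y0)), int(np.ceil(y0 + h))
        if c0 < 0 or r0 < 0 or c1 > ncols or r1 > nrows:
            warnings.warn(
                f"censor rectangle {rect} extends outside the image; clipping",
                stacklevel=2,
            )
        img[max(r0, 0) : max(min(r1, nrows), 0), max(c0, 0) : max(min(c1, ncols), 0)] = 0.0
    return img
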