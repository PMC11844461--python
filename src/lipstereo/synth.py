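"""Synthetic stereo articulatory scenes: the pipeline's ground-truth oracle.

Real validation of a markerless lip tracker needs participant videos and a
reference articulograph; neither is required to exercise the *deterministic*
pipeline.  This module generates complete synthetic recording sessions with
analytically known ground truth:

* a lip-aperture trajectory built from raised-cosine opening gestures whose
  bilabial closures (local minima at the baseline) sit at known times;
* a rigid head-motion trajectory (none / small jitter / alternating yaw /
  constant rotation at 18°/s, the rotating-mannequin condition) applied to a
  face-local landmark layout — rigid motion is an isometry, so ground-truth
  LA is untouched by any head mode;
* a stereo rig matching the study geometry: two cameras ≈ 800 mm from the
  face, ≈ 600 mm apart, 5312×2988 px at 60 Hz;
* pixel tracks produced by projecting the ground truth through the rig and
  adding detector-like (iid) or tracker-like (AR(1)) pixel jitter;
* a 250 Hz reference stream emulating an articulograph export, with a
  sensor-placement amplitude offset, an optional start lag and optional
  noise;
* a clap audio pair with a configured stagger;
* exact checkerboard correspondences for calibration (18×25 squares of
  15 mm; 50 random poses).

Every stochastic element is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import BehindCameraError, DegenerateGeometryError, LipStereoError
from .geometry import CameraModel, StereoRig, project
from .kinematics import ApertureSeries, resample
from .landmarks import LandmarkTrack2D
from .sync import AudioTrack

__all__ = [
    "IMAGE_WIDTH",
    "IMAGE_HEIGHT",
    "DEFAULT_FPS",
    "FACE_CENTER_MM",
    "GestureParams",
    "HeadMotionParams",
    "JitterModel",
    "SyntheticScene",
    "CheckerboardData",
    "default_rig",
    "la_trajectory",
    "static_lips",
    "build_scene",
    "render_tracks",
    "render_audio",
    "checkerboard_correspondences",
]

IMAGE_WIDTH = 5312
IMAGE_HEIGHT = 2988
DEFAULT_FPS = 60.0
DEFAULT_FOCAL_PX = 3000.0
# Face centered on the two cameras: 600 mm baseline, ~800 mm range.
FACE_CENTER_MM = np.array([300.0, 0.0, 741.62])


def _look_at(center: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World->camera (R, t) for a camera at ``center`` aimed at ``target``,
    with image y pointing down (world +y)."""
    z = target - center
    z = z / np.linalg.norm(z)
    x = np.cross([0.0, 1.0, 0.0], z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return R, -R @ center


def default_rig(
    baseline_mm: float = 600.0,
    focal_px: float = DEFAULT_FOCAL_PX,
    dist: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
) -> StereoRig:
    """Study-geometry stereo rig: left camera at the world origin looking
    down +z, right camera ``baseline_mm`` to the side, toed in toward the
    face center.  Distortion defaults to zero (rectilinear lens regime)."""
    cx, cy = IMAGE_WIDTH / 2.0, IMAGE_HEIGHT / 2.0
    left = CameraModel(fx=focal_px, fy=focal_px, cx=cx, cy=cy, dist=dist)
    R, t = _look_at(np.array([baseline_mm, 0.0, 0.0]), FACE_CENTER_MM)
    right = CameraModel(fx=focal_px, fy=focal_px, cx=cx, cy=cy, dist=dist, R=R, t=t)
    return StereoRig(left=left, right=right)


@dataclass(frozen=True)
class GestureParams:
    """Lip-aperture gesture specification.

    ``gestures`` is a sequence of ``(onset_s, duration_s, amplitude_mm)``
    raised-cosine opening gestures; consecutive gestures may touch but not
    overlap.  LA returns to ``baseline_la`` (the bilabial-closure aperture)
    exactly at every gesture boundary.
    """

    baseline_la: float = 2.0
    gestures: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if not (np.isfinite(self.baseline_la) and self.baseline_la >= 0):
            raise LipStereoError("baseline LA must be nonnegative")
        g = tuple(
            (float(o), float(d), float(a)) for o, d, a in self.gestures
        )
        prev_end = -np.inf
        for o, d, a in g:
            if not all(np.isfinite(v) for v in (o, d, a)):
                raise LipStereoError("gesture parameters must be finite")
            if o < 0 or d <= 0 or a <= 0:
                raise LipStereoError(
                    "gestures need onset >= 0, duration > 0, amplitude > 0"
                )
            if o < prev_end - 1e-12:
                raise LipStereoError("gestures overlap or are out of onset order")
            prev_end = o + d
        object.__setattr__(self, "gestures", g)

    @property
    def end_time(self) -> float:
        return max((o + d for o, d, _ in self.gestures), default=0.0)

    @classmethod
    def template(
        cls,
        name: str,
        rng: np.random.Generator | None = None,
        start: float = 0.3,
        baseline_la: float | None = None,
    ) -> "GestureParams":
        """Utterance templates with known closure structure.

        ``"puppy"``: three adjacent opening gestures → two bilabial closures
        (the /p/ closures).  ``"buy-bobby-a-puppy"``: five adjacent gestures
        → four closures.  With ``rng`` the amplitudes (5–15 mm), durations
        (0.15–0.35 s) and baseline (0–3 mm) are randomized; without, fixed
        representative values are used.
        """
        counts = {"puppy": 3, "buy-bobby-a-puppy": 5}
        if name not in counts:
            raise LipStereoError(f"unknown gesture template {name!r}")
        n = counts[name]
        if rng is None:
            amps = [10.0, 8.0, 12.0, 9.0, 11.0][:n]
            durs = [0.25, 0.20, 0.30, 0.22, 0.26][:n]
            base = 2.0
        else:
            amps = list(rng.uniform(5.0, 15.0, size=n))
            durs = list(rng.uniform(0.15, 0.35, size=n))
            base = float(rng.uniform(0.0, 3.0))
        if baseline_la is not None:
            base = baseline_la
        gestures = []
        t = start
        for a, d in zip(amps, durs):
            gestures.append((t, d, a))
            t += d
        return cls(baseline_la=base, gestures=tuple(gestures))


@dataclass(frozen=True)
class HeadMotionParams:
    """Rigid head-motion trajectory parameters.

    Modes
    -----
    ``"none"`` — static head.
    ``"small-jitter"`` — low-amplitude smooth yaw/pitch wobble plus
    translation sinusoids of amplitude ``translation_sd_mm`` (posture
    adjustments while listening).
    ``"alternating-yaw"`` — ``yaw_amplitude_deg`` sinusoidal yaw at
    ``frequency_hz`` (looking at one camera, then the other).
    ``"constant-rotation"`` — yaw at ``angular_rate_deg_s`` (default 18°/s,
    the rotating rigid-head condition), centered on the clip midpoint.
    """

    mode: str = "none"
    angular_rate_deg_s: float = 18.0
    yaw_amplitude_deg: float = 20.0
    frequency_hz: float = 0.25
    translation_sd_mm: float = 2.0

    _MODES = ("none", "small-jitter", "alternating-yaw", "constant-rotation")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise LipStereoError(f"unknown head-motion mode {self.mode!r}")
        if self.angular_rate_deg_s < 0 or self.translation_sd_mm < 0:
            raise LipStereoError("head-motion magnitudes must be nonnegative")


@dataclass(frozen=True)
class JitterModel:
    """Pixel-noise model for synthetic tracks.

    ``"iid"`` emulates a per-frame detector (each frame located
    independently); ``"ar1"`` emulates a temporally coherent tracker:
    e_t = rho * e_{t-1} + sqrt(1 - rho^2) * N(0, sigma_px), which has
    stationary marginal SD exactly ``sigma_px``.  The magnitudes are free
    parameters of the simulation, not estimates of any particular tracker.
    """

    kind: str = "iid"
    sigma_px: float = 1.0
    rho: float = 0.9
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("iid", "ar1"):
            raise LipStereoError(f"unknown jitter kind {self.kind!r}")
        if not (np.isfinite(self.sigma_px) and self.sigma_px >= 0):
            raise LipStereoError("sigma_px must be nonnegative")
        if not (0.0 <= self.rho < 1.0):
            raise LipStereoError("rho must lie in [0, 1)")

    def sample(self, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        """Draw jitter with time along the first axis."""
        if self.sigma_px == 0:
            return np.zeros(shape)
        if self.kind == "iid":
            return rng.normal(0.0, self.sigma_px, size=shape)
        e = np.empty(shape)
        e[0] = rng.normal(0.0, self.sigma_px, size=shape[1:])
        c = np.sqrt(1.0 - self.rho**2)
        innov = rng.normal(0.0, self.sigma_px, size=shape)
        for k in range(1, shape[0]):
            e[k] = self.rho * e[k - 1] + c * innov[k]
        return e


def la_trajectory(
    params: GestureParams, fps: float = DEFAULT_FPS, duration: float | None = None
) -> ApertureSeries:
    """Ground-truth lip-aperture series: baseline plus raised-cosine bumps.

    Each gesture contributes ``amp * (1 - cos(2*pi*(t - onset)/dur)) / 2``
    within its span, so LA touches the baseline exactly at gesture onsets
    and offsets — the synthetic bilabial closures.
    """
    if fps <= 0:
        raise LipStereoError("fps must be positive")
    if duration is None:
        duration = params.end_time + 0.3
    if duration <= 0:
        raise LipStereoError("duration must be positive")
    n = int(np.floor(duration * fps + 1e-9)) + 1
    t = np.arange(n) / fps
    v = np.full(n, params.baseline_la)
    for onset, dur, amp in params.gestures:
        m = (t >= onset) & (t <= onset + dur)
        v[m] += amp * (1.0 - np.cos(2.0 * np.pi * (t[m] - onset) / dur)) / 2.0
    return ApertureSeries(v, rate=fps)


def static_lips(baseline_la: float = 8.0) -> GestureParams:
    """Gesture parameters for a static, slightly parted mouth (precision
    experiments; the mannequin condition)."""
    return GestureParams(baseline_la=baseline_la, gestures=())


# ---------------------------------------------------------------------------
# Face-local landmark layout


_MOUTH_HALF_WIDTH = 25.0  # mm
_LIP_PROTRUSION = -20.0  # face-local z of the lip points (toward the cameras)


def _lip_layout(la: np.ndarray) -> dict[str, np.ndarray]:
    """Face-local 3D trajectories of the 10 lip landmarks for LA(t).

    The two mid-sagittal points are separated vertically by exactly LA(t);
    flanking points follow with reduced vertical excursion; corners stay
    fixed.  y is down, so the upper lip has negative y.
    """
    n = la.shape[0]
    half = la / 2.0
    s = np.sin(np.deg2rad(54.0))
    cx = _MOUTH_HALF_WIDTH * np.cos(np.deg2rad(54.0))
    z = np.full(n, _LIP_PROTRUSION)

    def traj(x, y, dz=0.0):
        return np.stack([np.full(n, x) if np.isscalar(x) else x, y, z + dz], axis=1)

    return {
        "upper_mid": traj(0.0, -half),
        "lower_mid": traj(0.0, +half),
        "upper_right": traj(cx, -half * s, 2.0),
        "upper_left": traj(-cx, -half * s, 2.0),
        "lower_right": traj(cx, +half * s, 2.0),
        "lower_left": traj(-cx, +half * s, 2.0),
        "corner_right": traj(_MOUTH_HALF_WIDTH, np.zeros(n), 5.0),
        "corner_left": traj(-_MOUTH_HALF_WIDTH, np.zeros(n), 5.0),
        "upper_outer_mid": traj(0.0, -half - 5.0, 1.0),
        "lower_outer_mid": traj(0.0, +half + 5.0, 1.0),
    }


def _support_layout(grid: tuple[int, int]) -> dict[str, np.ndarray]:
    """Static face-plane supporting points over a 140x180 mm face box."""
    rows, cols = grid
    out = {}
    for i in range(rows):
        for j in range(cols):
            x = -70.0 + (j + 0.5) * 140.0 / cols
            y = -90.0 + (i + 0.5) * 180.0 / rows
            out[f"support/r{i}c{j}"] = np.array([x, y, 0.0])
    return out


def _yaw(angle_rad: np.ndarray) -> np.ndarray:
    """Rotation about the vertical (y) axis, vectorized: (n, 3, 3)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.zeros(angle_rad.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 2] = s
    R[..., 2, 0] = -s
    R[..., 2, 2] = c
    R[..., 1, 1] = 1.0
    return R


def _pitch(angle_rad: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.zeros(angle_rad.shape + (3, 3))
    R[..., 1, 1] = c
    R[..., 1, 2] = -s
    R[..., 2, 1] = s
    R[..., 2, 2] = c
    R[..., 0, 0] = 1.0
    return R


def _head_trajectory(
    head: HeadMotionParams, t: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame rigid head pose: rotations (n,3,3) and translations (n,3)."""
    n = t.shape[0]
    if head.mode == "none":
        return np.broadcast_to(np.eye(3), (n, 3, 3)).copy(), np.zeros((n, 3))
    if head.mode == "constant-rotation":
        rate = np.deg2rad(head.angular_rate_deg_s)
        yaw = rate * (t - t[-1] / 2.0)
        return _yaw(yaw), np.zeros((n, 3))
    if head.mode == "alternating-yaw":
        yaw = np.deg2rad(head.yaw_amplitude_deg) * np.sin(
            2.0 * np.pi * head.frequency_hz * t
        )
        return _yaw(yaw), np.zeros((n, 3))
    # small-jitter: smooth low-amplitude wobble with random phases.
    ph = rng.uniform(0.0, 2.0 * np.pi, size=5)
    yaw = np.deg2rad(1.5) * np.sin(2.0 * np.pi * 0.6 * t + ph[0])
    pitch = np.deg2rad(1.5) * np.sin(2.0 * np.pi * 0.9 * t + ph[1])
    R = _yaw(yaw) @ _pitch(pitch)
    trans = head.translation_sd_mm * np.stack(
        [
            np.sin(2.0 * np.pi * 0.5 * t + ph[2]),
            np.sin(2.0 * np.pi * 0.8 * t + ph[3]),
            np.sin(2.0 * np.pi * 0.4 * t + ph[4]),
        ],
        axis=1,
    )
    return R, trans


@dataclass(frozen=True)
class SyntheticScene:
    """A complete synthetic recording session with ground truth.

    ``trajectories`` maps landmark id → (n_frames, 3) world coordinates in
    mm; ``gt_la`` is the analytic lip aperture at the video rate;
    ``reference`` is the emulated 250 Hz articulograph stream (ground-truth
    LA linearly resampled to 250 Hz, plus sensor offset, start lag and
    noise).
    """

    fps: float
    duration: float
    rig: StereoRig
    trajectories: dict[str, np.ndarray]
    gt_la: ApertureSeries
    reference: ApertureSeries
    sensor_offset_mm: float
    reference_lag_samples: int
    gestures: GestureParams
    head: HeadMotionParams
    seed: int

    @property
    def n_frames(self) -> int:
        return len(self.gt_la)

    @property
    def landmark_ids(self) -> tuple[str, ...]:
        return tuple(self.trajectories)


def build_scene(
    gestures: GestureParams | None = None,
    head: HeadMotionParams | None = None,
    rig: StereoRig | None = None,
    *,
    sensor_offset_mm: float = 1.5,
    reference_noise_sd_mm: float = 0.0,
    reference_lag_samples: int = 0,
    fps: float = DEFAULT_FPS,
    duration: float | None = None,
    support_grid: tuple[int, int] = (4, 4),
    seed: int = 0,
) -> SyntheticScene:
    """Assemble a synthetic stereo articulatory scene.

    The face-local landmark layout (mid-sagittal pair separated by LA(t),
    eight flanking lip points, a static support lattice) is carried through
    the rigid head-motion trajectory and placed at the study geometry in the
    world (left-camera) frame.  The 250 Hz reference stream is derived from
    the same ground truth, shifted by ``sensor_offset_mm`` in amplitude and
    ``reference_lag_samples`` in time, with optional iid noise.  The result
    is a pure function of the parameters and ``seed``.
    """
    gestures = gestures if gestures is not None else GestureParams.template("puppy")
    head = head if head is not None else HeadMotionParams()
    rig = rig if rig is not None else default_rig()
    rng = np.random.default_rng(seed)

    gt = la_trajectory(gestures, fps=fps, duration=duration)
    n = len(gt)
    t = gt.timestamps
    actual_duration = float(t[-1])

    local = _lip_layout(gt.values)
    local.update({k: np.broadcast_to(v, (n, 3)) for k, v in _support_layout(support_grid).items()})

    R, trans = _head_trajectory(head, t, rng)
    trajectories = {
        lid: FACE_CENTER_MM + np.einsum("nij,nj->ni", R, pts) + trans
        for lid, pts in local.items()
    }

    base = resample(gt, 250.0)
    vals = base.values + sensor_offset_mm
    lag = int(reference_lag_samples)
    if abs(lag) >= len(vals):
        raise LipStereoError("reference lag exceeds the reference length")
    if lag > 0:
        vals = np.concatenate([np.full(lag, vals[0]), vals[:-lag]])
    elif lag < 0:
        vals = np.concatenate([vals[-lag:], np.full(-lag, vals[-1])])
    if reference_noise_sd_mm > 0:
        vals = vals + rng.normal(0.0, reference_noise_sd_mm, size=vals.shape)
    reference = ApertureSeries(vals, rate=250.0)

    return SyntheticScene(
        fps=fps,
        duration=actual_duration,
        rig=rig,
        trajectories=trajectories,
        gt_la=gt,
        reference=reference,
        sensor_offset_mm=float(sensor_offset_mm),
        reference_lag_samples=lag,
        gestures=gestures,
        head=head,
        seed=int(seed),
    )


def render_tracks(
    scene: SyntheticScene,
    jitter_left: JitterModel | None = None,
    jitter_right: JitterModel | None = None,
    seed: int = 0,
) -> tuple[LandmarkTrack2D, LandmarkTrack2D]:
    """Project the scene through the rig and add pixel jitter.

    Stands in for the neural tracker: the output feeds the real pipeline
    through the tracker-adapter seam.  Each camera gets an independent
    jitter stream seeded from ``(seed, camera_index)`` unless the jitter
    model carries its own seed.
    """
    ids = scene.landmark_ids
    pts = np.stack([scene.trajectories[i] for i in ids], axis=1)  # (n, k, 3)
    n, k, _ = pts.shape
    tracks = []
    for cam_idx, (cam, jitter) in enumerate(
        [(scene.rig.left, jitter_left), (scene.rig.right, jitter_right)]
    ):
        depths = pts @ cam.R.T[:, 2] + cam.t[2]
        if np.any(depths <= 0):
            fi, li = np.argwhere(depths <= 0)[0]
            raise BehindCameraError(
                f"landmark {ids[li]!r} behind the camera at frame {fi}"
            )
        px = project(cam, pts.reshape(-1, 3)).reshape(n, k, 2)
        if jitter is not None and jitter.sigma_px > 0:
            jseed = jitter.seed if jitter.seed is not None else (seed, cam_idx)
            px = px + jitter.sample((n, k, 2), np.random.default_rng(jseed))
        tracks.append(LandmarkTrack2D(ids=ids, xy=px, fps=scene.fps))
    return tracks[0], tracks[1]


def render_audio(
    scene_or_duration,
    rate: int = 48000,
    clap_time_s: float = 0.5,
    stagger_samples: int = 0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[AudioTrack, AudioTrack]:
    """Clap audio pair: low-level Gaussian noise plus a unit impulse.

    The right track's impulse is staggered by ``stagger_samples`` relative
    to the left, emulating cameras that started recording at different
    times.
    """
    duration = (
        scene_or_duration.duration
        if isinstance(scene_or_duration, SyntheticScene)
        else float(scene_or_duration)
    )
    n = int(round(duration * rate))
    li = int(round(clap_time_s * rate))
    ri = li + int(stagger_samples)
    if not (0 <= li < n and 0 <= ri < n):
        raise LipStereoError(
            f"clap indices {li}, {ri} outside the {n}-sample track"
        )
    rng = np.random.default_rng(seed)
    left = rng.normal(0.0, noise_sd, size=n)
    right = rng.normal(0.0, noise_sd, size=n)
    left[li] = 1.0
    right[ri] = 1.0
    return AudioTrack(np.clip(left, -1, 1), rate), AudioTrack(np.clip(right, -1, 1), rate)


class CheckerboardData(NamedTuple):
    """Exact calibration correspondences from randomized board poses."""

    world: np.ndarray  # (m, 3) mm
    left_px: np.ndarray  # (m, 2)
    right_px: np.ndarray  # (m, 2)
    n_frames: int
    corners_per_frame: int


def checkerboard_correspondences(
    rig: StereoRig | None = None,
    rows: int = 18,
    cols: int = 25,
    square_mm: float = 15.0,
    n_frames: int = 50,
    seed: int = 0,
    max_retries: int = 100,
) -> CheckerboardData:
    """Generate exact 3D–2D correspondences from a waved checkerboard.

    Interior corners of a ``rows x cols``-square board (``(rows-1)*(cols-1)``
    per frame) are placed at randomized poses near the face position and
    projected into both cameras.  Poses leaving any corner out of view are
    resampled up to ``max_retries`` times per frame.  The board's 15 mm
    square size is what fixes the metric scale of the reconstruction.
    """
    rig = rig if rig is not None else default_rig()
    rng = np.random.default_rng(seed)
    nr, nc = rows - 1, cols - 1
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    board = np.stack(
        [
            (jj - (nc - 1) / 2.0) * square_mm,
            (ii - (nr - 1) / 2.0) * square_mm,
            np.zeros_like(ii, dtype=float),
        ],
        axis=-1,
    ).reshape(-1, 3)

    worlds, lpx, rpx = [], [], []
    for _ in range(n_frames):
        for attempt in range(max_retries):
            ang = np.deg2rad(rng.uniform(-25.0, 25.0, size=3))
            Rz = _yaw(np.array(ang[0]))
            Rx = _pitch(np.array(ang[1]))
            cz, sz = np.cos(ang[2]), np.sin(ang[2])
            Rroll = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
            Rb = Rz @ Rx @ Rroll
            center = FACE_CENTER_MM + rng.uniform(
                [-100.0, -80.0, -100.0], [100.0, 80.0, 150.0]
            )
            world = board @ Rb.T + center
            try:
                pl = project(rig.left, world)
                pr = project(rig.right, world)
            except BehindCameraError:
                continue
            inview = lambda p: bool(
                np.all((p[:, 0] >= 0) & (p[:, 0] < IMAGE_WIDTH)
                       & (p[:, 1] >= 0) & (p[:, 1] < IMAGE_HEIGHT))
            )
            if inview(pl) and inview(pr):
                worlds.append(world)
                lpx.append(pl)
                rpx.append(pr)
                break
        else:
            raise DegenerateGeometryError(
                f"no visible board pose found in {max_retries} attempts"
            )
    return CheckerboardData(
        world=np.concatenate(worlds),
        left_px=np.concatenate(lpx),
        right_px=np.concatenate(rpx),
        n_frames=n_frames,
        corners_per_frame=nr * nc,
    )
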