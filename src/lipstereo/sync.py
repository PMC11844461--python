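"""Clap-based temporal synchronization of the two camera streams.

Both cameras record the same clapboard impulse; the difference between the
two clap sample indices, converted to video frames, is the inter-camera
frame offset.  Detection is deliberately simple and deterministic: a
user-set amplitude threshold gates candidate samples, the global maximum of
|amplitude| among candidates wins, and ties break to the earliest index.

The sub-frame residual of the offset is recorded but not corrected here —
fine temporal alignment happens later against the reference stream
(:func:`lipstereo.kinematics.refine_align`), mirroring the two-stage timing
strategy of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import LipStereoError, NoClapFoundError
from .landmarks import LandmarkTrack2D

__all__ = [
    "AudioTrack",
    "SyncResult",
    "detect_clap",
    "compute_offset",
    "apply_frame_offset",
    "synchronize_tracks",
]

DEFAULT_CLAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class AudioTrack:
    """A mono audio signal with amplitudes normalized to [-1, 1]."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise LipStereoError("AudioTrack expects a 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise LipStereoError("audio contains non-finite samples")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise LipStereoError("audio rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self):
        return self.samples.shape[0]


@dataclass(frozen=True)
class SyncResult:
    """Inter-camera offset measured from the clap impulses.

    ``offset_samples = right_clap_index - left_clap_index``;
    ``offset_frames`` is that difference converted to video frames and
    rounded to the nearest integer (half away from zero).
    ``residual_frames`` is the signed sub-frame remainder left uncorrected.
    """

    offset_samples: int
    offset_frames: int
    left_clap_index: int
    right_clap_index: int
    audio_rate: float
    frame_rate: float

    @property
    def residual_frames(self) -> float:
        return (
            self.offset_samples * self.frame_rate / self.audio_rate
            - self.offset_frames
        )


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def detect_clap(audio: AudioTrack, threshold: float = DEFAULT_CLAP_THRESHOLD) -> int:
    """Locate the clap impulse: index of the largest |amplitude| at or above
    ``threshold``; ties break to the earliest index.

    Raises
    ------
    NoClapFoundError
        If no sample reaches the threshold; carries the maximum |amplitude|
        actually observed.
    """
    if not (0.0 < threshold <= 1.0):
        raise LipStereoError("clap threshold must lie in (0, 1]")
    mag = np.abs(audio.samples)
    peak = float(mag.max()) if len(audio) else 0.0
    if len(audio) == 0 or peak < threshold:
        raise NoClapFoundError(
            f"no sample reaches threshold {threshold} (max |amplitude| {peak:.4f})",
            max_amplitude=peak,
        )
    # np.argmax returns the first occurrence -> earliest-index tie-break.
    return int(np.argmax(mag))


def compute_offset(
    left: AudioTrack,
    right: AudioTrack,
    threshold: float = DEFAULT_CLAP_THRESHOLD,
    frame_rate: float = 60.0,
) -> SyncResult:
    """Clap offset between the two audio tracks, in samples and frames."""
    if left.rate != right.rate:
        raise LipStereoError(
            f"audio rates differ: {left.rate} vs {right.rate}"
        )
    if frame_rate <= 0:
        raise LipStereoError("frame rate must be positive")
    li = detect_clap(left, threshold)
    ri = detect_clap(right, threshold)
    ds = ri - li
    df = _round_half_away(ds * frame_rate / left.rate)
    return SyncResult(
        offset_samples=ds,
        offset_frames=df,
        left_clap_index=li,
        right_clap_index=ri,
        audio_rate=left.rate,
        frame_rate=frame_rate,
    )


def apply_frame_offset(track: LandmarkTrack2D, offset_frames: int) -> LandmarkTrack2D:
    """Shift a track's frame origin by ``offset_frames``.

    A positive offset drops that many frames from the head (the track's new
    frame 0 is the old frame ``offset_frames``); a negative offset truncates
    the tail instead, so the retained frames keep their timestamps.
    """
    o = int(offset_frames)
    if abs(o) >= track.n_frames:
        raise LipStereoError(
            f"offset {o} not smaller than track length {track.n_frames}"
        )
    if o >= 0:
        return track.slice_frames(o, track.n_frames)
    return track.slice_frames(0, track.n_frames + o)


def synchronize_tracks(
    left: LandmarkTrack2D, right: LandmarkTrack2D, offset_frames: int
) -> tuple[LandmarkTrack2D, LandmarkTrack2D]:
    """Make the two cameras' frame 0 simultaneous and equalize lengths.

    ``offset_frames`` is the :class:`SyncResult` convention (right minus
    left): a positive value means the clap appears later in the right track,
    i.e. the right camera started earlier, so its head is dropped.
    The non-overlapping head and tail frames are discarded on both sides.
    """
    o = int(offset_frames)
    if o > 0:
        right = apply_frame_offset(right, o)
    elif o < 0:
        left = apply_frame_offset(left, -o)
    n = min(left.n_frames, right.n_frames)
    return left.slice_frames(0, n), right.slice_frames(0, n)
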