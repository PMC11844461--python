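"""Lip-aperture kinematics: extraction, alignment and validation metrics.

Lip aperture (LA) is the 3D Euclidean distance between the mid-sagittal
upper- and lower-lip vermilion-border points,

    LA_i = sqrt((xu_i - xl_i)^2 + (yu_i - yl_i)^2 + (zu_i - zl_i)^2)   [mm],

computed per video frame from the triangulated landmark positions.  To
validate the video-derived LA against a reference articulograph stream
(250 Hz), the pipeline:

1. upsamples the video LA to the reference rate (linear interpolation);
2. coarsely aligns the two series on their global LA maxima;
3. refines the alignment by exhaustive integer-shift search minimizing RMSE;
4. segments the utterance between the first and last bilabial-closure
   minima of the aligned reference;
5. additively normalizes the test series to the reference mean over the
   utterance window (sensor placement and landmark placement differ by a
   roughly constant offset);
6. reports the final RMSE over the window.

Precision on static-lip clips is simply the sample standard deviation of LA
across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.signal

from .errors import AlignmentError, LipStereoError

__all__ = [
    "ApertureSeries",
    "UtteranceWindow",
    "AlignmentResult",
    "NormalizationResult",
    "AccuracyReport",
    "lip_aperture",
    "resample",
    "coarse_align",
    "refine_align",
    "find_closure_minima",
    "utterance_window",
    "normalize_offset",
    "rmse",
    "precision_sd",
    "accuracy_report",
]

REFERENCE_RATE_HZ = 250.0


@dataclass(frozen=True)
class ApertureSeries:
    """A lip-aperture signal sampled at a fixed rate.

    ``values`` are millimetres; physically apertures are nonnegative, and
    every generator in this package produces nonnegative series, but the
    container does not enforce it because additive normalization may shift a
    series by a signed constant.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise LipStereoError("ApertureSeries expects a 1-D value array")
        if not np.all(np.isfinite(v)):
            raise LipStereoError("aperture values must be finite")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise LipStereoError("sampling rate must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return self.values.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate


@dataclass(frozen=True)
class UtteranceWindow:
    """Inclusive sample-index window [onset_index, offset_index]."""

    onset_index: int
    offset_index: int

    def __post_init__(self):
        if not (0 <= self.onset_index < self.offset_index):
            raise LipStereoError(
                f"invalid utterance window ({self.onset_index}, {self.offset_index})"
            )

    def slice(self) -> slice:
        return slice(self.onset_index, self.offset_index + 1)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of the fine RMSE-minimizing shift search."""

    lag: int
    rmse_at_lag: float
    search_range: int


@dataclass(frozen=True)
class NormalizationResult:
    """Additive amplitude normalization over an utterance window."""

    additive_offset: float
    window: UtteranceWindow


@dataclass(frozen=True)
class AccuracyReport:
    """Full record of one test-vs-reference accuracy comparison."""

    rate: float
    coarse_lag: int
    alignment: AlignmentResult
    segment_start: int
    n_overlap: int
    minima_indices: tuple[int, ...]
    window: UtteranceWindow
    additive_offset_mm: float
    rmse_mm: float


def _values(series) -> np.ndarray:
    if isinstance(series, ApertureSeries):
        return series.values
    v = np.asarray(series, dtype=float)
    if v.ndim != 1:
        raise LipStereoError("expected a 1-D series")
    return v


def lip_aperture(upper, lower, rate: float, t0: float = 0.0) -> ApertureSeries:
    """Per-frame 3D distance between the upper and lower lip points (mm)."""
    u = np.atleast_2d(np.asarray(upper, dtype=float))
    l = np.atleast_2d(np.asarray(lower, dtype=float))
    if u.shape != l.shape:
        raise LipStereoError(f"upper/lower lengths differ: {u.shape} vs {l.shape}")
    if u.shape[-1] != 3:
        raise LipStereoError("points must be 3-D")
    return ApertureSeries(np.linalg.norm(u - l, axis=-1), rate=rate, t0=t0)


def resample(series: ApertureSeries, target_rate: float = REFERENCE_RATE_HZ) -> ApertureSeries:
    """Linearly interpolate a series onto a uniform target-rate grid.

    The new grid spans [t0, t_last]; its length is
    ``floor((t_last - t0) * target_rate) + 1``.  Linear interpolation is
    shape preserving (no overshoot) and exact for the identity case.
    """
    if not (np.isfinite(target_rate) and target_rate > 0):
        raise LipStereoError("target rate must be positive")
    if len(series) < 2:
        raise LipStereoError("resampling needs at least 2 samples")
    span = (len(series) - 1) / series.rate
    n_out = int(np.floor(span * target_rate + 1e-9)) + 1
    t_new = np.arange(n_out) / target_rate
    t_old = np.arange(len(series)) / series.rate
    return ApertureSeries(
        np.interp(t_new, t_old, series.values), rate=target_rate, t0=series.t0
    )


def coarse_align(a: ApertureSeries, b: ApertureSeries) -> int:
    """Coarse lag from the global LA maxima: argmax(b) - argmax(a).

    Ties resolve to the earliest sample.  With this sign convention,
    ``b[i + lag]`` corresponds to ``a[i]``.
    """
    va, vb = _values(a), _values(b)
    if len(va) == 0 or len(vb) == 0:
        raise AlignmentError("cannot align an empty series")
    if isinstance(a, ApertureSeries) and isinstance(b, ApertureSeries) and a.rate != b.rate:
        raise AlignmentError(f"rates differ: {a.rate} vs {b.rate}")
    return int(np.argmax(vb)) - int(np.argmax(va))


def refine_align(
    a,
    b,
    initial_lag: int = 0,
    max_shift: int = 50,
    min_overlap: int = 10,
) -> AlignmentResult:
    """Exhaustive integer-shift search minimizing RMSE around ``initial_lag``.

    For every shift ``s`` in ``[initial_lag - max_shift, initial_lag +
    max_shift]`` the RMSE between ``a[i]`` and ``b[i + s]`` is evaluated
    over the overlapping region; the minimizing shift is returned.  Ties
    (RMSE equal to within 1e-9 relative) break to the smallest |lag|, then
    to the more negative lag.

    Raises
    ------
    AlignmentError
        If no tested shift leaves at least ``min_overlap`` samples.
    """
    va, vb = _values(a), _values(b)
    if (
        isinstance(a, ApertureSeries)
        and isinstance(b, ApertureSeries)
        and a.rate != b.rate
    ):
        raise AlignmentError(f"rates differ: {a.rate} vs {b.rate}")
    candidates: list[tuple[float, int]] = []
    for s in range(int(initial_lag) - int(max_shift), int(initial_lag) + int(max_shift) + 1):
        i0 = max(0, -s)
        i1 = min(len(va), len(vb) - s)
        if i1 - i0 < min_overlap:
            continue
        d = va[i0:i1] - vb[i0 + s : i1 + s]
        candidates.append((float(np.sqrt(np.mean(d * d))), s))
    if not candidates:
        raise AlignmentError(
            f"no shift within ±{max_shift} of {initial_lag} leaves "
            f"{min_overlap} overlapping samples"
        )
    rmin = min(r for r, _ in candidates)
    tol = rmin * 1e-9 + 1e-12
    tied = [s for r, s in candidates if r <= rmin + tol]
    best = min(tied, key=lambda s: (abs(s), s))
    best_rmse = next(r for r, s in candidates if s == best)
    return AlignmentResult(lag=best, rmse_at_lag=best_rmse, search_range=int(max_shift))


def find_closure_minima(
    series, min_prominence: float, min_separation: int = 1
) -> np.ndarray:
    """Indices of bilabial-closure minima in a lip-aperture series.

    A closure is an interior local minimum whose prominence — the height of
    the lower of the two surrounding peaks above the minimum — reaches
    ``min_prominence`` (mm).  Minima closer than ``min_separation`` samples
    are pruned keeping the deeper one.  May return an empty array.
    """
    if not (np.isfinite(min_prominence) and min_prominence > 0):
        raise LipStereoError("min_prominence must be positive")
    v = _values(series)
    if len(v) < 3:
        return np.array([], dtype=int)
    idx, _ = scipy.signal.find_peaks(
        -v, prominence=min_prominence, distance=max(1, int(min_separation))
    )
    return idx


def utterance_window(
    minima: Sequence[int],
    mode: str = "first-last",
    select: tuple[int, int] | None = None,
) -> UtteranceWindow:
    """Build the utterance window from closure-minima indices.

    ``"first-last"`` spans from the first to the last detected closure.
    ``"explicit"`` picks two minima by position in the list via ``select``
    (for manual selection when an utterance contains extra closures).
    """
    idx = [int(i) for i in minima]
    if len(idx) < 2:
        raise AlignmentError(
            f"need at least 2 closure minima to delimit an utterance, got {len(idx)}"
        )
    if mode == "first-last":
        return UtteranceWindow(idx[0], idx[-1])
    if mode == "explicit":
        if select is None:
            raise LipStereoError("explicit window mode requires select=(i, j)")
        return UtteranceWindow(idx[select[0]], idx[select[1]])
    raise LipStereoError(f"unknown window mode {mode!r}")


def normalize_offset(series, reference, window: UtteranceWindow):
    """Additively normalize ``series`` to the reference mean over a window.

    The articulograph sensors and the video landmarks sit at slightly
    different anatomical locations, producing a near-constant amplitude
    offset; it is removed by adding ``mean(reference) - mean(series)`` over
    the utterance window.  No gain/scale is fitted.

    Returns ``(normalized, NormalizationResult)``; the normalized object has
    the same type as the input (array or :class:`ApertureSeries`).
    """
    vs, vr = _values(series), _values(reference)
    for name, v in (("series", vs), ("reference", vr)):
        if window.offset_index >= len(v):
            raise LipStereoError(
                f"window ({window.onset_index}, {window.offset_index}) exceeds "
                f"{name} length {len(v)}"
            )
    offset = float(np.mean(vr[window.slice()]) - np.mean(vs[window.slice()]))
    result = NormalizationResult(additive_offset=offset, window=window)
    if isinstance(series, ApertureSeries):
        return replace(series, values=vs + offset), result
    return vs + offset, result


def rmse(a, b, window: UtteranceWindow | None = None) -> float:
    """Root mean square difference between two aligned series (mm)."""
    va, vb = _values(a), _values(b)
    if window is not None:
        if window.offset_index >= min(len(va), len(vb)):
            raise LipStereoError("window exceeds series length")
        va, vb = va[window.slice()], vb[window.slice()]
    if len(va) != len(vb):
        raise LipStereoError(f"length mismatch: {len(va)} vs {len(vb)}")
    if len(va) == 0:
        raise LipStereoError("RMSE of empty series")
    d = va - vb
    return float(np.sqrt(np.mean(d * d)))


def precision_sd(series) -> float:
    """Sample standard deviation (divisor N-1) of a lip-aperture series (mm)."""
    v = _values(series)
    if len(v) < 2:
        raise LipStereoError("precision SD needs at least 2 samples")
    return float(np.std(v, ddof=1))


def accuracy_report(
    test: ApertureSeries,
    reference: ApertureSeries,
    *,
    max_shift: int = 50,
    min_prominence: float = 1.0,
    min_separation: int | None = None,
    window_mode: str = "first-last",
    window_select: tuple[int, int] | None = None,
    min_overlap: int = 10,
) -> AccuracyReport:
    """Run the full accuracy comparison of a test LA series against a
    reference stream.

    Composition: resample the test to the reference rate → coarse peak
    alignment → RMSE-minimizing shift refinement (on raw amplitudes) →
    closure segmentation on the aligned reference → additive normalization →
    final RMSE.  Deterministic given inputs and parameters.
    """
    rate = reference.rate
    if test.rate != rate:
        test = resample(test, rate)
    if min_separation is None:
        min_separation = max(1, int(round(0.1 * rate)))

    coarse = coarse_align(test, reference)
    align = refine_align(test, reference, coarse, max_shift, min_overlap=min_overlap)
    s = align.lag
    i0 = max(0, -s)
    i1 = min(len(test), len(reference) - s)
    t_seg = test.values[i0:i1]
    r_seg = reference.values[i0 + s : i1 + s]

    minima = find_closure_minima(r_seg, min_prominence, min_separation)
    window = utterance_window(minima, mode=window_mode, select=window_select)
    t_norm, norm = normalize_offset(t_seg, r_seg, window)
    final = rmse(t_norm, r_seg, window)

    return AccuracyReport(
        rate=rate,
        coarse_lag=int(coarse),
        alignment=align,
        segment_start=int(i0),
        n_overlap=int(i1 - i0),
        minima_indices=tuple(int(i) for i in minima),
        window=window,
        additive_offset_mm=norm.additive_offset,
        rmse_mm=final,
    )
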