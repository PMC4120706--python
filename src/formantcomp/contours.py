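"""Algebra on formant frequency and amplitude contours.

A formant track is a frame-sampled pair of contours: center frequency in Hz
and linear amplitude, one value per 1-ms frame.  All depth manipulations
operate on log frequency about the geometric mean of the whole contour, so
that scaling and inversion are symmetric on a log axis and leave the
geometric mean untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import InvalidTrackError

__all__ = [
    "FormantTrack",
    "CycleEstimate",
    "TriangleSpec",
    "geometric_mean",
    "scale_depth",
    "invert_about_gmean",
    "block_smooth",
    "estimate_cycles",
    "triangle_contour",
    "flatten_amplitude",
    "check_min_separation",
    "TRIANGLE_HARMONICS",
    "TRIANGLE_PEAK",
]

#: Odd harmonics retained in the band-limited triangle wave.
TRIANGLE_HARMONICS: tuple[int, ...] = (1, 3, 5, 7)

#: Analytic peak of the truncated triangle-wave series, attained at phase 0:
#: (8/pi^2) * (1 + 1/9 + 1/25 + 1/49).  Normalising by this value bounds the
#: series exactly in [-1, 1] regardless of how frames sample the phase.
TRIANGLE_PEAK: float = (8.0 / math.pi**2) * sum(1.0 / n**2 for n in TRIANGLE_HARMONICS)


@dataclass(frozen=True)
class FormantTrack:
    """Frame-sampled frequency and amplitude contour of one formant.

    Parameters
    ----------
    freqs : array of float
        Center frequency per frame, Hz; all values must be positive.
    amps : array of float
        Linear amplitude per frame, dimensionless, >= 0.
    frame_period : float
        Frame spacing in seconds (default 1 ms).
    label : str
        Free-text label, e.g. ``"F2"``.
    """

    freqs: NDArray[np.float64]
    amps: NDArray[np.float64]
    frame_period: float = 0.001
    label: str = ""

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        amps = np.asarray(self.amps, dtype=np.float64)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "amps", amps)
        if freqs.ndim != 1 or amps.ndim != 1:
            raise InvalidTrackError("freqs and amps must be 1-D")
        if len(freqs) == 0:
            raise InvalidTrackError("track must contain at least one frame")
        if len(freqs) != len(amps):
            raise InvalidTrackError(
                f"freqs ({len(freqs)}) and amps ({len(amps)}) differ in length"
            )
        if not np.all(np.isfinite(freqs)) or np.any(freqs <= 0):
            raise InvalidTrackError("all frequencies must be finite and > 0")
        if not np.all(np.isfinite(amps)) or np.any(amps < 0):
            raise InvalidTrackError("all amplitudes must be finite and >= 0")
        if not self.frame_period > 0:
            raise InvalidTrackError("frame_period must be > 0")

    def __len__(self) -> int:
        return len(self.freqs)

    @property
    def duration(self) -> float:
        """Track duration in seconds (frames x frame period)."""
        return len(self.freqs) * self.frame_period

    @property
    def times(self) -> NDArray[np.float64]:
        """Frame-start times in seconds."""
        return np.arange(len(self.freqs)) * self.frame_period


@dataclass(frozen=True)
class CycleEstimate:
    """Modulation-cycle estimate for a formant contour.

    ``half_cycles`` is the number of geometric-mean crossings plus one, so a
    contour that never crosses its mean still counts as half a cycle.
    ``period_T`` is the track duration divided by ``cycles`` and retains
    half-cycle precision.
    """

    half_cycles: int
    cycles: float = field(init=False)
    period_T: float = field(init=False)
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.half_cycles < 1:
            raise ValueError("half_cycles must be >= 1")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        object.__setattr__(self, "cycles", self.half_cycles / 2.0)
        object.__setattr__(self, "period_T", self.duration / (self.half_cycles / 2.0))


@dataclass(frozen=True)
class TriangleSpec:
    """Parameters of a band-limited triangle-wave log-frequency contour.

    Parameters
    ----------
    g : float
        Geometric-mean pivot frequency, Hz.
    r : float
        Half the log-range (natural log) of the target F2 contour.
    period_T : float
        Modulation period in seconds.
    start_phase : float
        Starting phase as a fraction of one period, in [0, 1).
    scale_x : float
        Depth scale factor in [0, 1].
    """

    g: float
    r: float
    period_T: float
    start_phase: float = 0.0
    scale_x: float = 1.0

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError("g must be > 0")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not self.period_T > 0:
            raise ValueError("period_T must be > 0")
        if not 0.0 <= self.start_phase < 1.0:
            raise ValueError("start_phase must lie in [0, 1)")
        if not 0.0 <= self.scale_x <= 1.0:
            raise ValueError("scale_x must lie in [0, 1]")


def geometric_mean(track: FormantTrack) -> float:
    """Geometric mean of the whole frequency contour, unweighted over frames.

    Returns ``exp(mean(log f))`` in Hz.
    """
    return float(np.exp(np.mean(np.log(track.freqs))))


def scale_depth(track: FormantTrack, x: float) -> FormantTrack:
    """Rescale the depth of frequency variation about the geometric mean.

    Per frame, ``log s = log g + x * log(f / g)`` where ``g`` is the
    geometric mean of the whole contour.  ``x = 0`` collapses the contour to
    a constant at ``g``; ``x = 1`` is the identity.  Amplitudes are never
    adjusted.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"scale factor x must lie in [0, 1], got {x}")
    g = geometric_mean(track)
    scaled = g * (track.freqs / g) ** x
    return replace(track, freqs=scaled)


def invert_about_gmean(track: FormantTrack) -> FormantTrack:
    """Reflect the frequency contour about its geometric mean on a log scale.

    Per frame, ``log s = log g - log(f / g)``, i.e. ``s = g**2 / f``.  The
    operation is an involution and preserves both the geometric mean and the
    rate and depth of frequency variation.  Amplitudes are unchanged.
    """
    g = geometric_mean(track)
    return replace(track, freqs=g * g / track.freqs)


def block_smooth(freqs: ArrayLike, block: int = 40) -> NDArray[np.float64]:
    """Down-sample a contour by non-overlapping block averaging.

    With 1-ms frames the default 40-sample block corresponds to low-pass
    filtering at 25 Hz.  A trailing partial block is averaged over its own
    length rather than dropped.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.size == 0:
        raise InvalidTrackError("contour must be non-empty")
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    n_full = freqs.size // block
    out = []
    if n_full:
        out.append(freqs[: n_full * block].reshape(n_full, block).mean(axis=1))
    if freqs.size % block:
        out.append(np.array([freqs[n_full * block :].mean()]))
    return np.concatenate(out)


def estimate_cycles(smoothed: ArrayLike, g: float, duration: float) -> CycleEstimate:
    """Estimate the modulation period of a contour from mean crossings.

    Counts sign changes of ``value - g`` between successive samples of the
    (already smoothed) contour; the number of half-cycles is the crossing
    count plus one, so precision is retained in half-cycles.  A sample lying
    exactly on ``g`` is treated as positive.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if smoothed.size == 0:
        raise InvalidTrackError("smoothed contour must be non-empty")
    if not g > 0:
        raise ValueError("g must be > 0")
    if not duration > 0:
        raise ValueError("duration must be > 0")
    # sign with zero treated as positive
    signs = np.where(smoothed - g >= 0, 1, -1)
    crossings = int(np.count_nonzero(signs[1:] != signs[:-1]))
    return CycleEstimate(half_cycles=crossings + 1, duration=duration)


def triangle_wave(t: ArrayLike, period_T: float, start_phase: float = 0.0) -> NDArray[np.float64]:
    """Band-limited triangle wave normalised to peak +/-1.

    ``a(t) = (8/pi^2) * sum_{n in 1,3,5,7} (1/n^2) cos(2 pi n (t + phi T)/T)``
    divided by its analytic peak so the result is bounded exactly in [-1, 1].
    """
    t = np.asarray(t, dtype=np.float64)
    arg = 2.0 * math.pi * (t + start_phase * period_T) / period_T
    a = np.zeros_like(t)
    for n in TRIANGLE_HARMONICS:
        a += np.cos(n * arg) / n**2
    a *= 8.0 / math.pi**2
    return a / TRIANGLE_PEAK


def triangle_contour(
    spec: TriangleSpec, duration: float, frame_period: float = 0.001
) -> FormantTrack:
    """Generate a triangle-wave frequency contour on a log scale.

    The normalised triangle wave modulates log frequency about the pivot:
    ``f(t) = g * exp(x * r * a_hat(t))``, giving a peak-to-trough log-range
    of ``2 x r`` centered on ``g``.  Amplitudes are set to 1 as a
    placeholder; RMS flattening is applied downstream.
    """
    if duration < frame_period:
        raise ValueError("duration must be at least one frame period")
    n_frames = int(round(duration / frame_period))
    t = np.arange(n_frames) * frame_period
    a_hat = triangle_wave(t, spec.period_T, spec.start_phase)
    freqs = spec.g * np.exp(spec.scale_x * spec.r * a_hat)
    return FormantTrack(
        freqs=freqs,
        amps=np.ones(n_frames),
        frame_period=frame_period,
        label="F2C",
    )


def flatten_amplitude(track: FormantTrack) -> FormantTrack:
    """Replace the amplitude contour by its constant RMS value.

    An all-zero amplitude contour is returned unchanged with a warning,
    since the resulting stimulus would be silent.
    """
    rms = float(np.sqrt(np.mean(track.amps**2)))
    if rms == 0.0:
        warnings.warn(
            "amplitude contour is all zero; flattened track is silent",
            stacklevel=2,
        )
    return replace(track, amps=np.full(len(track), rms))


def check_min_separation(
    a: FormantTrack, b: FormantTrack, min_hz: float = 80.0
) -> list[int]:
    """Frames at which two tracks approach closer than ``min_hz``.

    Returns the indices ``i`` with ``|a.freqs[i] - b.freqs[i]| < min_hz``;
    an empty list means the proximity constraint is satisfied everywhere.
    """
    if len(a) != len(b):
        raise InvalidTrackError(
            f"tracks differ in length ({len(a)} vs {len(b)})"
        )
    if not math.isclose(a.frame_period, b.frame_period):
        raise InvalidTrackError("tracks differ in frame period")
    gaps = np.abs(a.freqs - b.freqs)
    return [int(i) for i in np.nonzero(gaps < min_hz)[0]]
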