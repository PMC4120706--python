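"""Parallel-formant synthesis of dichotic stimuli.

The synthesizer drives time-varying second-order resonators in parallel
from a common glottal-pulse source.  Each resonator follows one formant
frequency contour; its output is weighted by the formant's amplitude
contour and the weighted outputs are summed (with alternating polarity to
avoid deep spectral zeros between formants).  Stimuli are rendered at
22.05 kHz with 10-ms raised-cosine onset/offset ramps and written as
16-bit PCM stereo WAV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.io import wavfile

from .contours import FormantTrack
from .exceptions import InvalidTrackError

__all__ = [
    "SourceSpec",
    "ResonatorSpec",
    "StereoStimulus",
    "glottal_source",
    "resonate",
    "synthesize_formants",
    "apply_ramps",
    "assemble_dichotic",
    "write_wav",
    "read_wav",
    "DEFAULT_SAMPLE_RATE",
]

DEFAULT_SAMPLE_RATE = 22050

#: Constant 3-dB bandwidths (Hz) per formant label; the competitor shares
#: the F2 bandwidth.
DEFAULT_BANDWIDTHS = {"F1": 50.0, "F2": 70.0, "F3": 90.0, "F2C": 70.0}


@dataclass(frozen=True)
class SourceSpec:
    """Glottal excitation source: a Rosenberg-style pulse train.

    ``f0_hz`` may be a scalar (monotone voice, default 140 Hz) or a per-frame
    contour.  ``open_fraction`` and ``closing_fraction`` are the opening and
    closing portions of each glottal period; the remainder is closed.
    """

    f0_hz: float | NDArray[np.float64] = 140.0
    open_fraction: float = 0.6
    closing_fraction: float = 0.2
    sample_rate: int = DEFAULT_SAMPLE_RATE
    frame_period: float = 0.001

    def __post_init__(self) -> None:
        f0 = np.atleast_1d(np.asarray(self.f0_hz, dtype=np.float64))
        object.__setattr__(self, "f0_hz", f0)
        if np.any(f0 <= 0) or np.any(f0 >= self.sample_rate / 4):
            raise ValueError("f0 must satisfy 0 < f0 < sample_rate/4")
        if not (0 < self.open_fraction < 1 and 0 < self.closing_fraction < 1):
            raise ValueError("pulse fractions must lie in (0, 1)")
        if self.open_fraction + self.closing_fraction > 1:
            raise ValueError("open + closing fractions must be <= 1")


@dataclass(frozen=True)
class ResonatorSpec:
    """Resonator bank configuration: per-formant 3-dB bandwidths."""

    bandwidths_hz: dict = field(default_factory=lambda: dict(DEFAULT_BANDWIDTHS))
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        for label, bw in self.bandwidths_hz.items():
            if not 0 < bw < self.sample_rate / 2:
                raise ValueError(f"bandwidth for {label} out of range: {bw}")

    def bandwidth_for(self, label: str) -> float:
        return self.bandwidths_hz.get(label, self.bandwidths_hz.get("F2", 70.0))


@dataclass
class StereoStimulus:
    """Two-channel sampled stimulus with condition metadata."""

    sample_rate: int
    left: NDArray[np.float64]
    right: NDArray[np.float64]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise InvalidTrackError("channel lengths differ")

    @property
    def duration(self) -> float:
        return len(self.left) / self.sample_rate


def _per_sample(contour: NDArray[np.float64], n_samples: int, frame_period: float,
                sample_rate: int) -> NDArray[np.float64]:
    """Linearly interpolate a per-frame contour to per-sample values."""
    contour = np.asarray(contour, dtype=np.float64)
    if contour.size == 1:
        return np.full(n_samples, contour[0])
    frame_t = np.arange(contour.size) * frame_period
    sample_t = np.arange(n_samples) / sample_rate
    return np.interp(sample_t, frame_t, contour)


def rosenberg_pulse(phase: NDArray[np.float64], open_fraction: float,
                    closing_fraction: float) -> NDArray[np.float64]:
    """Rosenberg glottal-flow waveform as a function of cycle phase in [0, 1).

    Flow rises as ``0.5 (1 - cos(pi p / tp))`` over the opening portion,
    falls as ``cos(pi (p - tp) / (2 tn))`` over the closing portion, and is
    zero during closure.
    """
    tp, tn = open_fraction, closing_fraction
    y = np.zeros_like(phase)
    opening = phase < tp
    closing = (phase >= tp) & (phase < tp + tn)
    y[opening] = 0.5 * (1.0 - np.cos(math.pi * phase[opening] / tp))
    y[closing] = np.cos(math.pi * (phase[closing] - tp) / (2.0 * tn))
    return y


def glottal_source(spec: SourceSpec, duration: float) -> NDArray[np.float64]:
    """Rosenberg pulse train for ``duration`` seconds.

    Cycle boundaries are placed by accumulating instantaneous phase from the
    interpolated F0 contour, so fractional periods (e.g. 157.5 samples per
    cycle at 140 Hz / 22.05 kHz) are honoured on average.  The waveform is
    returned zero-mean.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n = int(round(duration * spec.sample_rate))
    if n == 0:
        return np.zeros(0)
    f0 = _per_sample(np.atleast_1d(spec.f0_hz), n, spec.frame_period, spec.sample_rate)
    phase = np.cumsum(f0 / spec.sample_rate)  # cycles, monotone
    frac = np.mod(phase, 1.0)
    pulse = rosenberg_pulse(frac, spec.open_fraction, spec.closing_fraction)
    return pulse - pulse.mean()


def _resonator_coeffs(freqs: NDArray[np.float64], bandwidth: float,
                      sample_rate: int):
    """Per-sample coefficients of a unity-peak-gain two-pole resonator.

    Pole radius ``exp(-pi B / fs)``, pole angle ``2 pi F / fs``; the input
    gain ``b0`` normalises the transfer function to magnitude 1 at the
    instantaneous center frequency.
    """
    r = math.exp(-math.pi * bandwidth / sample_rate)
    theta = 2.0 * math.pi * freqs / sample_rate
    a1 = 2.0 * r * np.cos(theta)
    a2 = -r * r
    z = np.exp(-1j * theta)
    b0 = np.abs(1.0 - a1 * z - a2 * z * z)
    return b0, a1, a2


def resonate(source: ArrayLike, freq_contour: ArrayLike, bandwidth: float,
             sample_rate: int = DEFAULT_SAMPLE_RATE,
             frame_period: float = 0.001) -> NDArray[np.float64]:
    """Filter a source through a time-varying second-order resonator.

    The per-frame frequency contour is linearly interpolated to per-sample
    center frequencies; filter coefficients track them sample by sample.
    """
    source = np.asarray(source, dtype=np.float64)
    freq_contour = np.asarray(freq_contour, dtype=np.float64)
    if np.any(freq_contour >= sample_rate / 2):
        raise ValueError("formant frequency at or above Nyquist")
    if np.any(freq_contour <= 0):
        raise ValueError("formant frequency must be positive")
    n = source.size
    if n == 0:
        return np.zeros(0)
    freqs = _per_sample(freq_contour, n, frame_period, sample_rate)
    b0, a1, a2 = _resonator_coeffs(freqs, bandwidth, sample_rate)
    y = np.empty(n)
    y1 = 0.0
    y2 = 0.0
    x = source
    for i in range(n):
        yi = b0[i] * x[i] + a1[i] * y1 + a2 * y2
        y[i] = yi
        y2 = y1
        y1 = yi
    return y


def synthesize_formants(
    tracks: list[FormantTrack],
    source: SourceSpec | None = None,
    res: ResonatorSpec | None = None,
    polarity_scheme: str = "alternating",
    normalize_peak: float | None = None,
) -> NDArray[np.float64]:
    """Render formant tracks to a mono waveform via parallel resonators.

    Each track's resonator output is multiplied by its per-sample
    interpolated amplitude contour; outputs are summed with alternating
    polarity (+, -, +, ...) by default.  With ``normalize_peak`` set, the
    result is scaled so its peak magnitude equals that value.
    """
    if not tracks:
        raise InvalidTrackError("at least one track is required")
    source = source or SourceSpec()
    res = res or ResonatorSpec(sample_rate=source.sample_rate)
    durations = {len(t) for t in tracks}
    periods = {t.frame_period for t in tracks}
    if len(durations) > 1 or len(periods) > 1:
        raise InvalidTrackError("all tracks must share duration and frame period")
    duration = tracks[0].duration
    fs = source.sample_rate
    flow = glottal_source(source, duration)
    # excite with the glottal-flow derivative: folds the +6 dB/oct lip
    # radiation characteristic into the source, as in standard source-filter
    # synthesis, so formant-region harmonics dominate the output spectrum
    excitation = np.diff(flow, prepend=flow[:1])
    n = excitation.size
    total = np.zeros(n)
    for k, track in enumerate(tracks):
        bw = res.bandwidth_for(track.label or f"F{k + 1}")
        y = resonate(excitation, track.freqs, bw, fs, track.frame_period)
        amp = _per_sample(track.amps, n, track.frame_period, fs)
        sign = -1.0 if (polarity_scheme == "alternating" and k % 2 == 1) else 1.0
        total += sign * amp * y
    if normalize_peak is not None:
        peak = np.max(np.abs(total))
        if peak > 0:
            total = total * (normalize_peak / peak)
    return total


def apply_ramps(wave: ArrayLike, ramp: float = 0.010,
                sample_rate: int = DEFAULT_SAMPLE_RATE) -> NDArray[np.float64]:
    """Apply raised-cosine onset and offset ramps (default 10 ms)."""
    wave = np.asarray(wave, dtype=np.float64)
    n_ramp = int(round(ramp * sample_rate))
    if wave.size < 2 * n_ramp:
        raise InvalidTrackError("waveform shorter than two ramps")
    out = wave.copy()
    if n_ramp > 0:
        t = np.arange(n_ramp) / (n_ramp * 1.0)
        env = 0.5 * (1.0 - np.cos(math.pi * t))
        out[:n_ramp] *= env
        out[-n_ramp:] *= env[::-1]
    return out


def assemble_dichotic(
    left_tracks: list[FormantTrack],
    right_tracks: list[FormantTrack],
    level_offsets_db: tuple[float, float] = (0.0, 0.0),
    source: SourceSpec | None = None,
    res: ResonatorSpec | None = None,
    ramp: float = 0.010,
    headroom: float = 0.9,
    auto_normalize: bool = True,
    meta: dict | None = None,
) -> StereoStimulus:
    """Synthesize each ear independently and combine into a stereo stimulus.

    Per-ear dB offsets are applied to the raw synthesized waveforms, after
    which both channels are scaled by a single common factor so the overall
    peak equals ``headroom`` (preserving the inter-ear level ratio).  An
    empty track list yields a silent ear.
    """
    source = source or SourceSpec()
    fs = source.sample_rate
    all_tracks = left_tracks + right_tracks
    if not all_tracks:
        raise InvalidTrackError("both ears are empty")
    duration = all_tracks[0].duration
    n = int(round(duration * fs))

    def render(tracks):
        if not tracks:
            return np.zeros(n)
        w = synthesize_formants(tracks, source, res)
        return apply_ramps(w, ramp, fs)

    left = render(left_tracks) * 10.0 ** (level_offsets_db[0] / 20.0)
    right = render(right_tracks) * 10.0 ** (level_offsets_db[1] / 20.0)
    peak = max(np.max(np.abs(left)), np.max(np.abs(right)))
    if peak > 0:
        if auto_normalize:
            scale = headroom / peak
            left = left * scale
            right = right * scale
        elif peak > 1.0:
            raise ValueError(f"stimulus clips (peak {peak:.3f}) and "
                             "auto_normalize is disabled")
    info = {"level_offsets_db": tuple(level_offsets_db)}
    if meta:
        info.update(meta)
    return StereoStimulus(sample_rate=fs, left=left, right=right, meta=info)


def write_wav(stim: StereoStimulus, path: str | Path) -> Path:
    """Write a stimulus as 16-bit PCM stereo WAV."""
    path = Path(path)
    data = np.stack([stim.left, stim.right], axis=1)
    scaled = np.clip(data, -1.0, 1.0)
    pcm = np.round(scaled * 32767.0).astype(np.int16)
    wavfile.write(path, stim.sample_rate, pcm)
    return path


def read_wav(path: str | Path) -> StereoStimulus:
    """Read a 16-bit stereo WAV back into a :class:`StereoStimulus`."""
    rate, pcm = wavfile.read(path)
    data = pcm.astype(np.float64) / 32767.0
    if data.ndim == 1:
        data = np.stack([data, data], axis=1)
    return StereoStimulus(sample_rate=int(rate), left=data[:, 0], right=data[:, 1])
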