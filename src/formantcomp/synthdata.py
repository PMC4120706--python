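"""Synthetic formant-track corpora and simulated listener responses.

No public corpus of hand-corrected sentence formant tracks exists, so this
module generates plausible stand-ins: smooth, non-crossing F1-F3 contours
near typical adult-male centers (500/1500/2500 Hz) with syllable-like
amplitude modulation, at 1-ms frames.  Log-frequency contours are
band-limited sums of random-phase cosines (2-6 Hz), so their modulation
rates and log-ranges are known analytically and can serve as test oracles.
Simulated listener responses draw keyword outcomes as independent
Bernoulli trials from a Weibull psychometric function of the condition
covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contours import FormantTrack
from .paradigm import SentenceTracks
from .psychometrics import WeibullParams, weibull_eval

__all__ = [
    "SyntheticSentenceSpec",
    "SimulatedListenerSpec",
    "make_tracks",
    "make_corpus",
    "simulate_responses",
]

# small word pool for synthetic keyword lists (BKB-like content words)
_WORD_POOL = (
    "cat dog mud boat rain tree house spoon bread milk door clock green "
    "brown small clean ball girl boy book road hand fire wall fish bird "
    "chair table floor water glass paper shoe coat bag cup"
).split()

# trivial letter-to-symbol lookup used only to give fixtures phoneme strings
_G2P = {c: c for c in "abcdefghijklmnopqrstuvwxyz"}


@dataclass(frozen=True)
class SyntheticSentenceSpec:
    """Recipe for one synthetic sentence's formant tracks.

    Defaults emulate a typical adult male vocal tract: formant centers at
    500/1500/2500 Hz, log-frequency excursions of 0.25/0.30/0.12 (natural
    log) around them, contour components in the 2-6 Hz modulation band, and
    a 4-Hz syllabic amplitude envelope.  Durations are drawn uniformly from
    1.5-2.5 s when not fixed.
    """

    duration: float | None = None
    formant_centers: tuple[float, float, float] = (500.0, 1500.0, 2500.0)
    log_excursion: tuple[float, float, float] = (0.25, 0.30, 0.12)
    modulation_rate_band: tuple[float, float] = (2.0, 6.0)
    syllable_rate: float = 4.0
    n_keywords: int | None = None
    amp_peaks: tuple[float, float, float] = (1.0, 0.35, 0.15)
    min_f2_f1_gap_hz: float = 200.0
    frame_period: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        c = self.formant_centers
        if not (c[0] < c[1] < c[2]):
            raise ValueError("formant centers must be strictly increasing")
        if any(e < 0 for e in self.log_excursion):
            raise ValueError("log excursions must be >= 0")
        if self.duration is not None and not self.duration > 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class SimulatedListenerSpec:
    """Recipe for simulated listener keyword outcomes."""

    psychometric: WeibullParams = field(
        default_factory=lambda: WeibullParams(0.073, 0.284, 32.978, 1.455)
    )
    n_listeners: int = 11
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_listeners < 1:
            raise ValueError("n_listeners must be >= 1")


def _log_contour(
    rng: np.random.Generator,
    n_frames: int,
    frame_period: float,
    excursion: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Zero-centered log-frequency deviation with half-range ``excursion``.

    Sum of 3-5 random-phase cosines in the modulation band, shifted and
    rescaled so max deviation = +excursion and min = -excursion exactly.
    """
    t = np.arange(n_frames) * frame_period
    n_comp = int(rng.integers(3, 6))
    dev = np.zeros(n_frames)
    for _ in range(n_comp):
        f = rng.uniform(*band)
        phi = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        dev += amp * np.cos(2 * np.pi * f * t + phi)
    if excursion == 0 or np.ptp(dev) == 0:
        return np.zeros(n_frames)
    dev -= (dev.max() + dev.min()) / 2.0
    dev *= excursion / dev.max()
    return dev


def _syllabic_envelope(
    rng: np.random.Generator, n_frames: int, frame_period: float, rate: float
) -> np.ndarray:
    """Raised-cosine syllable-like amplitude envelope in [0, 1]."""
    t = np.arange(n_frames) * frame_period
    phi = rng.uniform(0, 2 * np.pi)
    env = 0.5 * (1.0 - np.cos(2 * np.pi * rate * t + phi))
    return 0.1 + 0.9 * env  # keep a floor so no frame is fully silent


def make_tracks(spec: SyntheticSentenceSpec, sentence_id: str = "syn") -> SentenceTracks:
    """Generate one synthetic sentence's F1-F3 tracks and references.

    Deterministic given ``spec.rng_seed``.  By construction every frame
    satisfies F1 < F2 < F3 and F2 - F1 >= ``min_f2_f1_gap_hz``; generation
    fails loudly if the requested centers/excursions make that infeasible.
    """
    rng = np.random.default_rng(spec.rng_seed)
    duration = spec.duration if spec.duration is not None else float(rng.uniform(1.5, 2.5))
    n = int(round(duration / spec.frame_period))
    tracks = []
    for center, exc, peak, label in zip(
        spec.formant_centers, spec.log_excursion, spec.amp_peaks, ("F1", "F2", "F3")
    ):
        dev = _log_contour(rng, n, spec.frame_period, exc, spec.modulation_rate_band)
        freqs = center * np.exp(dev)
        amps = peak * _syllabic_envelope(rng, n, spec.frame_period, spec.syllable_rate)
        tracks.append(FormantTrack(freqs=freqs, amps=amps,
                                   frame_period=spec.frame_period, label=label))
    f1, f2, f3 = tracks
    if np.any(f2.freqs - f1.freqs < spec.min_f2_f1_gap_hz) or np.any(
        f3.freqs <= f2.freqs
    ):
        raise ValueError(
            "infeasible spec: formant bands overlap (reduce excursions or "
            "spread centers)"
        )
    n_kw = spec.n_keywords if spec.n_keywords is not None else int(rng.integers(2, 6))
    keywords = tuple(rng.choice(_WORD_POOL, size=n_kw, replace=False))
    phonemes = tuple(p for w in keywords for p in (_G2P[c] for c in w))
    return SentenceTracks(
        id=sentence_id, f1=f1, f2=f2, f3=f3, keywords=keywords, phonemes=phonemes
    )


def make_corpus(
    n: int, base_seed: int = 0, out_dir: str | Path | None = None
) -> list[SentenceTracks]:
    """Generate ``n`` synthetic sentences with per-sentence derived seeds.

    When ``out_dir`` is given, each sentence's tracks are also written in
    the standard delimited track format (see :mod:`formantcomp.io`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n) % (2**31)
    corpus = []
    for i in range(n):
        spec = SyntheticSentenceSpec(rng_seed=int(seeds[i]))
        corpus.append(make_tracks(spec, sentence_id=f"s{i + 1:03d}"))
    if out_dir is not None:
        from .io import write_track_file

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sent in corpus:
            write_track_file(sent, out_dir / f"{sent.id}.csv")
    return corpus


def simulate_responses(
    plan: Mapping[str, tuple[float, Sequence[SentenceTracks]]],
    spec: SimulatedListenerSpec,
) -> pd.DataFrame:
    """Simulate per-listener keyword outcomes for an experiment plan.

    ``plan`` maps condition id to ``(covariate, sentences)``, where the
    covariate (e.g. the depth scale factor in percent) is fed through the
    Weibull psychometric function to give the per-keyword probability
    correct.  Keyword outcomes are independent Bernoulli draws.  Returns a
    tidy frame with columns listener, condition, x, sentence_id,
    n_keywords, n_correct.
    """
    if not plan:
        raise ValueError("plan must be non-empty")
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for listener in range(spec.n_listeners):
        for cond_id, (x, sentences) in plan.items():
            p = float(weibull_eval(float(x), spec.psychometric))
            for sent in sentences:
                n_kw = max(1, len(sent.keywords))
                n_ok = int(rng.binomial(n_kw, p))
                rows.append(
                    {
                        "listener": listener,
                        "condition": cond_id,
                        "x": float(x),
                        "sentence_id": sent.id,
                        "n_keywords": n_kw,
                        "n_correct": n_ok,
                    }
                )
    return pd.DataFrame(rows)
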