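"""Experiment construction: condition tables, sentence rotation, competitors.

Three experiment designs are supported.  The first varies the depth of
formant-frequency variation of diotically presented three-formant sentence
analogues (scale factors 100% down to 0% in 10% steps).  The second and
third use a dichotic configuration (left ear = F1 + competitor, right ear =
F2 + F3) and add a second-formant competitor (F2C) whose frequency contour
is derived from the target F2 — by spectral inversion about the geometric
mean, or as a band-limited triangle wave matched in average rate and depth
to the target F2 — at depth scale factors 0-100% in 25% steps.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import contours
from .contours import FormantTrack
from .exceptions import InvalidTrackError, SeparationViolationError
from .synth import ResonatorSpec, SourceSpec, StereoStimulus, assemble_dichotic

__all__ = [
    "CompetitorSpec",
    "ConditionSpec",
    "SentenceTracks",
    "build_condition_table",
    "allocate_sentences",
    "make_competitor",
    "build_stimulus",
    "survey_min_separation",
    "derive_seed",
]

EXPERIMENTS = ("exp1", "exp2", "exp3")


@dataclass(frozen=True)
class CompetitorSpec:
    """Recipe for a second-formant competitor (F2C).

    ``kind`` selects the frequency-contour family: ``"inverted"`` reflects
    the target F2 about its geometric mean on a log scale, ``"triangle"``
    builds a band-limited triangle wave matched to F2's average modulation
    rate and log-range, and ``"constant"`` pins the contour at the geometric
    mean (the 0%-depth limit of both).
    """

    kind: str
    scale_x: float = 1.0
    min_separation_hz: float = 80.0
    max_phase_redraws: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("inverted", "triangle", "constant"):
            raise ValueError(f"unknown competitor kind: {self.kind!r}")
        if not 0.0 <= self.scale_x <= 1.0:
            raise ValueError("scale_x must lie in [0, 1]")
        if self.min_separation_hz < 0:
            raise ValueError("min_separation_hz must be >= 0")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: formant routing, scaling, competitor."""

    id: str
    left_formants: tuple[str, ...]
    right_formants: tuple[str, ...]
    target_scale_x: float = 0.5
    competitor: CompetitorSpec | None = None
    level_offset_db: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        left, right = set(self.left_formants), set(self.right_formants)
        if left & right:
            raise ValueError(f"formants duplicated across ears: {left & right}")
        for ear in (left, right):
            if "F2C" in ear and "F2" in ear:
                raise ValueError("F2C may not share an ear with the target F2")


@dataclass(frozen=True)
class SentenceTracks:
    """Formant tracks plus scoring references for one sentence."""

    id: str
    f1: FormantTrack
    f2: FormantTrack
    f3: FormantTrack
    keywords: tuple[str, ...] = ()
    phonemes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lens = {len(self.f1), len(self.f2), len(self.f3)}
        if len(lens) > 1:
            raise InvalidTrackError("F1-F3 tracks differ in length")

    @property
    def duration(self) -> float:
        return self.f1.duration


def build_condition_table(experiment: str) -> list[ConditionSpec]:
    """Condition tables for the three experiment designs.

    * ``exp1``: 11 diotic conditions, common target scale factor 100% down
      to 0% in 10% steps, no competitor.
    * ``exp2``: 7 conditions — C1 control (F1+F2C; F3, inverted 100%),
      C2-C6 (F1+F2C; F2+F3) with inverted F2C scaled 0-100% in 25% steps,
      C7 dichotic reference (F1; F2+F3).  Targets at 50% depth.
    * ``exp3``: 8 conditions — C1 control (—; F2+F3), C2-C6 triangle F2C
      scaled 0-100% in 25% steps, C7 inverted 100%, C8 dichotic reference.
      Targets at 50% depth.
    """
    if experiment == "exp1":
        table = []
        for pct in range(100, -1, -10):
            table.append(
                ConditionSpec(
                    id=f"S{pct}",
                    left_formants=("F1", "F2", "F3"),
                    right_formants=(),
                    target_scale_x=pct / 100.0,
                    competitor=None,
                )
            )
        return table

    if experiment == "exp2":
        table = [
            ConditionSpec(
                id="C1",
                left_formants=("F1", "F2C"),
                right_formants=("F3",),
                competitor=CompetitorSpec(kind="inverted", scale_x=1.0),
            )
        ]
        for i, pct in enumerate((0, 25, 50, 75, 100), start=2):
            table.append(
                ConditionSpec(
                    id=f"C{i}",
                    left_formants=("F1", "F2C"),
                    right_formants=("F2", "F3"),
                    competitor=CompetitorSpec(kind="inverted", scale_x=pct / 100.0),
                )
            )
        table.append(
            ConditionSpec(id="C7", left_formants=("F1",), right_formants=("F2", "F3"))
        )
        return table

    if experiment == "exp3":
        table = [
            ConditionSpec(id="C1", left_formants=(), right_formants=("F2", "F3"))
        ]
        for i, pct in enumerate((0, 25, 50, 75, 100), start=2):
            table.append(
                ConditionSpec(
                    id=f"C{i}",
                    left_formants=("F1", "F2C"),
                    right_formants=("F2", "F3"),
                    competitor=CompetitorSpec(kind="triangle", scale_x=pct / 100.0),
                )
            )
        table.append(
            ConditionSpec(
                id="C7",
                left_formants=("F1", "F2C"),
                right_formants=("F2", "F3"),
                competitor=CompetitorSpec(kind="inverted", scale_x=1.0),
            )
        )
        table.append(
            ConditionSpec(id="C8", left_formants=("F1",), right_formants=("F2", "F3"))
        )
        return table

    raise ValueError(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")


def allocate_sentences(
    sentence_ids: list[str], n_conditions: int, rotation: int = 0
) -> dict[int, list[str]]:
    """Assign equal-sized sentence blocks to conditions by cyclic rotation.

    Sentences are split in order into ``n_conditions`` consecutive blocks;
    block ``i`` goes to condition ``(i + rotation) mod n_conditions``.
    Across a full rotation cycle every sentence serves every condition
    exactly once, counterbalancing sentence difficulty across listeners.
    """
    n = len(sentence_ids)
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    if n % n_conditions != 0:
        raise ValueError(
            f"{n} sentences cannot be divided equally into {n_conditions} conditions"
        )
    per = n // n_conditions
    out: dict[int, list[str]] = {}
    for i in range(n_conditions):
        cond = (i + rotation) % n_conditions
        out[cond] = list(sentence_ids[i * per : (i + 1) * per])
    return dict(sorted(out.items()))


def derive_seed(base_seed: int, *tokens: str) -> int:
    """Deterministic 31-bit seed from a base seed and string tokens."""
    h = base_seed & 0x7FFFFFFF
    for tok in tokens:
        h = (h * 1000003 + zlib.crc32(tok.encode("utf-8"))) & 0x7FFFFFFF
    return h


def make_competitor(
    f2: FormantTrack, f1: FormantTrack, spec: CompetitorSpec
) -> FormantTrack:
    """Construct a second-formant competitor track from the target F2.

    All kinds pivot on the geometric mean of the (unscaled) target F2 and
    end with a constant amplitude contour equal to the RMS of F2's
    amplitude contour.  Triangle competitors draw their starting phase from
    a seeded generator and redraw it when the contour would approach F1
    closer than ``min_separation_hz`` at any frame; inverted and constant
    contours have no free phase, so a violation is reported as an error.
    """
    if len(f2) != len(f1):
        raise InvalidTrackError("f2 and f1 tracks differ in length")
    g = contours.geometric_mean(f2)
    frame_period = f2.frame_period
    n = len(f2)

    def finalize(track: FormantTrack) -> FormantTrack:
        flat = contours.flatten_amplitude(replace(track, amps=f2.amps, label="F2C"))
        return flat

    def verify(track: FormantTrack) -> list[int]:
        return contours.check_min_separation(track, f1, spec.min_separation_hz)

    if spec.kind == "constant" or (spec.kind != "triangle" and spec.scale_x == 0.0):
        track = FormantTrack(
            freqs=np.full(n, g), amps=f2.amps, frame_period=frame_period, label="F2C"
        )
        _raise_on_violation(track, f1, verify(track))
        return finalize(track)

    if spec.kind == "inverted":
        track = contours.scale_depth(contours.invert_about_gmean(f2), spec.scale_x)
        _raise_on_violation(track, f1, verify(track))
        return finalize(track)

    # triangle: match average modulation rate and log-range of the target F2
    smoothed = contours.block_smooth(f2.freqs, 40)
    est = contours.estimate_cycles(smoothed, g, f2.duration)
    log_f = np.log(f2.freqs)
    r = 0.5 * (log_f.max() - log_f.min())
    rng = np.random.default_rng(spec.rng_seed)
    last_violations: list[int] = []
    track = None
    for _ in range(max(1, spec.max_phase_redraws)):
        phase = float(rng.uniform(0.0, 1.0))
        tri = contours.TriangleSpec(
            g=g, r=r, period_T=est.period_T, start_phase=phase, scale_x=spec.scale_x
        )
        cand = contours.triangle_contour(tri, f2.duration, frame_period)
        # frame count can differ by one from rounding; force alignment
        if len(cand) != n:
            cand = FormantTrack(
                freqs=np.resize(cand.freqs, n),
                amps=np.ones(n),
                frame_period=frame_period,
                label="F2C",
            )
        last_violations = verify(cand)
        if not last_violations:
            track = replace(cand, freqs=cand.freqs)
            break
    if track is None:
        _raise_on_violation(cand, f1, last_violations)
    return finalize(track)


def _raise_on_violation(track: FormantTrack, f1: FormantTrack, violations: list[int]) -> None:
    if not violations:
        return
    gaps = np.abs(track.freqs[violations] - f1.freqs[violations])
    worst = int(violations[int(np.argmin(gaps))])
    worst_gap = float(np.min(gaps))
    raise SeparationViolationError(
        f"competitor approaches F1 within {worst_gap:.1f} Hz at frame {worst} "
        f"({len(violations)} frames in violation)",
        violations=violations,
        worst_frame=worst,
        worst_gap_hz=worst_gap,
    )


def survey_min_separation(
    corpus: list[SentenceTracks],
    base_seed: int = 0,
    target_scale_x: float = 0.5,
    min_separation_hz: float = 80.0,
) -> tuple[float, int]:
    """Minimum per-frame F2C-to-F1 separation over a whole corpus.

    For every sentence, builds competitors of every kind at every condition
    scale factor (inverted and triangle at 0-100% in 25% steps, plus the
    constant case) with seeded phase redraw, against the depth-scaled F1 as
    presented.  Returns ``(min_gap_hz, n_competitors)``; competitor
    generation raises if any contour cannot satisfy the constraint.
    """
    scales = (0.0, 0.25, 0.5, 0.75, 1.0)
    specs = [CompetitorSpec(kind="constant")]
    specs += [CompetitorSpec(kind=k, scale_x=x) for k in ("inverted", "triangle")
              for x in scales]
    min_gap = float("inf")
    count = 0
    for sent in corpus:
        f1_scaled = contours.scale_depth(sent.f1, target_scale_x)
        for spec in specs:
            seed = derive_seed(base_seed, sent.id, f"{spec.kind}:{spec.scale_x}")
            comp = make_competitor(
                sent.f2,
                f1_scaled,
                replace(spec, rng_seed=seed, min_separation_hz=min_separation_hz),
            )
            gap = float(np.min(np.abs(comp.freqs - f1_scaled.freqs)))
            min_gap = min(min_gap, gap)
            count += 1
    return min_gap, count


def build_stimulus(
    sentence: SentenceTracks,
    cond: ConditionSpec,
    rng_seed: int = 0,
    source: SourceSpec | None = None,
    res: ResonatorSpec | None = None,
) -> StereoStimulus:
    """Assemble the stereo stimulus for one sentence in one condition.

    Target formants are depth-scaled by the condition's common scale
    factor; the competitor, when present, is derived from the *unscaled*
    target F2 (its scale factor is expressed relative to the original F2
    depth).  Formants are routed to ears per the condition and synthesized
    dichotically.  The per-stimulus competitor seed derives from
    ``(rng_seed, sentence.id, cond.id)`` so rotations are reproducible.
    """
    scaled = {
        "F1": contours.scale_depth(sentence.f1, cond.target_scale_x),
        "F2": contours.scale_depth(sentence.f2, cond.target_scale_x),
        "F3": contours.scale_depth(sentence.f3, cond.target_scale_x),
    }
    needs_f2c = "F2C" in cond.left_formants + cond.right_formants
    if needs_f2c:
        if cond.competitor is None:
            raise ValueError(f"condition {cond.id} routes F2C but has no competitor spec")
        seed = derive_seed(rng_seed, sentence.id, cond.id)
        comp_spec = replace(cond.competitor, rng_seed=seed)
        scaled["F2C"] = make_competitor(sentence.f2, scaled["F1"], comp_spec)

    def tracks_for(ear: tuple[str, ...]) -> list[FormantTrack]:
        return [replace(scaled[name], label=name) for name in ear]

    stim = assemble_dichotic(
        tracks_for(cond.left_formants),
        tracks_for(cond.right_formants),
        level_offsets_db=cond.level_offset_db,
        source=source,
        res=res,
        meta={
            "condition": cond.id,
            "sentence": sentence.id,
            "seed": rng_seed,
            "left": cond.left_formants,
            "right": cond.right_formants,
        },
    )
    return stim
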