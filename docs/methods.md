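# Methods

This note documents the models and procedures implemented in `formantcomp`,
the parameter choices that matter, and the limits of what the synthetic
test data can show.

## Contour algebra

A formant track is a pair of contours sampled at 1-ms frames: center
frequency (Hz, strictly positive) and linear amplitude (≥ 0). All depth
manipulations work on the log-frequency deviation from the geometric mean
*g* of the whole contour, computed unweighted over all frames — including
low-amplitude frames, since amplitude weighting would couple the pivot to
the envelope. Depth scaling multiplies the log deviation by *x* ∈ [0, 1];
inversion negates it. Both therefore preserve *g* exactly (to rounding) and
commute with one another, which the tests verify.

**Cycle estimation.** The modulation period of an F2 contour is estimated
by (a) block-averaging the contour over 40 non-overlapping frames
(effectively low-pass filtering at 25 Hz, suppressing spurious crossings
near *g*), (b) counting sign changes of (value − *g*) between successive
smoothed samples, (c) taking half-cycles = crossings + 1, and (d)
period = duration / (half-cycles / 2). Ties (a sample exactly at *g*) take
positive sign; a trailing partial block is averaged over its own length
rather than dropped, so no frames are discarded. On noiseless log-sinusoids
with 1–20 whole cycles the estimator is exact.

**Triangle contours.** The band-limited triangle wave keeps harmonics
1, 3, 5, 7 with 1/n² amplitudes; the normalising peak is computed
analytically as (8/π²)(1 + 1/9 + 1/25 + 1/49) rather than from sampled
frames, so the wave is bounded in [−1, 1] regardless of frame phase. The
normalised wave â(t) modulates **log** frequency multiplicatively,
f(t) = g·exp(x·r·â(t)), with *r* half the log-range of the raw
(unsmoothed) target F2. The multiplicative form is the only one consistent
with the intended geometry — a contour triangular on a log axis, with
peak-to-trough range equal to F2's max-to-min range and centered on the
geometric mean; an additive reading of the same expression would not even
carry units of frequency. Over an integer number of periods the contour's
geometric mean equals *g* to within 1e−6 relative; with an odd number of
half-cycles a phase-dependent bias remains, shrinking as cycle count grows.

## Competitor construction

All competitor kinds pivot on *g* of the unscaled target F2 (the competitor
scale factor is expressed relative to original F2 depth, while the targets
themselves are presented at 50 % depth in the dichotic designs), and all
end with a constant amplitude equal to the RMS of F2's amplitude contour.
The ≥ 80-Hz proximity constraint against F1 is enforced on nominal frame
frequencies — no account is taken of resonance skirts. Triangle starting
phase is drawn uniformly on [0, 1) of the period from a generator seeded by
(corpus seed, sentence id, condition id), and redrawn up to a budget
(default 100) when the constraint is violated; inverted and constant
contours have no free phase, so a violation raises an error naming the
worst frame instead of silently excluding the sentence.

## Synthesis

The source is a Rosenberg-style glottal pulse train: flow rises over the
opening fraction of each period (0.6), falls over the closing fraction
(0.2), and is zero during closure — conventional values, as the original
source model leaves them free. Cycle boundaries come from accumulating
instantaneous phase per sample, so the 157.5-sample period at
F0 = 140 Hz / 22.05 kHz is realised as alternating 157/158-sample cycles.
Resonators excite on the flow *derivative*, folding the +6 dB/oct radiation
characteristic into the source as in standard source-filter synthesis;
without it the output spectrum peaks at the fundamental instead of in the
formant region.

Each formant is a two-pole resonator with pole radius exp(−πB/fs) and pole
angle 2πF/fs, input-gain-normalised to unity magnitude at the instantaneous
center frequency; coefficients track the per-sample linearly interpolated
frequency contour. Parallel outputs are weighted by per-sample interpolated
amplitude contours and summed with alternating polarity (+, −, +) to avoid
deep spectral zeros between formants (configurable). Each ear is
synthesized independently, ramped (10-ms raised cosine), offset by its
per-ear dB level, and the stereo pair is scaled by one common factor to a
0.9 peak headroom — preserving inter-ear ratios. Absolute SPL is a hardware
property; the software treats all levels as relative offsets.

## Scoring

Tight keyword scoring normalises responses (case-fold, strip punctuation,
whitespace tokenize) and counts a keyword correct only on exact match or a
homonym-map alternative, consuming response tokens one-to-one. Phoneme
alignment is a minimum-cost global edit alignment with costs
substitution 10, insertion 7, deletion 7 (substitution preferred over
delete+insert; ties broken substitution-first, then deletion), and the
phonemic score is 100·hits/len(reference) — insertions do not reduce it.
Condition means pool keywords (Σ correct / Σ keywords), weighting every
keyword equally rather than every sentence. Competitor efficacy is
100·(ref − cond)/(ref − control) and is undefined when the reference does
not exceed the control. Grapheme-to-phoneme conversion is out of scope;
phoneme sequences are inputs.

## Psychometric fitting

Ψ(x) = γ + (1−γ−λ)(1−exp(−(x/α)^β)) is fitted by bounded least squares on
mean proportions (γ, λ ∈ [0, 0.5]; α ∈ (0, 2·max x]; β ∈ [0.1, 10]),
multi-started over a 3 × 3 grid of (α, β) initial values with tolerances of
1e−14 on the objective, taking the lowest-cost converged start. The loss on
condition means is a deliberate choice matching a curve fit to plotted
means; when per-point trial counts are supplied, residuals are weighted by
√n (approximate binomial weighting). r² is reported against the observed
means. Noiseless data are recovered essentially exactly; under binomial
noise at 11 points × 260 trials the median recovered α is verified to lie
within ±10 % and β within ±25 % of the generating values across 100
seeded replicates.

## Synthetic data

Synthetic sentences emulate the *statistical shape* of formant tracks for
an adult male voice: log-frequency contours are sums of 3–5 random-phase
cosines confined to the 2–6 Hz modulation band (roughly syllabic
articulation rates), shifted and rescaled so the log half-range equals the
per-formant excursion exactly (defaults 0.25/0.30/0.12 about
500/1500/2500 Hz); amplitude contours are raised-cosine syllabic envelopes
at 4 Hz with a 0.1 floor, peaking at 1.0/0.35/0.15 so F1 dominates as in
natural speech. Band-limited cosine sums were chosen over filtered noise so
cycle counts and log-ranges are analytically known and can serve as test
oracles. Durations draw uniformly from 1.5–2.5 s. The generator guarantees
F1 < F2 < F3 and F2 − F1 ≥ 200 Hz at every frame, which also means the
80-Hz competitor constraint is satisfiable by construction — mirroring the
practice of pre-selecting sentences that satisfy it.

What this does *not* emulate: phonetic segment structure, consonantal
closures and occlusion-related tracking errors, fricative formants,
natural F0 contours, or any lexical content (keywords are drawn from a
small word pool and simulated responses are independent Bernoulli draws
with no confusion structure). Passing tests therefore demonstrate the
correctness of the contour algebra, constraint logic, synthesis,
scoring and fitting machinery on well-behaved inputs — not robustness to
the artifacts of real formant estimation.

## Problem sizes and numerical choices

The test suite and the acceptance script use a 50-sentence synthetic corpus
for constraint surveys, 10–20 s of noise for resonator frequency-response
measurements, 100 replicates for binomial recovery, and an exhaustive
1.19M-pair sweep (all phoneme strings up to length 6 over a 3-symbol
alphabet) for alignment verification — sizes at which every check is exact
or tightly toleranced while the whole suite runs in well under a minute.
Degenerate inputs are handled explicitly: empty tracks, zero amplitudes
(warn, do not fail), contours that never cross their mean (half a cycle),
all-constant observed vectors (r² undefined), and clipping stimuli (error
unless auto-normalisation is enabled).

## Known limitations

* The original synthesizer's resonator gain and amplitude-control semantics
  are not public; unity gain at the center frequency is an assumption, and
  per-ear (rather than post-mix) ramping is likewise assumed.
* Efficacy and reduction figures from human listeners are not reproducible
  here: simulated listeners have no perceptual model of informational
  masking, so the package validates stimulus construction and analysis, not
  perception.
* The homonym set and exact alignment penalties used in the original
  scoring pipeline are unknown; both are configurable.
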