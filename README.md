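# formantcomp

Tools for the **second-formant-competitor (F2C) paradigm** in auditory
psychophysics: constructing dichotic synthetic-formant speech stimuli in
which listeners must reject an extraneous formant, and analysing the
resulting intelligibility data.

In this paradigm, three-formant synthetic analogues of sentences (F1–F3,
driven by frame-by-frame frequency and amplitude contours) are split across
the ears — typically left = F1 + F2C, right = F2 + F3 — so that the
competitor interferes with recognition almost entirely through
*informational* masking (central competition for the second formant) rather
than energetic overlap in the periphery. The package is aimed at speech
perception researchers who need to build such stimuli reproducibly and
score the responses.

## What it computes

**Depth scaling ("formant squash").** The depth of frequency variation of a
formant contour *f*(*t*) is rescaled about its geometric mean *g* on a log
scale:

```
log s(t) = log g + x · log( f(t) / g ),     0 ≤ x ≤ 1
```

*x* = 0 pins the contour at *g*; *x* = 1 leaves it unchanged. The geometric
mean is preserved for every *x*; amplitude contours are never adjusted.

**Competitors.** An F2C is derived from the target F2 in one of three ways,
all pivoting on *g* of F2 and all given a constant amplitude equal to the
RMS of F2's amplitude contour:

* *inverted* — spectral inversion about the geometric mean on a log scale
  (`s = g²/f`), a speech-plausible contour, then depth-scaled by *x*;
* *triangle* — a band-limited triangle wave on log frequency built from the
  first four odd harmonics,
  `a(t) = (8/π²) Σ_{n=1,3,5,7} n⁻² cos(2πn(t+φT)/T)`, normalised to ±1 and
  applied as `f(t) = g · exp(x · r · â(t))`, where *r* is half the log-range
  of F2 and the period *T* comes from counting geometric-mean crossings of
  the 40-frame block-smoothed F2 contour (half-cycle precision) — a
  regular, non-speech-like contour matched to F2's average rate and depth;
* *constant* — fixed at *g* (the 0 %-depth limit of both).

A proximity constraint keeps every competitor ≥ 80 Hz from F1 at every
frame; triangle phases are redrawn (seeded) until it holds.

**Synthesis.** Rosenberg-pulse excitation (F0 = 140 Hz, monotone) drives
parallel time-varying second-order resonators (3-dB bandwidths 50/70/90 Hz
for F1/F2/F3; 70 Hz for F2C) at 22.05 kHz, with 10-ms raised-cosine ramps
and 16-bit stereo WAV output.

**Scoring and psychometrics.** Tight keyword scoring (exact match, homonyms
accepted, one-to-one token consumption), minimum-cost phoneme alignment
(costs 10/7/7 for substitution/insertion/deletion) with
`phonemic score = 100 · hits / len(reference)`, keyword-pooled condition
means, competitor efficacy
`100 · (ref − cond)/(ref − control)`, and Weibull psychometric fits
`Ψ(x) = γ + (1−γ−λ)(1−exp(−(x/α)^β))`.

Because no public corpus of hand-corrected sentence formant tracks exists,
`formantcomp.synthdata` generates realistic synthetic corpora (smooth,
non-crossing contours near 500/1500/2500 Hz with syllabic amplitude
envelopes) and simulated listener responses, so the full pipeline runs
end-to-end with no external data.

## Worked example

Simulate a depth-scaling experiment (11 diotic conditions, scale factors
100 % → 0 %, 22 listeners, 44 sentences) and fit the psychometric function:

```python
from formantcomp import (build_condition_table, make_corpus,
                         simulate_responses, SimulatedListenerSpec,
                         fit_weibull)

table = build_condition_table("exp1")
corpus = make_corpus(44, base_seed=1)
plan = {c.id: (c.target_scale_x * 100.0, corpus[i*4:(i+1)*4])
        for i, c in enumerate(table)}
df = simulate_responses(plan, SimulatedListenerSpec(n_listeners=22, rng_seed=1))
pooled = df.groupby("x").apply(
    lambda g: g.n_correct.sum() / g.n_keywords.sum(), include_groups=False)
params, r2 = fit_weibull(pooled.index.to_numpy(), pooled.to_numpy())
```

This prints pooled keyword scores rising from 7.4 % at 0 % depth to 71.0 %
at full depth, and recovers

```
gamma=0.066 lambda=0.312 alpha=29.276 beta=1.754 r2=0.9952
```

i.e. a guess rate of ~7 %, a lapse-limited ceiling near 69 %, an inflection
near a 29 % scale factor and a slope of ~1.8 — close to the simulated
listener's generating parameters (γ = 0.073, λ = 0.284, α = 32.978,
β = 1.455), with the fit explaining 99.5 % of the variance.

Stimuli can be rendered from the command line:

```
formantcomp tracks-gen --n 48 --seed 1 --out tracks/
formantcomp make-stimuli --experiment exp3 --tracks-dir tracks/ --seed 1 --out stim/
```

which writes one stereo WAV per sentence × condition plus a manifest.

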