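# Methods

## Model

The package treats a smoothed daily new-case curve as an Elliott-wave
pattern: impulses (five sub-waves in the direction of the prevailing
move) alternating with correctives (three sub-waves against it),
nested fractally across degrees — five sub-waves of one degree form
one wave of the next. The pipeline has four stages:

1. **Smoothing.** Trailing moving average over `window` days (default
   7, the convention for surveillance curves), with partial windows at
   the series start so no future day is used. Missing days are
   excluded from the window mean; negative raw entries (retroactive
   corrections) are clamped to zero for smoothing only. A window with
   no observed day yields a missing smoothed value.
2. **Pivot detection.** A percentage-reversal zigzag: a peak (trough)
   is confirmed once the curve moves away from the running extreme by
   at least `reversal_fraction` (default 0.30) of the extreme's value.
   The 0.30 default reflects the large relative swings epidemic curves
   exhibit; it is configurable. Endpoints are always pivots, so the
   leading and trailing swings may be sub-threshold. Detection is
   scale-invariant by construction.
3. **Labeling.** The swing sequence between pivots is parsed into the
   wave grammar by a memoized dynamic program that keeps the best
   parse per (start pivot, degree, role, end pivot). Because the score
   is additive over nodes, this DP is exactly optimal — equivalent to
   exhaustive enumeration of segmentations at any pivot count, with no
   need for a beam fallback. Ties resolve deterministically toward the
   earliest-completing candidate and toward an impulse-first reading.
4. **Projection.** Fibonacci retracements/extensions of a reference
   swing give support/resistance grids and correction scenarios
   (below).

## Labeling score

`score = 1000·(hard violations) + structural penalties + Σ ratio penalties`

- **Hard rules** (1000 each, individually switchable): R1 — wave 2
  ends beyond wave 1's origin; R2 — wave 3 is the shortest of impulses
  1/3/5; R3 — wave 4's terminal crosses wave 1's terminal level. R2/R3
  are only evaluated when the children they reference exist, so an
  in-progress wave is scored on what is observable. For a subdivided
  wave 4 the node's terminal pivot stands in for its extreme (exact
  for zigzag-shaped corrections, a proxy for flats).
- **Structural penalties:** 5 per top-level node (prefers cohesive
  counts over fragmented ones), 3·degree for a wave left unsubdivided
  (a "leaf" above degree 0), 3 per absent child of an in-progress
  wave. Leaves above degree 0 are essential robustness: smoothing can
  merge sub-swings, and without unsubdivided waves many real pivot
  sequences would have no legal parse at all.
- **Ratio penalties:** for each child pair conventionally related by a
  Fibonacci ratio (wave2/wave1, wave3/wave1, wave4/wave3, wave5/wave1;
  b/a, c/a), `min over ratio set of |ln(observed/ratio)|`. The default
  set is {0.236, 0.382, 0.5, 0.618, 1.0, 1.618, 2.618}.

The penalty weights are ordinal design choices, not fitted constants:
hard rules must dominate everything, structural shortcuts must cost
more than typical ratio noise (≈0.1–0.7 per pair) and less than a hard
rule. Amplitudes are measured on `log10(value+1)` by default — case
curves are read on logarithmic axes and wave moves span orders of
magnitude — with a linear mode available.

An Elliott count is not unique. The labeler returns the minimum-score
reading; `validate_wave_count` re-checks any count (including
hand-built ones) against the grammar (G1/G2) and R1–R3, raising on
structural malformation and returning violation records otherwise.

## Level grids and scenarios

The four update formulas are implemented exactly as conventionally
written (the up/down variants are algebraic mirror images; both are
kept for fidelity), clamped at zero. A level grid applies them over a
ratio set to one reference swing: retracements project back across the
swing from its endpoint, extensions continue past the endpoint by the
swing's amplitude times the ratio; the default six retracement ratios
are {0.236, 0.382, 0.5, 0.618, 1.0, 1.618} (a 300 % level can be added
via `ratios`). Levels below the current value are supports, others
resistances.

Scenario projection retraces the most recent completed swing (the last
swing not still forming; the anchor is overridable, since which swing
anchors a correction is a judgment call) at three configured depths —
default strong = 100 %, moderate = 61.8 %, mild = 50 %. Scenarios are
then ranked by terminal level: fewer daily cases is the better
outcome, so the deepest correction is the best case. An optional
continuation segment extends the reference amplitude beyond each
correction target (the follow-on impulsive rally). Grid and scenario
arithmetic defaults to the linear scale — level targets are reported
in cases/day and retracement percentages are conventionally linear —
with a log mode for consistency with log-fit counts. Projections are
level targets only; no calendar-time model is attached.

## Historical analogy

`infections = deaths / CFR`; `attack fraction = infections /
population`; projected infections = attack fraction × target
population; projected deaths = projected infections × target CFR.
Shipped reference constants: 675,000 deaths, 2.5 % CFR, 103 million
population (US, 1918–1920 H1N1). The modern population is a required
input, not a constant: any value in 324–331 million reproduces the
familiar ~85-million-infection headline at 5-million rounding, and
1.8 % CFR then gives ~1.5 million deaths at 0.5-million rounding.
Outputs are reported raw and rounded. The module is deliberately this
back-of-envelope chain and nothing more.

## Synthetic generator

`generate_elliott_epidemic` realizes a wave plan as a daily curve:

- Pivot levels are laid out on the log10 scale. Default amplitude
  ratios — wave 2 = 0.5·wave 1, wave 3 = 1.618·wave 1, wave 4 =
  0.382·wave 3, wave 5 = 1.0·wave 1; b = 0.5·a, c = 1.0·a — are
  Fibonacci members chosen to satisfy R1–R3 with margin; the
  generator rejects ratio sets that would violate them (e.g. a wave-2
  ratio above 1).
- Study conditions, chosen once as realistic epidemic scales: base
  level 1000 cases/day; first-wave amplitude 1.5 orders of magnitude
  for degree-1 plans and 2.8 for the degree-2 pandemic-year plan
  (≈300 days); 14 days per finest sub-wave. Days between pivots are
  geometrically interpolated (linear in log space), consistent with
  the log-scale wave engine.
- Noise is multiplicative log-normal with unit mean and configurable
  CV (case counts are positive and heteroskedastic); every random
  draw flows from the explicit `seed` — no global state.

Ground truth (pivots at their noiseless levels, the full labeled tree)
is returned alongside the series and always passes validation.

What the generator does **not** emulate: transmission dynamics,
weekday reporting cycles, holiday gaps, count integer-ness, or
revisions. Passing recovery tests therefore show that the pipeline
recovers wave structure from curves that *have* one under day-level
noise — not that real surveillance curves obey the wave model.

## Recovery experiments

- *Noiseless:* curves are analyzed unsmoothed (window 1) — there is no
  noise to suppress, and any trailing average would displace the true
  extremes. Detection recovers every ground-truth pivot exactly and
  labeling reproduces the full tree on all plans and seeds.
- *Noisy (CV 0.15):* curves are smoothed with a 3-day trailing window
  before detection. The window is the smallest that suppresses iid
  day noise (residual CV ≈ 0.15/√3 ≈ 0.09, well under the 30 %
  reversal threshold); the 7-day display default targets weekly
  reporting cycles the generator does not produce, and at 14-day
  sub-wave scale it attenuates the smallest swings below the reversal
  threshold even without noise. Recovery of the degree-1
  impulse/corrective sequence is checked on 50 fresh seeds.

Problem sizes used throughout (20 noiseless seeds, 50 noisy seeds,
degree-2 plans with 22 pivots) keep the full suite and the acceptance
script in the seconds range while exercising the exhaustive-equivalent
parser on the deepest plan the generator ships.

## Numerical choices and degenerate inputs

- Rule comparisons use an absolute tolerance of 1e-9 on the
  transformed scale; amplitude ratios guard against zero amplitudes
  with a 1e-12 floor, and relative reversal tests guard division by
  zero the same way (a rise from a zero level always confirms).
- Zero-amplitude reference swings collapse every grid level to the
  swing value. Strictly monotone series yield exactly two pivots (the
  endpoints). A single up-swing labels as an in-progress wave 1.
- CSV round-trips preserve missing cells as blanks and integer-valued
  counts as integers; dates are ISO-8601 and calendar gaps are filled
  with missing markers on load.

## Known limitations

- The labeler's score is one defensible formalization of by-eye wave
  counting; it does not attempt to reproduce any particular analyst's
  published count, and counts on real data should be read as one
  admissible labeling.
- Corrective sub-structure is modeled as zigzags (5/3 at every level);
  flats, triangles and other corrective families are not in the
  grammar.
- The in-progress mechanism permits a partial wave only at the end of
  the series (the present moment).
- Scenario projections carry no uncertainty quantification and no
  timing; they are level targets conditional on the wave reading.
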