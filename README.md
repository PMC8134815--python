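# epiwave

Elliott-wave segmentation and Fibonacci-pinball scenario projection for
epidemic daily-new-case curves.

Technical analysts describe sentiment-driven time series as nested
patterns of five-wave advances (*impulses*, labeled 1-2-3-4-5) and
three-wave pullbacks (*correctives*, labeled a-b-c), repeating fractally
across *degrees*. Epidemic curves are also shaped by mass behaviour —
waves of compliance and fatigue — so the same machinery can be turned on
a smoothed daily-case series: segment it into waves, check the wave
rules, and project where the curve may find support or resistance.
`epiwave` makes that procedure computational and testable:

- **series_io** — reads/writes wide surveillance CSVs (a `date` column
  plus one column per country/region) and computes the trailing 7-day
  moving average ``s_t = mean(x_{t-6..t})``.
- **wave_engine** — reduces the smoothed curve to alternating swing
  pivots (percentage-reversal zigzag, default 30 %) and searches all
  segmentations of the swing sequence into the 5/3 wave grammar,
  scoring hard rule violations (wave 2 never retraces >100 % of wave 1;
  wave 3 is never the shortest impulse; wave 4 stays out of wave 1's
  territory) plus the distance of swing-amplitude ratios from the
  Fibonacci set {0.236, 0.382, 0.5, 0.618, 1, 1.618, 2.618}.
- **fibonacci_pinball** — the four level-update formulas, e.g. uptrend
  retracement ``P_{t+1} = P_t − (P_t − P_{t−1})·Fib`` and uptrend
  extension ``P_{t+1} = P_t + (P_{t−1} − P_{t−2})·Fib``, applied over a
  ratio set to build six-level support/resistance grids and
  best/intermediate/worst-case correction scenarios.
- **historical_analogy** — attack-fraction transfer: infections =
  deaths / CFR; the historical attack fraction applied to a modern
  population, converted back to deaths with a modern CFR.
- **synthetic_data** — epidemic-shaped curves with *known* wave ground
  truth (Fibonacci-ratio amplitudes on the log scale, geometric
  interpolation, multiplicative log-normal day noise), so the whole
  pipeline is testable without downloading surveillance data.

## Worked example

Generate a noisy synthetic pandemic year (a degree-2 impulse spanning
~2.8 orders of magnitude), label it, and project scenarios:

```sh
$ epiwave simulate --plan super_impulse --seed 11 --noise-cv 0.15 --out demo/
wrote super_impulse (seed 11, noise CV 0.15) to demo

$ epiwave label --csv demo/super_impulse_11.csv --region Synthetica \
      --smooth 3 --out demo/count.json
22 pivots, 1 top-level waves, score 6.845, in progress: False

$ epiwave project --count demo/count.json --out demo/scen.json
best         (strong correction): terminal level 245,140 cases/day
intermediate (moderate correction): terminal level 353,282 cases/day
worst        (mild correction): terminal level 386,687 cases/day
```

The labeler recovered all 22 ground-truth pivots and read the curve as
one completed super-wave impulse (score 6.845; scores ≥ 1000 would
flag hard rule violations). The scenario levels retrace the most
recent completed swing by 100 %, 61.8 % and 50 %: a *strong* correction
would bring the daily count down to ~245 k/day (the best case), a
*mild* one only to ~387 k/day (the worst case).

The analogy arithmetic, with the 1918 H1N1 reference values built in:

```sh
$ epiwave analogy --target-pop 325e6 --target-cfr 0.018
projected infections: 85,194,175 (~85 million)
projected deaths:     1,533,495 (~1.5 million)
```

675,000 historical deaths at a 2.5 % CFR imply 27 million infections —
26.2 % of the 1918 US population of 103 million; the same attack
fraction on 325 million people gives ~85 million infections and, at a
1.8 % CFR, ~1.5 million deaths.

The same pipeline runs from Python (`load_case_series`,
`moving_average`, `detect_pivots`, `label_waves`, `build_level_grid`,
`project_scenarios`, `generate_elliott_epidemic`, …); see the module
docstrings.

## Caveats

Elliott counts are famously non-unique; the labeler returns the
minimum-score reading under its documented score, not the only
defensible one. Scenario levels are targets, not dated forecasts, and
the analogy module is deliberately a back-of-envelope calculation — no
age structure, immunity or transmission dynamics. See
`docs/methods.md` for the model, parameter and design details.
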