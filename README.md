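# copycatdetect

Trend, change-point and temporal-interdependence ("copycat effect")
analysis for sparse daily event-count series.

## The problem

Some rare, heavily mediatised events — the motivating case is the Spanish
register of intimate-partner homicides (femicides), 655 events over the
4018 days from 2007 to 2017 — are widely believed to cluster: one event is
said to raise the probability of another in the following days.  Whether
such an imitation effect exists has direct policy consequences (media
reporting rules, timing of prevention campaigns), so the claim deserves a
careful statistical answer rather than a reading of apparent bursts.

`copycatdetect` treats the event list as a day-discretized counting
process N(t) and asks, in order:

1. **Is the rate constant?**  Uniformity tests of event times (KS,
   Cramér–von Mises, Anderson–Darling), a runs test of the binarized
   series, Dunn's rank comparison across calendar groups, a Cox–Stuart
   trend test, and an at-most-one-change (AMOC) mean+variance scan of the
   moving-average intensity λ̂(t).
2. **Is each regime a homogeneous Poisson process?**  After splitting at
   the detected change-point: Poisson χ² and Cameron–Trivedi dispersion
   tests on the daily counts, χ² fit of the whole-day inter-arrival gaps
   to the geometric law with p = 1 − exp(−λ̂) (with the merged 0/1-day
   variant that softens the daily-discretization artifact), and
   ACF/PACF + Ljung–Box screens at lags 7 and 14.  Under a Poisson
   process disjoint intervals are independent, so a good fit rules out
   imitation.
3. **Could the battery even detect imitation?**  A simulation study:
   batches of homogeneous, non-homogeneous (moving-average-driven) and
   copycat processes — base rate λ boosted to (1+δ)λ for the r days after
   any event — are pushed through the same battery and through two-sample
   comparisons with the observed series (KS, Anderson–Darling, χ²
   homogeneity of gaps, permutation energy test), aggregated as the
   median p-value over 500 replicates, pooled over r at each δ.

The package is usable as a library (each test is an importable function
returning a `TestResult`) and as a CLI.

## Worked example

The pipeline runs end-to-end on a synthetic register (no download
needed).  `two_segment` draws Poisson counts at 0.19 events/day for 1811
days, then 0.14 events/day for 2207 days — the shape of the Spanish
series:

```sh
copycatdetect h1 --synthetic two_segment --seed 100 --out reports
```

From `reports/h1.json` (seed 100):

* uniformity p-values: KS 0.000216, CVM 0.000397, AD 0.000444 — a
  constant rate over the full window is clearly rejected;
* runs test p = 0.4265 — the day-level binary sequence itself is not
  unusually clustered, so the rejection above is about the trend, not
  about bursts;
* change-points by smoothing window (days), with mean rate before/after:

  | window | τ̂ (day) | pre | post |
  |-------:|--------:|-----:|-----:|
  | 30  | 1335 | 0.187 | 0.136 |
  | 180 | 1692 | 0.180 | 0.134 |
  | 730 | 1632 | 0.179 | 0.134 |

  every window flags a significant drop of ≈0.045 events/day (true
  change at day 1811; narrow windows localize less precisely);
* Cox–Stuart decreasing-trend p < 1e-60 for every window.

`copycatdetect h2` then splits at the detected day and runs the Poisson
battery on both halves (each half passes, as it should for this input),
and `copycatdetect simstudy` runs the median-p simulation comparison.
With real data, replace `--synthetic` by `--input events.csv` where the
CSV has a `date` column of ISO-8601 dates, one row per event.

Running on the actual femicide register (a public date list) reproduces
the published analysis: a change around late 2011, a post-change series
compatible with a homogeneous Poisson process on every test, and no
autocorrelation signature — no statistical footprint of imitation.  The
simulation study bounds the claim: only boosts δ ≳ 0.7 are detectable at
this sample size, so small imitation effects cannot be excluded.

## Layout

| module | contents |
|--------|----------|
| `core_events` | event calendar, daily counts, gaps, binarization, splitting, calendar grouping, CSV I/O |
| `intensity_trend` | moving-average intensity, Cox–Stuart, AMOC change-point |
| `distribution_tests` | uniformity (KS/CVM/AD), runs test, Dunn's comparison |
| `poisson_fit` | rate estimation, frequency tables, Poisson χ², dispersion, geometric gap fit |
| `dependence` | ACF/PACF, Ljung–Box |
| `simulate` | homogeneous / non-homogeneous / copycat generators, count filter, calibration |
| `compare` | two-sample tests, energy test, median-p batch protocols |
| `pipeline` / `cli` | orchestration, reports, `copycatdetect` command |

See `docs/methods.md` for the model, the discretization caveats, and the
design decisions.
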