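# estuaryuse

Movement-ecology analysis of beluga whale (*Delphinapterus leucas*) summer
use of a sub-arctic river estuary, built as a tested, reusable Python
pipeline. The package covers the full chain from raw Argos satellite
telemetry and aerial strip-transect surveys to habitat inference:

1. **Track quality control** — best-of-duplicate selection, retention of
   "guaranteed" Argos location classes (3/2/1, ~250 m–1.5 km error), and a
   forward travel-rate filter (default < 3.5 km/h).
2. **Distance covariates** — daily median whale locations; great-circle
   distances to the river mouth (Port Nelson, 57.0552° N, 92.5967° W) and to
   the nearest shoreline.
3. **Migration timing** — a distribution-free cumulative sign test: day *t*
   scores sᵗ = sign(dᵗ − median d), and the estimated residency→migration
   change point is argmaxₜ |Σᵢ≤ₜ sᵢ|.
4. **Hydrological years** — study years are "wet" when their 14 Jul–31 Aug
   mean discharge exceeds the multi-year baseline (percent deviation > 0),
   else "dry".
5. **Home range** — fixed-kernel utilization distributions (isotropic
   bivariate normal kernel) with least-squares cross-validated bandwidth,
   probability contours (25/50/75/95%), geometric-mean and centre-of-mass
   summaries, and an alpha-shape estuary polygon.
6. **Inference** — gls-style regression of log distances with AR1 errors
   within whale, collinearity screening (|r| ≥ 0.6, VIF > 3), AICc ranking
   with Akaike weights: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),
   wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2).
7. **Aerial surveys** — strip-transect design math (coverage =
   2·half-width/spacing), 1 × 0.7 km block binning, density-weighted
   distance summaries, quasi-Poisson density models ranked by QAICc, and an
   uncorrected abundance index.

Because the original field data were never deposited, the package ships a
first-class synthetic-data module that emulates the study conditions — 13
tagged whales with an estuarine residency phase switching to coastal
migration in early August, Argos class-specific error and duty cycling,
semidiurnal tides with spring/neap modulation, seasonal discharge series,
and repeated high-tide strip-transect surveys over a funnel-shaped estuary —
so every stage is exercisable and testable end to end.

## Worked example

```python
from estuaryuse.synthetic_data import SimConfig, simulate_tracks
from estuaryuse import track_qc, geospatial, changepoint

cfg = SimConfig(seed=42)              # 13 whales, switch on day 221 (9 Aug)
tracks = simulate_tracks(cfg)
clean, report = track_qc.run_qc(tracks)
print(f"fixes: {report.n_input} raw -> {report.n_after_speed} retained "
      f"({100*report.retention_fraction:.1f}%)")
daily = geospatial.daily_summaries(clean)
pooled = geospatial.pooled_daily_distance(daily, "dist_mouth_km")
res = changepoint.cumulative_sign_changepoint(pooled)
print(f"estimated migration onset: day {res.change_doy} "
      f"(|cumsum| peak {res.max_abs_cumsum} over {res.n_days} days)")
```

prints

```
fixes: 9470 raw -> 2647 retained (28.0%)
estimated migration onset: day 220 (|cumsum| peak 30 over 61 days)
```

About 28% of raw fixes survive the class and travel-rate screens (most of
the loss is the 0/A/B location classes), and the change point lands on day
220 — the last full residency day before the configured switch on day 221,
the earliest day at which the absolute cumulative score peaks.

The same chain is available from a shell:

```sh
estuaryuse simulate --seed 42 tracks.csv
estuaryuse filter tracks.csv clean.csv
estuaryuse covariates clean.csv daily.csv
estuaryuse changepoint daily.csv
estuaryuse run --seed 42 --out-dir pipeline_out   # everything end to end
```

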