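# lunarpm

Tools for quantifying how firework discharge around the Chinese Lunar New
Year perturbs surface PM2.5, for air-quality researchers who want the whole
computational chain — satellite AOD handling, neural PM2.5 retrieval,
lunar-calendar time division, multi-year fusion, and event/policy
statistics — as one tested, reusable package.

## What it computes

* **Daily AOD merging** — Terra-like and Aqua-like overpass grids combined
  per pixel (both → mean, one → that value, none → missing).
* **Neural retrieval** — a 9→18→1 back-propagation network mapping
  (lon, lat, day-of-year, AOD, RH, TEMP, WS, SP, HPBL) to PM2.5, scored by
  Pearson R and RMSE = √(n⁻¹ Σ(yᵢ − yᵢ′)²) with sample-based 10-fold
  cross-validation.
* **Lunar time division** — each lunar cycle tiled into 21 labelled
  periods anchored on the 17-day celebration window Δt (New Year's Eve
  through the day after the Lantern Festival): `celebration`,
  `post-1…post-10`, and `pre-10…pre-1`, where `pre-10` absorbs the
  residual days.
* **Period fusion** — per-label, per-pixel means of retrieved PM2.5 grids
  across years; station-side period means against the pre-1/post-1
  flanking baseline.
* **Effect analysis** — national hourly means, daily maxima with their
  hour-of-day, peak-to-baseline ratios, and the three-category city
  response classification (significant / obvious / weak) over the
  00:00–04:00 discharge window of New Year's Day.
* **Policy evaluation** — hourly anomalies against a 34-day flanking
  baseline, compared across years around a firework-prohibition policy.
* **Synthetic worlds** — a seeded generator producing station networks,
  hourly PM2.5 with seasonal/diurnal/AR(1) structure and New-Year spikes,
  and consistent AOD/meteorology grids with known ground truth, so every
  stage is verified by recovery.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

```sh
lunarpm demo --seed 1 --out demo_out
```

simulates a one-cycle world (12 stations, 8 of them spiked at New Year),
trains the retrieval on 1500 grid samples, fuses periods, classifies
responses, and prints:

```json
{
 "seed": 1,
 "n_periods_per_cycle": 21,
 "fit_r": 1.0,
 "fit_rmse": 0.0391,
 "new_year_max_hour": 2,
 "peak_ratio_pct": 267.4,
 "celebration_mean": 78.51,
 "flanking_mean": 85.28,
 "categories": {"significant": 8, "obvious": 0, "weak": 4}
}
```

Reading it: the lunar cycle splits into the expected 21 periods; the
network recovers the known synthetic AOD→PM2.5 mapping essentially exactly
(R = 1.00, RMSE 0.04 μg/m³); the national daily maximum on New Year's Day
falls at 02:00 and is 267% of the flanking days' maxima (the instantaneous
firework effect); the celebration-period mean (78.5 μg/m³) sits *below*
the flanking baseline (85.3 μg/m³) because the holiday emission reduction
outweighs the short burst (the sustained effect); and exactly the 8 spiked
stations classify as significant responders. `demo_out/` holds the station
CSV, period JSON, fused NetCDF maps, model JSON, and a checksummed
manifest; runs with the same seed are bit-identical.

The same stages are available as composable subcommands (`simulate`,
`merge-aod`, `train`, `retrieve`, `divide`, `fuse`, `period-means`,
`effects`, `classify`, `policy`) and as plain library functions.

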