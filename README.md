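# budfreeze

Dormant-season bud cold-hardiness simulation for grapevine, with
chill-portion accumulation (Dynamic Model), budbreak prediction from
projected hardiness trajectories, freeze-damage detection/correction, and
frost-risk indicators — all exercisable on reproducible synthetic weather.

## What it does

1. **weather** — reads/validates daily Tmin/Tmax records, slices them into
   1 Jul–30 Jun dormant seasons, computes mean dormant-season temperature
   (MDST, 1 Nov–30 Apr) and derives hourly temperatures (sine day /
   logarithmic night with latitude-based day length).
2. **chill** — hourly Dynamic-Model chill portions (two-step
   precursor/portion process, irreversible banking) with an optional phase
   shift of the temperature response (−6…+6 °C).
3. **hardiness** — daily cold-hardiness integration per cultivar
   (Cabernet-Sauvignon, Riesling, Concord) and percentile (10/50/90):
   acclimation + deacclimation gated by a logistic deacclimation potential,
   in *projected* (unbounded) or *bounded* (spring-floored) mode.
4. **budbreak** — threshold crossing of the projected 50th-percentile
   trajectory (+10/+5/0 °C depending on cultivar and observation
   convention); FAILED crossings are first-class results.
5. **damage** — freeze events (Tmin below the 10th-percentile prediction),
   percent damage by piecewise-linear quantile interpolation (capped at
   90 %), survivor-percentile adjustment, and freeze-damage-corrected (FDC)
   budbreak.
6. **risk_metrics** — safety margins (Tmin − CH50), freeze-risk and
   near-miss day counts, MDST risk bands, budbreak-aligned series.
7. **evaluation** — residuals/RMSE/bias/r², binary damage-validation
   confusion matrix, the chilling phase-shift experiment, segmented MDST
   sensitivity slopes.
8. **synthetic** — seeded synthetic weather (seasonal sinusoid + AR(1)
   noise) calibratable to a target MDST, and noisy synthetic observations.

## CLI

```sh
# synthetic weather (and optional model-generated observations)
budfreeze synth --spec spec.yaml --out weather.csv --obs-out obs.csv --seed 1

# stages (all take a YAML run config; see below)
budfreeze chill     --config run.yaml --out out/ [--shift -6]
budfreeze hardiness --config run.yaml --out out/ [--no-damage-correction]
budfreeze budbreak  --config run.yaml --out out/
budfreeze risk      --config run.yaml --out out/
budfreeze evaluate  --config run.yaml --observations obs.csv --out out/
budfreeze phase-shift --config run.yaml --observations obs.csv --out out/
```

Run config (YAML):

```yaml
schema_version: 1
sites:
  - {site_id: cold, latitude_deg: 43.0, weather_csv: weather.csv}
cultivars: [Cabernet-Sauvignon, Riesling, Concord]
convention: BBCH07_50        # or BBCH05_50 / BBCH05_first
damage_correction: true
floors: {p10: -1.2, p50: -2.5, p90: -3.8}   # spring minimum hardiness, °C
integration_start: "09-01"
seed: 0
```

Weather CSV columns: `date` (YYYY-MM-DD), `tmin_c`, `tmax_c`
(optional `site_id`). Cultivar parameters ship as a long-format CSV
(`cultivar,percentile,param_name,value,source`) and can be replaced via
`params_csv:` in the config.

Per-site outputs: `chill.csv`, `hardiness_<cultivar>.csv`,
`events_<cultivar>.csv`, `predictions.csv`, `risk.csv`, `report.json` —
byte-stable under a fixed config and seed.

## Notes

- Cold hardiness is a lethal temperature in °C: more negative = hardier;
  within a day CH10 ≥ CH50 ≥ CH90 (the 10th percentile is damaged first).
- MDST uses the (Tmin+Tmax)/2 midpoint convention by default
  (`hourly-mean` available).
- Northern-Hemisphere season windows only; |latitude| must be ≤ 66.6°.
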