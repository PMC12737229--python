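# cwtburden

Source attribution of urban PM2.5 by ensemble back-trajectory receptor
modelling, and the short-term health burden it implies — packaged as a
tested, reusable pipeline for atmospheric / environmental-health analysts.

Given (1) HYSPLIT-style ensemble back-trajectory endpoint files arriving at
a receptor (by default the Beijing monitoring site at 39.98° N, 116.40° E;
27 members, 24 h paths, three-hourly arrivals), and (2) an hourly receptor
PM2.5 series, the package computes:

- a **Concentration-Weighted Trajectory (CWT)** field on a 0.25° grid,

  C<sub>ij</sub> = [ Σ<sub>l</sub> C<sub>l</sub> τ<sub>ijl</sub> /
  Σ<sub>l</sub> τ<sub>ijl</sub> ] · W(n<sub>ij</sub>),

  where C<sub>l</sub> is the receptor concentration at trajectory *l*'s
  arrival time, τ<sub>ijl</sub> the number of its hourly endpoints in cell
  (i, j), n<sub>ij</sub> = Σ<sub>l</sub> τ<sub>ijl</sub>, and the sparse-cell
  weight is W = 1.00 (n > 3 n̄), 0.70 (1.5 n̄ < n ≤ 3 n̄),
  0.42 (n̄ < n ≤ 1.5 n̄), 0.05 (n ≤ n̄), with n̄ the mean count over
  occupied cells;
- **five-sector source attribution** (local / west / north / east / south
  rectangles tiling 108–120° E × 34–43° N), per-arrival-time air-mass
  fractions and a dominant-source label per day;
- the **daily health burden** of short-term exposure,
  RR = exp(β<sub>eff</sub>(C − C₀)) and AF = (RR − 1)/RR, with
  β = 0.38 (sensitivity range 0.31–0.45) on an explicit, configurable
  scale (default: per 100 µg m⁻³), C₀ = 0;
- per-source box-whisker summaries (mean, p10/p25/p75/p90) of PM2.5 and AF.

Because the underlying station and reanalysis data are not public, the
package ships a first-class **regime-switching synthetic generator**: each
day draws one of five wind regimes that jointly control trajectory
geometry, PM2.5 level and spread, and meteorology, with defaults calibrated
to the published per-regime statistics. Every downstream stage is testable
against known ground truth.

## Worked example

```python
import pandas as pd
from cwtburden import CWTModel, HealthBurdenModel
from cwtburden.simulate import ScenarioConfig, generate_scenario

scenario = generate_scenario(ScenarioConfig(n_days=10, seed=42))
res = CWTModel(scenario.trajectories, scenario.concentrations).fit()
print(res.summary())

days = res.daily_sources()
labels = pd.Series(days["source"].to_numpy(),
                   index=pd.to_datetime(days["date"], utc=True))
burden = HealthBurdenModel(scenario.concentrations, source_labels=labels).fit()
print(burden.summary())
```

prints

```
Concentration-Weighted Trajectory results
=============================================
trajectories (M):        2160
arrival times:           80
grid:                    48 x 36 cells @ 0.25 deg
endpoints outside grid:  8129
count weighting:         on (n_ave = 77.616, occupied cells)
defined cells:           591 / 1728

Sector shares of the CWT integral:
  local  integral       950.10  share  0.2255  (52 cells)
  west   integral       686.34  share  0.1629  (201 cells)
  north  integral       269.11  share  0.0639  (174 cells)
  east   integral      1812.85  share  0.4302  (93 cells)
  south  integral       495.79  share  0.1176  (71 cells)

Short-term PM2.5 health burden
=============================================
days:                 10 (10 complete)
beta:                 0.38 (range 0.31-0.45), scale 1/100 -> beta_eff = 0.00380 per ug m^-3
threshold C0:         0.0 ug m^-3
mean daily PM2.5:     35.63 ug m^-3
mean RR:              1.1475
mean AF:              0.1248 [beta-range spread 0.180]

Mean AF by dominant source:
  east   n=  5  mean 0.151  p10 0.098  p90 0.216
  local  n=  1  mean 0.178  p10 0.178  p90 0.178
  north  n=  2  mean 0.060  p10 0.053  p90 0.068
  west   n=  2  mean 0.097  p10 0.075  p90 0.118
```

Reading the output: 80 three-hourly arrivals over 10 days contribute 2160
member trajectories; the CWT integral concentrates in the east and local
sectors because most simulated days drew eastern or local regimes. The
dominant-source labels recover the generating regime sequence on all 10
days of this seed, and mean AF by source follows mean concentration —
north (clean) days carry the smallest attributable fraction. The
`beta-range spread` is the largest relative change in any day's AF when β
moves to either end of 0.31–0.45.

The same run from a shell:

```
cwtburden --config examples/demo.yaml --outdir out all
```

writes `cwt_field.csv`, `attribution_times.csv`, `attribution_days.csv`,
`burden_daily.csv`, `summary_by_source.csv` and a `run_log.txt` recording
the seed and every convention in effect. Reruns with the same config and
seed are byte-identical.

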