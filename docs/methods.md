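# Methods

## The receptor model

The pipeline estimates where the PM2.5 observed at a fixed receptor came
from, using only backward trajectories and the receptor's own concentration
record. For each arrival time, an ensemble of 27 back-trajectories (24 h,
hourly endpoints) describes the air parcel's plausible past paths; all
endpoints are binned on a regular 0.25° half-open lat/lon grid over
108–120° E × 34–43° N, the hull of the five source sectors.

With τ_ijl the number of endpoints of trajectory l in cell (i, j),
n_ij = Σ_l τ_ijl, and C_l the receptor concentration at l's arrival hour,

    C_ij = ( Σ_l C_l τ_ijl / Σ_l τ_ijl ) · W(n_ij)

The unweighted part is the residence-weighted mean of the concentrations
observed whenever air crossed the cell; cells crossed mostly on polluted
days get high values. W down-weights cells visited too rarely for that
mean to be trustworthy:

    W = 1.00 if n_ij > 3 n_ave        0.70 if 1.5 n_ave < n_ij <= 3 n_ave
        0.42 if n_ave < n_ij <= 1.5 n_ave    0.05 if n_ij <= n_ave

Bin edges are strict below, inclusive above (n_ij = 3 n_ave takes 0.70,
n_ij = n_ave takes 0.05). Assumptions worth keeping in mind: the method is
planar (trajectory heights are carried but unused), concentrations are
attributed uniformly along the whole path, and trajectories are treated as
error-free.

### Numerical conventions

- **n_ave over occupied cells** (n_ij > 0) by default. Averaging over *all*
  cells would make every weight depend on how much empty padding the domain
  happens to contain; the all-cells variant is available as
  `nave_mode="all"` and recorded in every run log.
- **τ counts endpoints** (hourly positions). An indicator variant
  (`tau_mode="indicator"`, at most one count per trajectory per cell) is
  provided for comparison.
- **Unvisited cells are undefined (NaN), not zero**, so sector integrals are
  sums over visited cells only and are not diluted by domain size.
- **Cells are half-open** (lower/left edge inclusive); a point exactly on
  the domain's upper/right edge is outside. This makes cell membership
  unambiguous and the sector tiling exact.
- **C_l matching**: each trajectory takes the receptor value at its exact
  arrival timestamp; a series whose timestamps are all at midnight is
  treated as daily and each arrival inherits its day's value. Any other gap
  is an error that lists the missing times — silent interpolation would
  corrupt the field.
- Degenerate inputs (empty series, no endpoints inside the domain, a field
  with no defined cell) raise or warn explicitly rather than returning
  zeros.

## Sectors and attribution

The five sectors — local 115.3–117.5° E × 39.4–41° N, west 108–115.3° E ×
34–41° N, north 108–117.5° E × 41–43° N, east 117.5–120° E × 39.4–43° N,
south 115.3–120° E × 34–39.4° N — are half-open rectangles that tile the
domain exactly. A grid cell belongs to the sector containing its center
(sector edges such as 115.3° E are not multiples of 0.25°, so cells can
straddle them).

Per-sector **integrals** sum defined CWT cells; **shares** normalise over
the five sectors, with out-of-sector cells reported separately.

Per-arrival-time **air-mass fractions** admit two modes, and the choice is
genuinely open because "fraction derived from CWT" does not pin down a
formula:

- `cwt` (default for the reported fraction series): each endpoint is
  weighted by the period CWT value of its cell (undefined cells weigh 0),
  so fractions measure concentration-weighted origin;
- `count`: each in-domain endpoint counts equally.

**Daily dominant-source labels** take the sector with the largest mean
fraction over the day's records — and default to *count* mode. This is a
deliberate deviation from weighting everything by CWT: concentration
weighting makes clean-sector days systematically mislabel, because a
north-regime day's few near-receptor endpoints sit in high-concentration
cells that outvote the many endpoints in clean northern cells. In a
60-day simulation the count-mode labels recover the generating regime on
every day while cwt-mode labels recover only about half (the acceptance
suite recomputes the count-mode figure). Exact ties break by the fixed
priority local > south > east > west > north and are flagged; records whose
endpoint weights are all zero are flagged indeterminate and excluded from
day labels.

## Health burden

Daily mean concentration C (days with fewer than 18 of 24 valid hours are
flagged; wholly missing days are absent with a warning) feeds

    RR = exp(beta_eff (C - C0)),    AF = (RR - 1) / RR

C0 = 0 by default (no safe threshold), configurable. The published
coefficient β = 0.38 (range 0.31–0.45) carries no units; taken literally
per µg m⁻³ it drives AF to ~1 at ordinary urban concentrations, which is
inconsistent with the AF levels reported alongside it. The model therefore
never hard-codes an interpretation: `beta_scale` is an explicit divisor,
beta_eff = β / beta_scale, default 100 (β per 100 µg m⁻³, giving RR
magnitudes in the range short-term exposure epidemiology reports), and
every output records the scale in effect. β-sensitivity reports per-day AF
at both range ends and the largest relative deviation from the nominal AF.

A structural consequence worth stating: AF(C) = 1 − exp(−beta_eff C) is
concave with AF(0) = 0, so for any beta_eff the ratio of two groups' mean
AFs can never exceed the ratio of their mean concentrations. With
per-regime means fixed at 61 (south) and 17.7 (north) µg m⁻³ that bound is
≈ 3.4 — the per-source AF *ordering* is reproducible, but a factor-five
south/north AF separation cannot arise from these concentration means
under this response model, whatever β is.

## The synthetic generator

Each simulated day draws one of five regimes (default frequencies: local
0.35, north 0.20, west/east/south 0.15 each; regimes are constant within a
day, matching daily event labelling). A regime fixes:

- **trajectory kinematics**: members move backward from the receptor along
  constant-bearing great circles. Bearings: regime direction + a
  per-ensemble Gaussian offset (sd 12°, synoptic variability between
  arrival times) + per-member jitter (sd 8°); speeds: regime mean × (1 +
  Gaussian, sd 0.10). Regime speeds (north 8, west 5, south 5, east 4 m/s)
  are chosen so 24 h paths reach well into their sectors, scaling the
  observed surface winds up to transport level; the stagnant local regime
  uses random bearings at 0.5 m/s with displacement capped at 50 km, which
  keeps every point inside the local sector (nearest edge ≈ 64 km).
- **PM2.5**: hourly lognormal with the regime mean (south 61, east 49,
  local 47, west 35, north 17.7 µg m⁻³ — the published means, with local
  set from the reported 1.3× south/local ratio and east/west filling the
  published ordering south > east ≈ local > west > north). Shape parameters
  (local 0.7 for its reported wide spread, west 0.35 for its narrow one,
  0.5 otherwise) are realism choices. Half of the log-variance is a shared
  daily draw and half hourly, so days differ in level while marginal means
  stay exact; σ = 0 reproduces the means identically.
- **meteorology**: Gaussian noise about the published regime means (wind
  speed clipped at 0, RH at [0, 100]); the east temperature (2 °C) is
  interpolated, being the one unpublished value.

The **hotspot mode** replaces regime concentrations with
`base + strength × (fraction of the ensemble's endpoints inside a
rectangle) + noise` — an invertible ground truth for recovery experiments.

What the generator does *not* emulate: curved or vertically sheared
trajectories, autocorrelated multi-day episodes, chemistry and deposition,
diurnal cycles, and measurement error. Passing recovery tests therefore
demonstrates that the pipeline's inference is correct when its assumptions
hold, not that real Beijing attributions are correct.

## Recovery experiments and problem sizes

- **Regime recovery**: 60 days (480 arrivals, 324k endpoints), default
  noise; daily labels must match the generating sequence on ≥ 90% of days.
- **Hotspot recovery**: 100 replicates of an 8-day all-south scenario with
  ensemble jitter 20°, member jitter 4°, strength/noise = 20; the field
  argmax must fall inside the source region in ≥ 95. The source rectangle
  spans the southern transport corridor (115.6–117.2° E × 36–39.4° N)
  because a single-receptor CWT cannot radially delimit a source along the
  mean transport ray: every cell on the dirty ray shares the same visiting
  trajectories and hence the same weighted mean — the known "trailing"
  behaviour of trajectory statistics. Transverse localisation (which
  bearing band is the source) is what the experiment tests.
- **Oracle equivalence**: 50 random instances (grids ≤ 10×10, ≤ 20
  trajectories, off-grid points included) must match a brute-force
  triple-loop CWT to 1e-12 relative.

These sizes keep the full suite to a couple of minutes while leaving the
statistical checks comfortably powered.

## Known limitations

- Straight-line synthetic kinematics understate trajectory curvature;
  recovery rates on real HYSPLIT output will be lower.
- The CWT field inherits trailing smear along transport rays; sector
  integrals partially mitigate this by aggregating over large regions.
- The β scale ambiguity means absolute AF levels are interpretation-
  dependent; orderings and relative comparisons across sources are the
  robust outputs.
- Day labels assume one dominant regime per calendar day; genuinely mixed
  days are attributed to whichever source leads on average.
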