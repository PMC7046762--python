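# Methods

## Dose model

Inhalation TED for one subject is a sum over the 56 six-hour segments
(6-HS) of 12–25 March 2011 (JST):

    E_inhal = Σ_{i=1..56} (V/4) · Σ_f C[l(i), i, f] · e[a, f] · FC · DF_shelter

- `V` — age-specific total daily ventilation volume (m³/day); divided by 4
  because each segment is a quarter day.  Reference values 5.16 / 8.72 /
  15.3 / 22.2 m³/day for 1-y, 5-y, 10-y and adult.
- `C[l, i, f]` — segment-mean air concentration (Bq/m³) of chemical form
  `f` (particulate, elemental vapour, methyl iodide) at landmark `l`.
  Segment means rather than hourly values are used because dispersion
  simulations misplace plume arrival by a few hours; averaging over six
  hours damps that error at the cost of smearing exposure for subjects who
  left just before a plume arrived.
- `e[a, f]` — age- and form-dependent committed thyroid equivalent dose
  coefficient (Sv/Bq).  A reference YAML ships with values transcribed
  from the published age-dependent coefficient tables; the test-suite uses
  round synthetic coefficients so no test depends on the transcription.
- `FC = 0.62` — the measured Japanese thyroid iodine uptake rate (18.5%)
  relative to the 30% of the ICRP thyroid model.
- `DF_shelter = 0.5` — indoor/outdoor concentration ratio while
  sheltering, a construction-year-weighted average over the housing stock
  (`averaged_df_shelter` implements the weighting).

Short-lived radionuclides (¹³²Te/¹³²I, ¹³³I) are included by a factor SF
applied to the dose accrued inside plume-date windows: ×1.59 for 12–13
March, ×1.08 for 15–16 March, 1 elsewhere.  SF is applied **per segment**,
not to the subject total: for a subject exposed only inside one window the
two are identical, but per-segment application remains correct for
mixed-plume trajectories.

Tap-water ingestion dose over the 14 days is

    E_ing = Σ_{j=1..14} V_tap · C_tap,j · e_ing · FC · Sf · X_j/3

with default consumption volumes 0.76 / 1.03 / 1.65 L/day (1-y / 5-y /
10-y), `X_j ∈ {0..3}` the meals taken in the supply area on day `j` (a
subject who evacuates after breakfast contributes `X_j = 1` at the origin
and the remaining meals at the destination source), and `Sf = 0.7` the
tap-water usage fraction.  The 30% well-water share is described in the
source material both as "30% used well water" and as the expected
proportion of the Sf binomial; we read Sf as the *tap* fraction
(1 − 0.3 = 0.7) — the reconstruction targets dwellings actually supplied
by the contaminated plants — and expose the complement switch on the
distribution for the other reading.

## Behaviour discretization

Waypoints hold from their timestamp to the next waypoint.  Each 6-HS
takes the location occupied for the most hours in the block; ties go to
the location occupied latest (an evacuating subject is dosed where they
arrive).  Hours flagged as travel are split half to the origin and half
to the destination, the odd hour to the destination; the source material
does not describe its travel-hour handling, so this rule is our choice
and is deliberately symmetric.  Unlocated hours inherit the last known
location; a calendar day that cannot be located at all makes the record
`incomplete_route`.  Movement between consecutive located waypoints
implying a sustained great-circle speed above 80 km/h (configurable)
marks the record `unrealistic_movement`; the threshold is our choice — a
questionnaire coding error produces hundreds of km/h, evacuation traffic
tens.

11 March is parsed but never dosed (releases start 12 March).  Indoor /
outdoor activity is retained as metadata but does not modulate the dose:
a single DF_shelter applies to everyone, so passing tests say nothing
about occupancy-weighted sheltering.

## Uncertainty propagation

Only FC, DF_shelter and Sf are treated as uncertain (not concentrations,
whereabouts or dose coefficients).  FC ~ Normal(0.62, 0.20) truncated at
0 (negative uptake is unphysical; the upper tail is left open), DF_shelter
~ Triangular(0.1, 0.5, 0.95), Sf = 1 − Binomial(100, 0.3)/100.  Sampling
is Latin-Hypercube: `n` equiprobable strata per variable, one uniform
draw per stratum, stratum order permuted independently per variable;
100,000 draws by default, seed recorded in run metadata (default
20110312).  Quantiles use linear interpolation of order statistics
(type 7) throughout.

Because every dose is linear in its factor product, one simulation yields
interval **multipliers** valid for every subject and every summary
statistic.  The multipliers are the product's 2.5th/97.5th percentiles
divided by the **simulated product mean** (≈ 0.3206 for FC·DF): the
published dose tables are only consistent with central statistics
interpreted as the expectation of the propagated dose distribution, and
this normalization reproduces their interval bounds across municipalities;
dividing by the plug-in central product 0.31 instead (≈ 3% smaller
denominator, multipliers 0.261/2.152 rather than 0.253/2.078) is available
via `normalize="central"`.  For combined inhalation + ingestion intervals
the FC draw is shared between pathways within each replicate, since it is
the same physiological factor.

## Scenario clustering

Forward stepwise OLS of total dose on the 56 per-segment doses selects
the dose-dominant segments (stop at cumulative R² ≥ 0.95 or 5 segments;
ties to the earlier segment).  Features are z-standardized before Ward
clustering — the standardization choice is ours; it prevents one
high-dose segment from dominating when landmark indicator features are
mixed in — and the dendrogram is cut at a user-chosen `k` (4–5 is
typical; the choice is inspection-driven, so the library reports sizes
and quartiles rather than fixing `k`).  Cluster labels are renumbered by
descending size.

Kruskal–Wallis (tie-corrected, chi-square reference) screens for any
between-scenario difference; Steel–Dwass compares all pairs: each pair's
rank-sum statistic is recomputed on that pair alone with tie-corrected
variance and referred to q(k, ∞)/√2, the studentized-range distribution
with infinite degrees of freedom.  At k = 2 this reduces exactly to the
normal-approximation Wilcoxon test (a test asserts the identity).  The
large-sample approximation is appropriate for scenario sizes of ~20–100;
it is anticonservative below ~5 observations per group.

## Synthetic data

Plume episodes place, in a few chosen segments, a footprint
`peak · exp(−d_along/decay) · exp(−(d_cross/width)²)` downwind of a source
(zero upwind), split 50/20/30 into particulate/elemental/methyl.  This is
a geometry generator, not a dispersion model: it reproduces the sharp
cross-track gradients and episodic timing of real dispersion output but
none of its meteorology, deposition or diurnal structure, so passing
tests validate the *pipeline arithmetic*, not dispersion realism.  The
default grid is 12 × 13 = 156 landmarks over a ~100 km coastal domain,
mirroring the scale of the 152-landmark table the dose reconstruction
used.  Default episode peaks (8000 / 5000 / 3000 Bq/m³) were chosen once
to put 1-year-old cohort doses in the 0–20 mSv range of the published
municipality tables.

Cohorts are built from four evacuation archetypes (shelter-in-place,
northbound into the first plume, southern repeat exposure, early
evacuee) whose waypoints sit on block boundaries; per-waypoint Gaussian
jitter (0.5 km default) individualizes subjects.  Because waypoints are
block-aligned, each subject's dose has a closed form evaluated by an
independent code path (explicit loops, brute-force nearest-landmark
scan, footprint formula instead of the stored table); an end-to-end test
requires pipeline agreement to 1 part in 10⁹ after a full CSV round
trip.  CSV writers use `%.17g` and readers `float_precision="round_trip"`
so round trips are bit-exact.

## Problem sizes and numerical choices

The default test cohort is 100 subjects on 156 landmarks, and the
uncertainty simulations use 100,000 LHS draws (the published replicate
count); the LHS-vs-plain-MC cross-check uses 10⁶ plain draws.  Nearest-
landmark ties break to the lexicographically smallest id; no maximum
nearest-landmark distance is enforced (the source material states none).
Segment boundaries are half-open `[start, end)` in JST.  Doses are kept
at full precision internally and rounded to two significant figures only
when report tables are serialized.

## Limitations

- Ventilation is not occupancy- or activity-weighted; DF_shelter is one
  number for everyone.
- The reference dose-coefficient YAML is a transcription aid, not a
  validated ICRP extract; verify before production use.
- The exact Latin-Hypercube pairing of the original proprietary software
  is unknown; only the stratification contract is reproduced (the
  quantile targets agree with plain Monte Carlo well inside reporting
  precision).
- No doses after 25 March; behaviour windows end there.
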