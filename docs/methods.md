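# Methods

This note documents the models, rules and defaults implemented in
`vegextent`, the choices made where the method leaves room, and what the
synthetic tests do and do not demonstrate.

## Survey data model

A survey is a set of 2 × 2 m plots grouped into belt transects laid
parallel to a linear construction corridor.  Each transect carries a
zone (`pipeline_area`, `inter_pipeline`, `distance`, `control`) and a
distance in metres from the outer edge of the outermost working area
(0 inside the corridor, 2000 m for the far-field control in the
reference designs).  Two standard designs are built in: `S1` (three
working-area + two inter-pipeline + eight distance transects at 10, 30,
50, 100, 300, 500, 800 and 1000 m; six plots each; 78 plots) and `S2`
(one working-area + the eight distance transects; 54 plots).

Per plot we store stalk counts and percent covers per species, plus the
visually estimated total vegetation cover.  Per-species covers may
overlap in the field, so we deliberately do **not** reconcile the
species covers with the plot total; a small slack (1 % cover) is
tolerated in validation.  Records with cover but zero counted stalks
are rejected by default (the field protocol counts every stalk) and
kept with count 0 under a permissive flag.

Filtering supports the two standard exclusions: named taxa whose growth
form distorts importance values (large-crowned shrubs such as *Tamarix
chinensis* can fill a whole plot), and "accidental" species below a
plot-occurrence threshold.

## Importance values

Within a transect, counts, plot occurrences and covers are summed over
plots *before* ratio-taking.  This is the only aggregation under which
relative density, frequency and cover are each true compositions
(sum 1 over species), which the reference table's printed columns
confirm (they sum to 1 up to printed rounding).  Averaging per-plot
ratios instead would not have that property.

The relative-cover denominator is the summed per-plot total cover by
default; a flag substitutes the summed per-species covers.  The two
agree exactly when covers do not overlap.  With overlapping covers the
total exceeds the species sum and relative covers sum to slightly less
than 1; we report them as defined rather than renormalising, since the
shortfall is real information about canopy overlap.

Display rounding is half-up (away from zero) to 3 decimals, the
convention of printed ecological tables; all internal arithmetic is
full precision.

The integrated importance value (IIV) of a species cluster is the
arithmetic mean of member IVs with absent members contributing 0 — the
cluster is judged by its whole potential composition, not by whoever
happens to be present.  Group-level IIV is the *sum* of member-cluster
IIVs.

## Modified TWINSPAN

The classifier is divisive.  One division works as follows:

1. **Pseudospecies expansion.** Each quantitative profile value becomes
   binary presences at ascending cut levels (cell = 1 iff value >
   level), preserving the nested property.
2. **Ordination.** The first non-trivial correspondence-analysis axis
   of the cluster's pseudospecies submatrix is computed by reciprocal
   averaging: row scores are weighted means of column scores and vice
   versa, centred (removing the trivial axis) and rescaled to unit
   weighted variance each pass, until the maximum score change is below
   1e-10 (at most 10 000 passes; failure raises with the residual).
   The shrinkage factor converges to the axis eigenvalue.  The start
   vector is drawn once from a fixed seed — a structured start can be
   exactly orthogonal to the leading axis on symmetric matrices — so
   the procedure is fully deterministic.  The sign convention makes the
   first row with nonzero weight score ≥ 0.
3. **Crude dichotomy.** The axis is split at its centroid: scores are
   centred, so score 0 *is* the middle of the axis.  If a side would
   fall below `min_group_size`, the boundary slides along the score
   order to the nearest admissible position.
4. **Refinement.** Pseudospecies at least twice as frequent on one side
   as the other are *preferential*; the `max_indicators` strongest (by
   frequency difference, ties by column order) vote on every item
   (+1 for a right-preferential present, −1 for left), and items whose
   net vote contradicts their side beyond `misclassification_threshold`
   are moved.  Up to `refine_passes` rounds; a round that would empty a
   side below `min_group_size` is discarded.

Division order follows Roleček's modification: the cluster with the
greatest heterogeneity — mean pairwise Bray–Curtis dissimilarity of the
raw profiles (total CA inertia available behind a flag) — is divided
next, until the requested number of terminal clusters exists or nothing
is divisible (warning + best-effort partition).  Everything is
deterministic; ties break by input order.

Defaults: `cut_levels = (0, 0.02, 0.05, 0.10, 0.20, 0.30)`,
`max_indicators = 7`, `refine_passes = 2`, `min_group_size = 1`,
`misclassification_threshold = 0`.

**Why a cut level at 0.30.**  Hill's classic percent-cover levels
(0/2/5/10/20) were designed for abundances that range up to ~100 %.
Importance values are compositional: a transect's IVs sum to 1 and a
community dominant typically sits between 0.3 and 0.6.  Rescaled
verbatim, Hill's ladder tops out at 0.2 and the binary representation
becomes blind to *dominance* — every species above 0.2 looks identical —
although dominance shifts are precisely the signal that separates
disturbance-promoted from disturbance-suppressed species.  The 0.30
level marks a species carrying about a third of the community's
importance, a conventional dominance reading on this scale.  On the
reference matrix this representation separates the pioneer and
suppressed-dominant clusters exactly as published.  The classification
is, however, sensitive to the top cut level on small matrices (a top
level of 0.25 or 0.40 merges or splits differently); for new data the
cut ladder should be reported alongside any partition, and the
sensitivity is worth checking.  No downweighting of rare pseudospecies
is applied: on matrices this small every column weight saturates, so
the option would be dead code.

Species whose IV is zero everywhere cannot be placed on a CA axis and
are dropped with a warning before clustering.

## Response groups and K points

Cluster trajectories are summarized by two zone means and a trend: the
near zone is the corridor (working-area and inter-pipeline transects)
plus distance transects up to `near_max_distance_m` (default 50 m); the
far zone is the `far_window` (default 3) outermost distance transects,
or the control transect when surveyed.  The trend is the Spearman rank
correlation of IIV against distance over the distance transects (rank
scale because the survey spacing is geometric; a flag switches to
Pearson on metres).

A cluster is **G1** if its near mean is at least `ratio` (1.5) times its
far mean, its near *share* — its fraction of the summed cluster IIVs in
the near zone — reaches `dominance_floor` (0.2), and its trend is
≤ −`trend_rho` (0.5); **G2** symmetrically with far dominance and a
rising trend; otherwise **G3**.  The floor is a share rather than an
absolute IIV so that the rule is scale-free (multiplying every IIV by a
positive constant changes nothing); it exists to keep sparse
accompanying species — present mainly far-field but never dominant —
out of the indicator group.

**Stabilization (K1/K2).**  The reference level is the mean of the
`far_window` outermost values (or an externally supplied far-field
value, e.g. from control plots); the trajectory has settled at the
smallest surveyed distance from which every value stays within
`tolerance` (default ±15 %) of the reference.  A constant series
settles at the nearest transect; a trajectory that never settles is
reported unresolved (effect extends beyond the survey).  The method
itself does not prescribe a band — "smooth and steady" is a judgement
call in the original framework — so the rule here is the simplest
auditable operationalization of a plateau, with both knobs exposed and
echoed in every report.  Tightening the band can only move K outward,
never inward.

**Crossover (K3).**  Scanning outward through the ordered transects,
the first position where the G2 trajectory strictly exceeds G1 closes
the half-open interval (previous position, that position].  No sign
change yields an empty interval with a dominance flag; multiple
changes yield the first outward crossing plus a warning.

K2 — stabilization of the summed G2 (indicator-group) trajectory — is
the headline effect extent.  When K2 and the K3 crossover disagree by a
transect, the report attaches a transition-zone note: plateau detection
and dominance change need not coincide, and the original analysis of
the reference survey illustrates exactly this, reading the indicator
trajectory as settled at 100 m by the band rule while a wider reading
folding in diversity evidence places the extent at the next surveyed
belt (300 m).  No rule reproducing the wider judgement from the IV
table alone exists; the package reports the band rule's answer and
flags the gap rather than hard-coding expert judgement.

**Indicator validation.**  `indicator_correlation` computes Pearson's r
between an IIV series and a community index with a two-sided
permutation p-value (one series shuffled `n_perm` times, add-one
correction), seed-reproducible.  Published per-cell validation values
for the reference survey cannot be reproduced here because they require
the plot-level raw data, which were never published; the test suite
instead verifies the statistic against the closed-form Pearson formula
and checks its type-I error calibration on null data.

## Diversity indices

Shannon–Wiener H uses base-10 logarithms by default, matching the
printed field convention, and evenness divides that H by the *natural*
log of species count — the published equations mix bases, so this
"evenness" is not bounded by 1.  `log_base="e"` restores the classical
Pielou index.  Richness is Margalef's (S − 1)/ln N.  Conventions:
single-species communities have H = 0 and evenness 0.  Indices are
computed either pooled per transect (default) or per plot (the sampling
unit for plot-level correlation analyses); percent cover per transect
is the mean of plot totals.

## Synthetic surveys

The generator exists so every downstream stage can be tested against
known ground truth.  Each species archetype responds to distance
through a logistic in log distance (the geometric transect spacing
makes log distance the natural scale):

```
lambda(d) = baseline * (1 + (near_multiplier - 1) * sigma(d))
sigma(d)  = 1 / (1 + ((d + 1) / midpoint_m) ** steepness)
```

Pioneers carry `near_multiplier` 5–10 (boosted near the corridor,
midpoints 50–80 m), suppressed dominants 0.08–0.1 (recovered to within
a few percent of baseline by the true extent `d_eff_m`), accompanying
species a small baseline with occupancy reduced near the corridor.
Counts are negative-binomial with quadratic overdispersion
`count_dispersion` (α = 0.2 by default; 0 gives Poisson), covers are
gamma sums over stalks (correlated with, but not determined by,
density), and plot occupancy is Bernoulli.  Pioneer archetypes get a
small per-stalk cover (0.35–0.40 % against 1.1–1.3 % for the
dominants): pioneer regrowth is thin-stalked, so total vegetation cover
is depressed near the corridor and rises outward, and the indicator
group's IIV correlates positively with percent cover — the qualitative
pattern of real post-construction gradients.  Plots are redrawn until
at least one stalk is present, since the field designs place plots in
vegetated steppe and an empty plot would make within-transect ratios
undefined.

Shipped scenarios (`src/vegextent/presets/archetypes.yaml`):
`s1_like` (13-transect design, 3 + 2 + 3 species, true extent 300 m),
`s2_like` (9-transect design, true extent 100 m), `null` (flat
responses, extent undefined).  Everything is reproducible from the
seed.

What the generator does *not* emulate: spatial autocorrelation within
transects, succession through time, invasive immigration, cover
overlap between canopies, and observer error in visual cover estimates.
Passing recovery tests therefore show that the pipeline inverts its own
generative model at realistic noise levels — not that it is robust to
every failure mode of field data.

## Problem sizes used in verification

The recovery test runs the full pipeline on 50 seeded replicates of
`s1_like` (78 plots each) and requires the archetype partition and a K2
within one transect spacing of truth in ≥ 80 % of runs (both currently
recover in 100 % of the 50 seeds).  The permutation-test calibration
uses 2 000 null replicates of length 78 with 999 permutations each.
The correspondence-analysis axis is checked against a dense SVD of the
correspondence operator on random binary matrices from 3 × 3 to 8 × 13
to 1e-8, skipping draws that are degenerate for either method (empty
rows/columns, disconnected incidence structure, near-tied leading
axes, an unstable sign anchor).

## Known limitations

- The TWINSPAN partition is sensitive to the pseudospecies cut ladder
  on small matrices (see above).
- The stabilization band (`tolerance`) has no canonical value; the
  extent estimate should always be read together with the band that
  produced it, and the framework itself regards the stable range as an
  empirical matter.
- Group assignment assumes the survey spans both a disturbed near zone
  and a recovered far field; surveys that end inside the disturbance
  yield unresolved K and should be extended outward.
- Distances are treated per-transect; the method cannot resolve an
  extent between two surveyed belts (the reference design's resolution
  gap between 100 m and 300 m is the canonical example).
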