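# Methods

## Court model and zone partition

One player's half court is modelled as a rectangle of width 5.18 m
(sideline to sideline, singles) and depth 6.7 m (net to baseline),
partitioned into a regular 4 x 3 grid of 12 equal cells: row 1 touches the
net, column 1 the left sideline, and zones are numbered row-major so the
front corners are 1 and 4, the back corners 9 and 12, and the central back
cells 10 and 11.  The physical dimensions are configurable
(`CourtGeometry`); the equal-cell grid is an assumption — coaching zone
charts do not fix cell boundaries numerically, and none of the entropy
measures depends on the absolute cell sizes, only on the partition being a
partition.

All coordinates live in the striker's own half-court frame (origin at the
net/left-sideline corner, y toward the baseline), so strokes of the two
players need no mirroring downstream.  Strikes recorded outside the
rectangle — players routinely hit from behind the baseline — are clamped to
the border cell rather than rejected: the grid is a discretization of
striking positions, not an in/out judgement.

## Standard entropy

For a zone distribution with probabilities `p_i`,
`H = -sum_i p_i ln p_i / ln 12`, with the `0 ln 0 = 0` convention for empty
zones.  Division by `ln 12` maps H to [0, 1] regardless of the sample size,
making per-match values comparable.  H is the plug-in estimator: at match
scale (L ~ 800 strokes) its downward bias at the uniform point is
`(12-1)/(2 L ln 12) ~ 0.003` (Miller–Madow), which the Monte Carlo tests
account for but no correction is applied — the analysis compares like with
like, and bias cancels in paired comparisons.

## Receiving entropy

Within each rally, every consecutive stroke pair contributes one
(origin zone -> destination zone) event; rally-final strokes contribute
none, so a match of L strokes in R rallies yields exactly L - R pairs.  Per
origin zone, the conditional destination distribution is scored with the
same ln 12-normalized entropy, so per-origin values share the standard
entropy's scale.  Origins with zero outgoing pairs are reported as missing
(NaN), never as 0 — "never strikes here" must not masquerade as "fully
predictable".  Pairs are pooled across both players of a match (the
per-player split is not identifiable from the published description; pooling
is the simpler choice and is stated here once).  Low-frequency origins (zone
10 especially) have few pairs per match, so their per-match plug-in
entropies carry a visible downward bias; the per-origin averages in the
analysis scripts should be read with that in mind.

## Spatial entropy

For N stroke coordinates in a window of area S, the Clark–Evans ratio
`Hs = <r> / r_ran` compares the observed mean nearest-neighbour distance
with its expectation under complete spatial randomness,
`r_ran = (1/2) sqrt(S/N)` (the mean of the Poisson nearest-neighbour density
`p(r) = 2 pi delta r exp(-pi delta r^2)`, `delta = N/S`).  Choices:

- **Window area** is the fixed half-court area (34.7 m²) for every match
  and split group, not the convex hull of the observed points — fixed S
  keeps values comparable across matches and groups.
- **No edge-effect correction** (e.g. Donnelly) by default: the random
  baseline of the uncorrected ratio on the half court at N = 500 averages
  ~1.01, consistent with the published random-case calibration (~0.997),
  so the uncorrected ratio is what the reference values mean.  Small-N
  patterns can exceed the asymptotic ceiling (the four corners of a unit
  square give Hs = 4); the ceiling is an asymptotic statement.
- Nearest neighbours via a KD-tree, exact; ties broken arbitrarily and
  duplicate points allowed (distance 0).

Reference generators cover the three regimes: corner-centred Gaussian
clusters (draws clamped to the window — re-sampling would bias the stream
length; at the spreads used the boundary mass is negligible), uniform
random, and a triangular lattice.  The lattice places cell-centred points
(inset half a spacing from the window edges) so its realised count stays at
or just below the target; an edge-touching grid overshoots the target
density and pushes the ratio above the `2 sqrt(2/sqrt(3)) = 2.149` ceiling.
At N = 500 the realised lattice gives Hs ~ 2.12.

## Mixture model

Each stroke adopts the four-corner strategy with probability gamma, else the
uniform-random strategy.  Marginal zone probabilities
`p4c = (1+2 gamma)/12` (corners) and `pn4c = (1-gamma)/12` (others) satisfy
`4 p4c + 8 pn4c = 1`; the closed-form entropy
`H(gamma) = -[4 p4c ln p4c + 8 pn4c ln pn4c]/ln 12` decreases strictly from
1 to `ln 4/ln 12 ~ 0.558`.

The Monte Carlo implementation follows the two-draw scheme literally: draw 1
selects the strategy (corner iff `ran1 <= gamma`), draw 2 selects the zone by
quartiles of [0, 1] (corners) or twelfths (random), with boundary hits —
probability-zero events — resolved toward the lower zone.  Simulations are
vectorized over replicates; one root seed expands through
`numpy.random.SeedSequence` substreams per (gamma, match), so sweeps are
reproducible and order-independent.  Default sweep settings: gamma grid step
0.01, 100 replicates per match, match lengths taken from the corpus under
analysis (mean ~842 strokes).

`fit_gamma` inverts an observed mean entropy by grid argmin against the
analytic curve — deterministic, no fresh simulation; passing a sweep result
switches the reference to the Monte Carlo means (reading the closest
simulated box off a sweep figure instead of the curve).  The two references
can differ by one or two grid steps near flat parts of the curve: inverting
0.894 gives 0.53 on the analytic grid, while the closest simulated mean can
sit at 0.55 — both are surfaced, neither privileged.  The curve is flat near
gamma = 0 (its derivative vanishes at the uniform point), so inversion is
ill-conditioned for observed entropies very close to 1; recovery tests
therefore start at gamma = 0.1.

## Synthetic corpus generator

The generator emulates the structure of elite singles stroke logs at the
scale of the private corpus the analysis was designed for (259 matches,
~2.2e5 strokes):

- **Zone shares**: anchored at the published corner/rarest-zone values
  (p1 = 0.170, p9 = 0.160, p4 = 0.139, p12 = 0.130, p10 = 0.011); the
  residual 0.390 is split over zones {2, 3, 5, 6, 7, 8, 11} proportionally
  to fixed weights {0.08, 0.06, 0.05, 0.05, 0.06, 0.05, 0.04} — arbitrary
  but frozen, since the published figure prints no numbers for these bars.
- **Rally lengths**: geometric on {1, 2, ...} with mean 9 (match play runs
  ~8–10 strokes per point), truncated at 50.
- **Scoring**: best-of-three sets, first to 21 without the win-by-two rule —
  the deuce rule affects entropy computations not at all, only set lengths
  slightly.  Rally winners are fair coin flips; the rally winner serves
  next.  This yields ~820 strokes per match, matching the per-match scale of
  the study corpus.
- **Coordinates**: uniform within the stroke's zone cell, optional Gaussian
  jitter clamped back to the cell, so stored zones always equal zones
  recomputed from coordinates.
- **Effect injection**: a separate zone distribution for each rally's
  eventual winner turns the null corpus into a positive control — a
  concentration difference between winner and loser distributions produces a
  detectable won/lost entropy gap, something an observational study cannot
  arrange.

What the generator does **not** emulate: serve-specific stroke placement,
within-rally spatial dependence (zones are i.i.d. given the striker),
player handedness and fatigue, opponent-quality effects, and the
within-point alternation physics of real rallies.  Tests passing on this
corpus therefore validate the measurement pipeline — not claims about real
match play.  In particular the synthetic per-match spatial entropies sit
near 0.97 (coordinates are near-uniform within corner-heavy zones), higher
than the 0.3–0.8 range reported for real matches, whose strokes cluster
within zones.

## Pipeline choices

- Won/lost split: strokes of each rally's winner vs loser, pooled per match.
- Leading/behind split: by the score at rally start; rallies starting level
  are excluded from both groups and the exclusion count is reported.
- Initial/final split: a rally is "initial" when both players are below 11
  points at rally start.
- Spatial entropy per split group uses the same fixed court area S for both
  groups.  Matches where a group has < 2 strokes (spatial) or 0 strokes
  (standard) are dropped from the pairing and logged.
- Paired comparisons use the two-sided paired Student's t-test
  (`scipy.stats.ttest_rel`); zero-variance differences raise a degenerate-
  test error rather than returning an infinite statistic.  Raw p-values are
  reported, with a Bonferroni-adjusted column (factor 3, the number of
  spatial comparisons) recorded alongside.
- Report histograms use 20 equal-width bins over the observed range; edges
  are recorded in the report so figures are reproducible from the JSON.

## Problem sizes

Defaults were chosen so the complete test suite runs in well under a minute
of compute for the unit layer and a few minutes including the study-scale
checks: Monte Carlo agreement uses 259 x 842-stroke matches x 100
replicates per gamma; the random-baseline and regime-ordering checks use
N = 500 points x 100 seeds; parameter recovery uses 10^4-stroke sequences.
The full-grid sweep (101 gamma values) lives in `analysis/06_gamma_sweep.py`
and takes about a minute and a half on one core.

## Known limitations

- Plug-in entropies are biased low at small group sizes; no Miller–Madow or
  coverage-adjusted correction is applied (out of scope; paired splits
  largely cancel the bias).
- Winner inference from score deltas cannot attribute the final rally of a
  set that started level (e.g. 20–20); files written by this package always
  carry an explicit winner column.
- The spatial entropy has no edge correction and its ceiling is asymptotic;
  values for very small N are calibration-dependent.
- Receiving entropy is first-order only (single-step transitions); no
  higher-order sequence entropies or entropy-rate estimators.
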