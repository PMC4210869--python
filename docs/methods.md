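# Methods

This note documents the models, estimators and design choices behind
`funcphylo`, and what the simulation-based tests do and do not
demonstrate about real assay data.

## Dose–response model and fitting

Each (receptor, ligand) series is modeled with the four-parameter
logistic (4PL) on log-transformed concentration,

    R(c) = bottom + (top − bottom) / (1 + 10^(h (log10 EC50 − log10 c))),

with concentration in nM throughout. `fit_4pl` performs bounded
nonlinear least squares (scipy's trust-region reflective method) over
all replicate points jointly; replicates are not averaged first, so the
error structure of the raw readings enters the fit. Initialization is
deterministic: asymptotes from the observed extremes, log10 EC50 at the
tested concentration whose mean response is nearest half-maximal, Hill
slope 1. Bounds: h ∈ [0.1, 10]; log10 EC50 within two decades of the
tested range; asymptotes within one observed span of the observed
extremes. Tolerances are set to machine level (xtol = ftol = gtol =
1e-15) so that noise-free series are recovered to ≲1e-6 relative error,
which the test suite checks.

A fitted series counts as a **responder** only if all of the following
hold, otherwise its EC50 is recorded as a non-responder sentinel (NaN):

* the optimizer converged;
* the fitted dynamic range (top − bottom) exceeds 20% (configurable) of
  the receptor's *reference* dynamic range — the fitted span of its most
  potent authentic ligand; when no reference is available the series'
  own observed range is the fallback;
* the EC50 lies within [min conc / 10, max conc × 10], i.e. at most one
  decade of extrapolation beyond the tested dilution series
  (0.01 nM – 10 μM by default);
* the sigmoid fits no worse than a flat line (RSS ≤ flat-model RSS).

Luminescence is normalized per receptor to the mean reading of the
reference ligand at its highest tested concentration, mapping the
reference plateau to 1.0. Because the 4PL is scale-equivariant, this
changes no EC50; it standardizes the responder call and reporting.

## Activity matrix

Per cell, x = min(log10 EC50[nM], cap) with cap = 4; non-responders are
assigned the cap outright (an EC50 of 10⁴ nM). The cap is applied
*before* row normalization, so a non-responder on a receptor whose best
EC50 is 100 nM scores 4 − 2 = 2, not 4. The default normalization is the
**log difference** score = x − x_lowest, the potency loss in log10 units
relative to the row's most potent ligand; the authentic ligand scores 0
and rows are invariant under a uniform potency rescale (until the cap is
hit). A literal **ratio of logs** mode (x / x_lowest) is retained for
sensitivity analysis but is numerically treacherous: it is undefined
when the best EC50 is exactly 1 nM (log = 0) and flips sign for sub-nM
potencies, which is why it is not the default.

## Sequence distances and trees

Distances between aligned receptor sequences (user-supplied alignment,
optionally trimmed to the TM1–TM7 span by coordinates) use **complete
deletion**: every column containing a gap in any sequence is dropped
globally before counting, so all pairs are scored over identical
columns. Models: uncorrected p-distance (default) and the Poisson
correction −ln(1 − p) for multiple hits. Bootstrap: columns are
resampled with replacement *before* per-replicate complete deletion;
the per-pair standard deviation over replicates (default n = 1000) is
reported as the distance SE, and the same resampling drives bipartition
supports on the NJ tree. Replicates in which no column survives
deletion are redrawn and counted.

Neighbor-Joining follows Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with the standard
branch-length and reduction formulas and a trifurcating root for the
final three lineages. Two numerical policies make runs bit-reproducible
and are logged rather than silent: Q-ties are broken by the
lexicographically smallest pair of subtree labels (keyed by the smallest
tip label beneath each node), and negative branch lengths are clamped to
zero with a count recorded on the tree. NJ is exact on additive
matrices, which the tests exploit as an oracle. The ligand-specificity
tree is scipy average-linkage (configurable: single/complete)
agglomeration of the functional distance matrix, reported as a
dendrogram with merge heights.

Pairwise "sequence distance" for the coevolution comparison defaults to
**patristic** distance (path length through the NJ tree), which smooths
individual pairwise estimates through the tree; raw pairwise distances
are available as an alternative mode. Both functional and sequence
distance matrices are normalized so their maximum off-diagonal entry is
exactly 1 before being compared.

## Coevolution comparison and pleiotropy calls

One point per unordered receptor pair: x = relative functional distance
(Euclidean distance between activity-matrix rows, normalized), y =
relative sequence distance, with y's bootstrap SE carried along.
Ordinary least squares of y on x; the 95% band is the confidence
interval of the **mean response** (t distribution, n−2 df) — a band
around the line, not a prediction interval, matching how such scatter
plots are drawn.

Flagging rule: a pair is called **positive pleiotropy** when its y lies
above the upper band limit and **negative** below the lower limit. Two
refinements make the rule usable on finite data:

* **Leave-one-out refit (default).** With ~10–15 points a gross outlier
  inflates the residual variance of the very fit used to judge it; each
  point is therefore compared against the band of a regression excluding
  it. A formal outlier test is deliberately avoided at these sample
  sizes.
* **Error-bar clearance.** A pointwise 95% mean-response band is narrow
  (half-width ∝ s·√(1/n + …) < s), so residuals of ordinary sampling
  size routinely cross it — with ~15 points, some pair would be flagged
  in nearly every dataset. When a point carries a bootstrap SE for its
  sequence distance, the call therefore requires the point minus/plus
  2 SE to clear the band: the numerical equivalent of judging a scatter
  plot with error bars by eye. Points without SEs (e.g. ground-truth
  distances in simulations) are compared to the band directly, with a
  1e-6 absolute guard so exactly-collinear inputs are never flagged
  through floating-point noise.

The **asymmetry score** formalizes non-reciprocal cross-activity:
cross(i→j) is the best (minimum) activity score any of receptor i's
authentic ligands achieves on receptor j, and asymmetry(i,j) =
cross(i→j) − cross(j→i). The matrix is antisymmetric; a negative entry
means i's ligands act on j more strongly than the reverse (scores are
potency losses, lower = stronger).

## Synthetic data: what it emulates, and what it does not

* **Plates.** Readings follow the 4PL exactly in expectation;
  measurement error is multiplicative log-normal with unit mean,
  parameterized by a coefficient of variation (luminescence is positive
  and heteroscedastic; default CV 5%). Dilutions: 10-fold from 0.01 nM
  to 10 μM (7 concentrations), 3 replicates — the standard
  deorphanization design. RNG streams are keyed by (seed, receptor
  label, ligand label) so any sub-plate reproduces exactly.
  Non-responders are flat curves (top = bottom).
* **Alignments.** 20-state equal-rates (Poisson) substitution: event
  counts per site are Poisson in the branch length (expected
  substitutions/site) and each event jumps uniformly to one of the 19
  other residues. Two sequences separated by total length b then differ
  per site with probability p = (19/20)(1 − e^(−20b/19)), the closed
  form the convergence tests use. No rate heterogeneity, no indels, no
  site-specific constraints — so bootstrap SEs on simulated data are
  binomial-clean in a way real TM-domain alignments are not.
* **Scenarios.** Receptors sit at jittered, evenly spread positions on a
  latent specificity axis; the true activity score of ligand j on
  receptor i is 3 × |position_i − position_j| (spread chosen so scores
  span the 0–4 range an activity matrix exhibits in practice), giving
  every receptor a 1 nM authentic potency and cross-potencies that decay
  with divergence. The emitted ground-truth sequence distances are
  defined as proportional to the null functional distances, so in the
  noise-free null the pipeline's points are exactly collinear and the
  detector must stay silent. Sequences evolve along an NJ tree fitted to
  that structure (deepest split 0.6 substitutions/site, alignment length
  600 by default), so *estimated* sequence distances track the truth
  only up to sampling noise — which is what the bootstrap SEs quantify.
  A planted pair (a, b) lowers b's EC50 for a's authentic ligand by
  `effect_size` log10 units (floored at the authentic potency). Note
  that planting moves receptor b's whole activity profile, so pairs
  adjacent to the planted pair also shift — detection tests therefore
  assert that the planted pair is the strongest positive call, not the
  only one.

Passing these tests shows the estimators recover the generating model
at realistic noise, not that real receptor panels satisfy the model: in
particular, real specificity profiles are not one-dimensional, real
assay noise has plate and batch structure, and real alignments violate
the equal-rates assumption.

## Problem sizes and determinism

Statistical checks are sized to run comfortably on one CPU: 200
simulated series for EC50 error calibration, 100 replicates (8 taxa ×
1000 columns) for NJ topology recovery, and 100 seeds each for
planted-pair power and the null false-flag rate, with 6-receptor panels.
Every stochastic component takes an explicit integer seed, and the
pipeline manifest records the package version, all parameters and the
seed, so any run is exactly reproducible from its manifest.
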