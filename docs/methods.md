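# Methods

## Knownness scoring

A protein's knownness is a weighted count of its GO annotations. Each
annotation record — one (protein, term, evidence code) line of a GAF file —
contributes the weight of its evidence code, and the weights (all in
[0, 1]) encode how much a given kind of evidence says about function being
*known*: experimental codes (EXP, IDA, IPI, IMP, IGI, IEP) weigh 0.8,
author statements 0.9 (TAS) or 0.6 (NAS), curator inference 1.0 (IC),
sequence-similarity codes 0.5, genomic-context inference 0.3 (IGC),
computational-analysis 0.6 (RCA), phylogenetic codes 0.5 (IBA, IBD), and
codes that carry no positive functional information — electronic inference
(IEA), "no data" (ND), NR, and the negative phylogenetic codes (IRD, IKR)
— weigh 0. All 22 weights are configurable through a YAML mapping; partial
configurations are completed from the defaults.

Interpretation choices that the raw definition leaves open:

- **Granularity.** "Number of annotations" means the number of distinct
  (protein, term, evidence code, negation) records after deduplication at
  read time. The same term supported by two different evidence codes
  counts twice — that is how annotation databases represent independent
  lines of evidence.
- **Negation.** NOT-qualified annotations are parsed and retained in the
  data model but excluded from scores by default (`include_negated=True`
  reverses this): a statement that a protein does *not* perform a function
  is not evidence of known function.
- **Aspects.** By default all three GO aspects (Process, Function,
  Component) contribute. Excluding the Component aspect is supported
  (`aspects_used={"P","F"}`) because localisation terms can be assigned by
  high-throughput methods without saying much about function.
- **Clusters.** A cluster's score is the maximum over members whose taxon
  is in the reference set (human + 11 model organisms); members from other
  species are ignored, and a cluster with no reference-species member is
  out of scope and raises. The maximum — rather than a mean — encodes that
  one well-studied ortholog transfers understanding to the family.
- **Time.** Annotations are dated by when they were first linked to the
  protein entry, so knownness-at-date sums only annotations up to the
  cut-off. Only currently held annotations are visible, so trajectories
  are non-decreasing by construction; undated records are usable for
  current scores but rejected (by name) in temporal queries.

Unknome selection combines three predicates: cluster score ≤ threshold,
all required species present, and precomputed metazoan-genome presence ≥ a
minimum fraction. The presence table must cover every candidate whenever
the presence threshold is positive; with threshold 0 the predicate is
vacuous and the table optional. Ranking is ascending (least-known first)
with ties broken lexicographically by cluster id, so orderings are fully
deterministic.

## Screen model

Screen measurements are long-format records (gene, batch, replicate,
1- or 2-dimensional value). The per-gene effect and its sampling
covariance come from ordinary least squares with gene indicators plus
additive batch offsets (first batch in sorted order is the reference, so
estimates live on the reference-batch scale; this cancels in all
downstream distances). The residual covariance is pooled across genes and
scaled by the design — pooling doubles as the variance floor for genes
with a single replicate, which are flagged `low_replicate`. A multi-batch
design in which some batch contains only one gene is rejected: its batch
effect is confounded with that gene's effect.

Variance-stabilising transforms (identity, log, log1p for counts, logit
for proportions) are applied to the *estimates*, with covariances
propagated by the first-order delta method (diagonal Jacobian). Domain
violations (log of a non-positive estimate, logit outside (0, 1)) raise
with the offending gene named.

## Robust bulk and bootstrap deflation

The per-gene estimates are modelled as a normal bulk plus a contaminating
minority of genuine outliers. Location is the coordinate-wise median
followed by one reweighting step (mean of the points inside the 97.5%
Mahalanobis contour of an initial robust fit), which removes the small
bias a plain median keeps under asymmetric contamination while preserving
exact permutation invariance (summation order is canonicalised).

The default scatter estimator is a one-step reweighted
Gnanadesikan–Kettenring (GK) estimator: MAD-based scales give variances,
pairwise covariances come from the identity
cov(x, y) = [s(x+y)² − s(x−y)²]/4, the result is projected to the PSD
cone, and a single chi-squared reweighting step (as in the reweighted MCD)
discards points beyond the 97.5% contour and rescales the survivors'
sample covariance by the normal truncation-consistency factor. If the
initial GK estimate is degenerate, the step falls back to the
smallest-distance half sample with the matching consistency factor. The
minimum covariance determinant (`method="mcd"`, via scikit-learn) is
available behind the same interface and is used as an independent
cross-check in the tests. GK was chosen as the default because the
deflation bootstrap re-runs the scatter estimator ~B times per screen and
GK is orders of magnitude faster at equal breakdown (50%) for the d ≤ 2
problems this toolkit targets.

The raw robust scatter of the estimates overstates the spread of the true
effects by (roughly) the average per-gene sampling covariance. The
deflation is a parametric bootstrap: draw synthetic bulks zⱼ ~ N(0, raw),
add per-gene noise eⱼ ~ N(0, Σⱼ), recompute the same scatter estimator,
and subtract the average inflation it exhibits relative to raw. Using the
*same* estimator inside the bootstrap cancels its finite-sample bias. The
result is clipped (in the whitened coordinates of raw) into the PSD
interval [0, raw], so deflation can never inflate and never goes negative;
clipping triggers a warning. Default B = 1000, minimum 100.

## Outlier region and per-gene test

The outlier region is the complement of the elliptical contour of
N(center, deflated scatter) with outside-probability α: Mahalanobis radius
√χ²₁₋α,d (for d = 1 this is the usual center ± z·sd interval). α is 0.05
or 0.1 in typical use; larger values are accepted but warn, since they
make the region unusually tight.

Each gene is tested with the null hypothesis "the true effect lies inside
the region". The test places the true effect at the least-favourable null
point — the boundary point nearest the estimate, which lies on the
Mahalanobis ray from the center — and simulates B estimates around it with
the gene's own sampling covariance; p is the fraction (with the +1/(B+1)
finite-sample correction) of simulated Mahalanobis distances at least as
extreme as observed. Estimates inside the region get p = 1 exactly. The
least-favourable placement makes the test conservative; calibration
simulations with the true effect on the boundary confirm the p-value
distribution is stochastically at least uniform. p-values are BH-adjusted
within each screen (not across screens), and a gene is flagged when its
q-value is at or below the configured level.

All randomness flows from a single mandatory seed through spawned
`SeedSequence` children (one for deflation, one per gene in sorted order),
so reruns are bit-identical and results are invariant to gene input order.

## Lifespan calling

A fly's lifespan from an hourly movement trace is (index of the last frame
whose displacement exceeds the threshold) × interval + one interval — the
"time point after the last change in position". The one-interval offset is
a documented convention (the death is only known to lie somewhere in the
frame after the last observed movement); the threshold defaults to 0, so
any nonzero displacement counts as movement, leaving imaging-noise
suppression to the caller. A fly still moving in the final frame is
censored at the experiment length; a fly that never moves gets lifespan 0.
Per-gene summaries use the plain median (midpoint convention for even
counts); censored flies contribute at the experiment length — a lower
bound — and an `any_censored` flag is propagated rather than attempting
survival-function estimation, which would be overkill for ranking lines by
median survival.

Viability calls follow the screen's qualitative rule: no adult progeny at
all is lethal; adults that emerge but mostly fail to survive is
semi-lethal; otherwise viable.

## Synthetic data

The generators define the conditions under which the toolkit is validated:

- `gen_gaf` draws per-code Poisson annotation counts per protein, with
  uniform dates and per-protein-unique terms (so deduplication removes
  nothing), and records each protein's exact expected score at generation
  time by direct summation — an oracle independent of the scoring engine.
- `gen_screen` draws true effects from N(bulk_mean, bulk_scatter),
  displaces a contaminated subset by a fixed vector (random sign per
  gene), assigns replicates to batches cyclically, and adds N(0, batch_sd²)
  batch offsets and N(0, noise_sd²) replicate noise. Defaults (J = 200
  genes, d = 2, 4 batches, 5 replicates, unit bulk and noise variances,
  5% contamination) are sized like a typical quantitative knockdown
  screen so full pipeline runs take seconds.
- `gen_traces` emits strictly positive displacements up to the lifespan
  frame and zeros after, so the lifespan caller recovers the inputs
  exactly at threshold 0.

What the generators deliberately do not emulate: GO term-graph structure
(no ancestor propagation — also out of scope for scoring), correlated or
non-normal replicate noise, batch-by-gene interactions, and realistic fly
demography. Passing tests therefore demonstrate correctness of the
algorithms under their stated model, not robustness to every failure mode
of real screen data; the robust estimators' contamination tolerance is
tested explicitly (20% point-mass contamination) as a partial guard.

## Numerical choices and limitations

- Eigenvalue floors (1e-10 relative) regularise near-singular scatter
  estimates before Cholesky; genuinely singular configurations (all points
  identical) raise.
- Zero per-gene sampling covariance short-circuits deflation (returns raw
  unchanged).
- The reported per-gene estimates are reference-batch means; only
  differences and distances are interpreted, never absolute locations.
- The bootstrap test's B caps p-value resolution at 1/(B+1); with BH over
  ~200 genes and B = 1000, the smallest achievable q is ~0.2/rank, ample
  for screen-scale decisions but not for genome-wide FDR levels.
- Exact reproduction of any particular published hit list additionally
  depends on that study's precise robust-estimator and bootstrap variants;
  the defaults here satisfy the same stated contracts (breakdown,
  consistency, conservatism) but boundary-grazing genes can differ.
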