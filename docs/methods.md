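# Methods

## Problem and model

The package implements a two-stage microbiome co-occurrence analysis
(MiCA) of effect modification. The scientific question it serves: does a
binary population stratifier — here food insecurity — modify the
association between small groups of co-occurring gut microbes
("cliques") and the risk of cognitive impairment (RCI)?

The outcome is an adapted mini-cog word-recall score, an integer 0–3
where higher means better recall. For regression it is inverted and
log-transformed to a risk scale:

    rci = ln(4 − score) ∈ {0, ln 2, ln 3, ln 4},

strictly decreasing in the score, so higher values mean higher risk. The
inversion constant 4 is the smallest integer shift keeping the log
argument positive, and it anchors the lowest-risk score (3 words
recalled) at exactly 0. The constant and log base are package choices —
"inverted then log-transformed" does not pin them down — and the
transform is centralized in `preprocess.transform_outcome` so a
different convention is a one-line change.

All association models are ordinary least squares of `rci` on an
exposure plus the fixed covariate set (age, BMI, dietary fiber in grams,
continuous; gender, race/ethnicity coded non-Hispanic White vs other,
pet ownership, ever-smoking, past-year antibiotic use, binary).

### Stage 1 — rh-SiRF clique discovery

Within each stratum of the modifier, a repeated-holdout signed iterative
random forest mines taxa that co-occur on decision paths:

1. **Iterated forests.** Each iteration grows `n_bootstraps` regression
   trees, each on a bootstrap resample. Split candidates are sampled in
   iteration 1 uniformly and afterwards proportional to the previous
   iteration's normalized impurity importances. Weighted per-node
   candidate sampling is implemented by giving each tree a feature
   multiset of size p drawn with replacement proportional to the
   weights, with per-node subsampling of `feature_fraction · p` columns
   — the weighted analogue of mtry. Iterating concentrates splits on the
   persistently informative taxa.
2. **Signed path parsing.** Each root-to-leaf path yields a set of
   (taxon, sign) pairs — `high` if the path takes the greater-than
   branch at that taxon's split, `low` otherwise; a taxon split at
   several depths keeps its deepest (most conditional) sign.
3. **Itemset mining.** Signed itemsets up to size 4 (the largest clique
   size of interest) are counted over paths, weighted by leaf sample
   count; support is anti-monotone by construction. Itemsets above a
   support floor count as "recovered" in that forest.
4. **Repeated holdouts.** The fit-and-mine cycle runs on `n_repeats`
   random 60/40 train/test partitions; an itemset's *stability* is the
   fraction of repeats recovering it. Real structure recurs across
   partitions; overfitting artefacts do not. Repeated holdouts guard
   against partition overfitting — they cannot remove dataset-level
   spurious associations, which is why stage 2 exists.
5. **Sign collapse for selection.** The downstream indicator counts
   *present* members, for which the side of the split is informationally
   symmetric: a path conditioning on joint absence identifies the same
   membership as one conditioning on joint presence (and in practice the
   largest leaves — joint absence — carry much of the signed support).
   Selection therefore operates on sign-collapsed taxon sets whose
   stability is the per-repeat union over sign patterns; the signed
   itemsets are still reported for interpretation.
6. **Closed-loop selection.** Taxon sets at or above the stability
   threshold (default 0.5) contribute pairwise edges to a co-occurrence
   graph. The accepted set is reduced from the top of the stability
   ranking by dropping the lowest-ranked candidate until every connected
   component is "closed": a single edge (a 2-node loop) or a component
   in which every node lies on a cycle. Each component becomes one
   candidate clique. This reading of "closed-loop network" accepts a
   triangle assembled from three pairwise itemsets and rejects a
   dangling chain extension.

Defaults for desk-scale runs are 100 repeats × 25 trees (the reference
procedure is 1000 × 250; stability estimates change only within binomial
Monte-Carlo error), 4 iRF iterations, tree depth 4, minimum leaf 4,
per-node candidate fraction 0.10, support floor 0.02. The forest
geometry was set by simulation probes of planted-pair recovery at
stratum-sized n (~70): shallow trees with few per-node candidates give
the conditional partner split its best chance against noise taxa, and
the feature-multiset scheme lets importance concentrate without losing
per-node diversity.

Stage 1 deliberately produces no p-values; prediction quality on the
test partitions is not an estimand.

### Stage 2 — permutation-calibrated inference

Each selected clique of k taxa is summarised per sample by an indicator
counting present members (abundance > 0), an integer 0..k. Within the
discovery stratum, OLS of `rci` on indicator + covariates gives the
effect per additional present member. The headline p-value permutes the
outcome vector N times (default 10⁵; scaled runs use 10³–10⁴) and
refits, comparing the coefficient's t-statistic:

    p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + N).

The t-statistic (pivotal) rather than the raw beta is compared, and the
outcome is permuted unconditionally, matching the plain reading of the
procedure; a Freedman–Lane-style residual permutation would condition on
covariates and is a possible extension. Refits are vectorised through
one QR decomposition of the fixed design, so the permutation
distribution is exact for the stated model. "Robust p" in this package
means this permutation p; heteroskedasticity-consistent (HC3) standard
errors are available in `ols_fit(robust=True)` but are not the default
inferential basis.

Supporting analyses per clique: out-of-bag validation (the same
regression in the opposite stratum; a constant indicator there is
reported as non-validatable, not an error), an indicator × modifier
product term in a single all-sample model (its coefficient estimates the
difference of stratum slopes), and covariate balance diagnostics —
logistic propensity of the dichotomised indicator (any member present),
five propensity-quantile subclasses (defective subclasses merged with a
neighbour), standardized mean differences per covariate before and
after subclass weighting with the pre-balancing pooled SD as the fixed
denominator.

### Univariate screening

Per-ASV regressions use quartile codes (empirical 25/50/75% cut points,
ties assigned to the lower code, constant vectors collapsing to 0) as a
single ordinal slope, so per-ASV estimates share a scale. Families for
Benjamini–Hochberg correction are per stratum, never pooled. Shannon
diversity is computed in nats from the unfiltered relative abundances.

## Synthetic cohort generator

The generator emulates the statistical structure of a mid-sized adult
cohort; it is the test bed for every stage:

- **n = 360** samples, **150** taxa, modifier prevalence **18.9%**.
- Covariates drawn from stratum-specific marginals of a Wisconsin adult
  survey sample (e.g. age 62.6 ± 13.2 secure vs 56.8 ± 13.6 insecure;
  fiber log-normal). Covariates are conditionally independent given the
  modifier: the joint dependence structure of real survey data is *not*
  emulated, so passing tests say nothing about confounding patterns that
  depend on covariate correlations.
- Abundances: per-taxon Bernoulli presence × Gamma positive draw, rows
  closed to sum 1. Presence probabilities Beta(1.2, 2.0) and log-normal
  Gamma shapes across taxa give many rare taxa and a long-tailed
  rank-abundance curve; some taxa fall below the 5% prevalence filter,
  exercising it. No phylogenetic, taxonomic or interaction structure
  beyond the planted cliques is simulated.
- **Planted clique:** taxa 0 and 1, joint prevalence target 0.25,
  latent slopes 0.29 (insecure) / 0.05 (secure) per present member. In
  the canonical fixture the members are fixed at 50% presence each, so
  the 25% joint prevalence corresponds to near-independent co-presence.
  This is the regime in which co-occurrence discovery is well-posed:
  near-perfectly co-present members leave the partner taxon no
  conditional signal along decision paths.
- **Outcome:** latent risk = 0.37 + covariate effects (centred) +
  stratum slope × indicator + N(0, 0.2²), clipped to [0, ln 4], then
  *stochastically rounded* to the neighbouring score grid values with
  probabilities proportional to proximity. This makes
  E[ln(4 − score) | latent] equal the clipped latent value, so the
  generator is the exact stochastic inverse of the outcome transform and
  downstream regressions recover planted slopes without attenuation
  (deterministic nearest-grid cuts attenuate a 0.29 slope by ~5% at this
  noise level). The baseline 0.37 puts the mean score near 2.3,
  matching the emulation target, and keeps clipping mass small (the
  residual clipping bias is ≪ 0.01 on the slopes). A corollary: with
  zero noise and zero effects the score is constant only when the
  baseline sits exactly on the transform grid.
- **Missingness:** covariate cells MCAR at 2%; outcome and modifier are
  never masked. Imputation is single-shot predictive mean matching
  (k = 5 donors, linear predicted means on the remaining covariates);
  single imputation keeps the pipeline deterministic given the seed, at
  the price of not propagating imputation uncertainty — defensible at
  <2% missingness.

All randomness flows from one master seed through named SHA-based
sub-streams (`synthio._rng`), so each operation is individually
reproducible and the end-to-end run is bit-identical under a fixed seed.

## Numerical and degenerate-input choices

- Prevalence filter: strictly more than the threshold ("more than 5%"),
  presence = abundance > 0 exactly, no pseudo-count; retained columns
  are bit-identical (no renormalization), so filtered row sums are ≤ 1.
- Quartile ties collapse downward; a constant vector codes to all 0.
- Rank-deficient designs raise an error naming the collinear columns.
- An all-zero abundance row is an error naming the sample.
- The permutation p-value uses add-one smoothing and can never be 0.
- Clique selection ties break by stability, then mean within-forest
  frequency, then lexicographic order — a total order for
  reproducibility.

## Scaled problem sizes

Test and script runs use 100 repeats × 25 bootstraps for stage 1,
2,000–10,000 permutations for stage 2, and 60–400 replicates for the
calibration experiments; these sizes were chosen so the full suite runs
in minutes on one CPU while keeping Monte-Carlo error well inside each
check's tolerance. The reference-scale counts (1000 × 250, 10⁵) are the
config defaults for real analyses.

## Known limitations

- At stratum sizes near n = 70 with 150 taxa, the maximum spurious
  association among noise taxa is comparable to a planted |r| ≈ 0.4
  signal; across replicate *datasets*, stage-1 recovery of the exact
  planted pair is therefore capped well below 1 no matter the miner.
  The shipped-fixture experiments hold the dataset fixed and vary the
  algorithm's randomness, which is the quantity stability scoring
  actually controls. Stage 2's permutation inference is the guard
  against dataset-level spurious discoveries (as the worked example
  shows: a spurious secure-stratum pair passes stage 1 and is nullified
  by stage 2).
- The closed-loop rule is one formalisation of an informally described
  selection criterion; alternatives (e.g. requiring triangles only)
  would select differently.
- Outcome permutation is unconditional; under strong covariate-outcome
  dependence a residual-permutation scheme would have better small-n
  exchangeability.
- The generator's covariate independence and lack of taxon-taxon
  correlation mean balance diagnostics and FDR behaviour are tested
  under milder dependence than real microbiome data exhibit.
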