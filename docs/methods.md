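# Methods

This note records the statistical models implemented in `assemblyproc`,
the conventions and defaults chosen where the literature allows several,
and what the synthetic-data validation does and does not demonstrate.

## Count-table handling

The canonical object is a taxa × samples matrix of non-negative integer
read counts. Rarefaction draws, per sample, a multivariate
hypergeometric subsample (without replacement) at the requested depth;
samples whose total falls below the depth are dropped with a warning
rather than raising, matching the common practice of rarefying to the
minimum observed depth. Relative abundance divides each sample column
by its total; all-zero samples are preserved as zeros and flagged.

The per-habitat abundance filter keeps a taxon when its **mean**
relative abundance across a habitat's samples exceeds the threshold
(default 1%). A per-sample variant (`mode="sample"`: any single sample
above the threshold) is exposed because both readings of "abundance
greater than 1% per habitat" are defensible; the mean is the default as
it is stable against single-sample spikes in sparse tables.

## Diversity conventions

* Shannon entropy uses the natural log. Gini–Simpson (1 − Σp²) is
  reported rather than Simpson's D. Chao1 is always the bias-corrected
  form S_obs + F₁(F₁−1)/(2(F₂+1)), which needs no special case when
  doubletons are absent.
* PCoA eigendecomposes −½·J·D²·J. Coordinates are formed from positive
  eigenvalues only; negative eigenvalues (non-Euclidean dissimilarities)
  are reported untouched, with no Lingoes/Cailliez correction, and
  variance proportions are taken over the positive part of the spectrum.
* PERMANOVA is restricted to one factor. The pseudo-F uses
  SS_total = Σd²/n and within-group sums computed the same way; the
  p-value permutes group labels.
* Mantel correlates the upper triangles (Pearson default, Spearman
  optional) and permutes rows/columns of the second matrix jointly;
  999 permutations by default. The test is one-sided for positive
  association.
* All permutation p-values use the add-one estimator
  (1 + #extreme)/(1 + B), so p is never exactly 0 and the Monte-Carlo
  test is exact-level. Given a seed, p-values are bit-for-bit
  reproducible; this is why the permutation machinery is implemented
  in-package, with scikit-bio used as an independent cross-check of the
  statistics in the test suite.

## Specificity and occupancy

For taxon S and habitat H over a factor with levels H₁…H_k:

* specificity(S, H) = mean abundance of S across H's samples, divided by
  the sum of those habitat means over all levels — so it sums to 1 over
  habitats and equals 1 for a habitat-exclusive taxon;
* occupancy(S, H) = fraction of H's samples where S has a nonzero count.

Habitat means are computed on relative abundances by default so that
unequal sequencing depth cannot bias specificity; on a rarefied table
this coincides exactly with count-based means (`use_relative=False`
provides the count reading). A specialist for H is a taxon with both
quantities ≥ τ (τ = 0.7 default, inclusive bound). Crossed factors
(e.g. lifestyle × region) are supported by label concatenation.

## Null-model assembly partitioning

βMNTD between samples j and k is the abundance-weighted mean distance
from each taxon present in one sample to its nearest phylogenetic
neighbour in the other, averaged over both directions; shared taxa
contribute zero. Weights are within-sample relative abundances
renormalized over present taxa (or 1/richness for the unweighted
variant). Cophenetic distances come from the tree's patristic path
lengths.

βNTI standardizes the observed βMNTD against a **taxa-shuffle** null:
taxon identities are permuted on the cophenetic matrix (abundances
fixed), βMNTD recomputed for every pair, 999 times by default, and the
z-score (obs − null mean)/null sd reported. Pairs whose null
distribution has zero spread — notably pairs with identical taxon
membership, where every nearest-neighbour distance is zero under any
relabeling — are flagged degenerate rather than scored, and excluded
from downstream fractions.

RC_bray builds, for each sample pair, null communities that preserve
each sample's observed richness and total reads: taxa enter a null
sample with probability proportional to their occurrence frequency
across samples, each chosen taxon receives one individual, and the
remaining reads are distributed multinomially in proportion to
dataset-wide relative abundances. With obs the observed Bray–Curtis,
RC = 2·[P(null < obs) + ½·P(null = obs)] − 1 ∈ [−1, 1]. Because the
null draws individuals, RC_bray should be computed on the rarefied
(equal-depth) count table.

Classification per pair: βNTI > 1.96 → heterogeneous selection;
βNTI < −1.96 → homogeneous selection; otherwise RC > 0.95 → dispersal
limitation; RC < −0.95 → homogenizing dispersal; otherwise drift.
Comparisons are strict, so values exactly at a threshold fall through
to the weaker category. Process fractions are tallied over unordered
within-group pairs (groups from a metadata factor), or over all pairs
when no factor is given; the whole-community two-matrix formulation is
implemented, not a per-clade decomposition.

## Sloan neutral community model

At neutral immigration–drift stationarity, the local relative abundance
of a taxon with metacommunity mean p follows Beta(Nmp, Nm(1−p)), with
N the local community size (reads per sample) and m the immigration
probability. The package offers two occurrence-frequency curves:

* **threshold** (`ncm_predict`): freq = 1 − I_d(Nmp, Nm(1−p)), the
  classical recipe with a sharp detection limit d (default 1/N).
* **reads** (`ncm_predict_reads`): detection is "at least one of N
  reads", whose exact probability under the Beta mixture is
  1 − B(a, b+N)/B(a, b) in closed form.

`fit_ncm` minimizes the squared frequency residuals over m ∈ [1e-6, 1]
with a bounded deterministic scalar optimizer (fixed tolerance, no
random start), N = mean sample total, and reports Nm, R² on
untransformed frequencies, a Wilson score envelope at the requested
confidence level (n = number of samples), and the above/within/below
partition of taxa relative to that envelope.

The **reads** curve is the fitting default. Validation against the
generative neutral simulator (below) shows the sharp-threshold recipe
overestimates m by roughly 20–30% at realistic depths — the d = 1/N
cutoff is only an approximation to read-level detection — while the
exact curve recovers the generating m within a few percent
(500 taxa, 50 samples, depth 5000, m ∈ {0.05, 0.1, 0.5}). The
threshold variant and its detection limit remain available for
comparability with the classical implementation lineage.

## Synthetic communities

* `simulate_tree`: pure-birth (Yule) tree, unit birth rate, ultrametric,
  tips t1…tn (via dendropy's birth–death simulator).
* `simulate_metacommunity`: lognormal abundances (σ = 1.5 default — a
  steep, realistic species-abundance distribution), normalized, sorted.
* `simulate_neutral`: samples the Sloan stationary Beta per taxon,
  renormalizes, draws reads multinomially. Sampling the stationary
  distribution directly (rather than simulating birth–death dynamics
  forward) makes neutral-model fitting a true parameter-recovery oracle.
* `simulate_selection`: Brownian traits along the tree (covariance =
  shared root-to-tip path length), standardized by the stationary SD so
  habitat optima are in trait-SD units; sampling weights
  p·exp(−strength·(trait − optimum)²), i.e. soft multiplicative
  filtering that preserves richness; multinomial reads.
* `simulate_dataset` splits samples evenly between two habitats and
  expands one config seed into per-component seeds. The metacommunity
  abundances are assigned to tips in **random order**: the generator's
  sorted output would otherwise correlate abundance rank with tip order
  and inject phylogenetic signal into the nominally neutral regime.

Defaults mirror a rarefied amplicon survey at small scale: hundreds of
taxa, tens of samples, read depths in the thousands, two habitats.
What the generators deliberately do not emulate: sequencing error and
chimeras, taxonomy, real environmental gradients, temporal structure,
and taxon–taxon interactions. Passing validation on these data
demonstrates the estimators are correct under their own assumptions —
not that any particular field dataset satisfies those assumptions.

## Validation design and problem sizes

The acceptance checks (mirrored in `scripts/acceptance.py`) use:

* 50 random tables (≤ 12 taxa × 6 samples) for exact brute-force oracle
  agreement (Bray–Curtis, βMNTD, specificity/occupancy, alpha indices);
* four neutral datasets of 200 taxa × 12 samples at depth 2000 with 999
  nulls each — 264 pooled sample pairs — for βNTI calibration (pooling
  stabilizes the extreme-pair fraction, which on a single 66-pair
  dataset can legitimately be zero);
* 500 taxa × 50 samples at depth 5000 for migration-rate recovery;
* 100 taxa × 12 samples at depth 1000 with 999 nulls for the
  selection-versus-neutral classification contrast (strength 5, optima
  3 SD apart);
* 400 replicates at 199 permutations for Mantel/PERMANOVA type-I rates;
* a 40-taxon pipeline run executed twice for byte-identical determinism.

These sizes keep the full validation under a few minutes on one CPU
while leaving each check comfortably powered.

## Known limitations

* PERMANOVA handles a single factor; no interactions, no strata.
* RC_bray assumes integer counts and equal-ish depths; run it after
  rarefaction.
* βNTI pairs with degenerate nulls are reported but unclassified; with
  very few taxa or near-identical membership this can remove pairs from
  the fractions.
* The NCM fit assumes one metacommunity for all samples; fit per
  habitat level (`--per-level`) when that is implausible.
* The fixture and simulators use two to three habitat levels; nothing
  prevents more, but the validation suite does not exercise them.
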