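# Methods

This note documents the statistical models behind `doms`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Fraction profiles and quality control

A replicate map assigns each protein a six-point profile: its LFQ
intensities in the 1k–78k × 1000 g pellets divided by their sum. Profiles
are comparable across proteins irrespective of abundance and are the sole
input to classification and shift statistics; abundance changes therefore
cannot masquerade as localization changes.

Quality control keeps proteins with at least `min_consecutive_fractions`
(default 3) consecutive measured pellet intensities and a mean MS/MS count
across the six fractions (missing counted as 0) of at least
`min_avg_ms_count` (default 2). Two conventions are worth noting:

- *Missing vs zero.* MaxQuant writes 0 for not-quantified proteins. The
  reader keeps a literal 0 distinct from an empty cell, but the
  consecutive-run rule treats 0 intensity as not measured (a run requires
  positive evidence), while MS-count averaging treats missing counts as 0.
- *Consecutive* is evaluated in the physical centrifugation order
  1k → 78k, the only order in which adjacency is meaningful.

For joint analyses (PCA, classification, neighborhood) the six fractions of
each replicate are concatenated column-wise (18 features for 3 replicates).
PCA mean-centers per column and reports scores on the first two components
with explained-variance fractions; an input of rank < 2 is an error rather
than a degenerate plot.

## Movement–reproducibility analysis

Comparing two conditions replicate-by-replicate (control replicate *i* with
treatment replicate *i*, the cognate pairing) yields per-protein delta
profiles whose components sum to zero. The eligible universe is restricted
to proteins profiled in every replicate of both conditions with all
within-condition pairwise cosine correlations above `cosine_prefilter`
(default 0.9).

**Outlier statistic.** Non-relocalizing proteins have delta profiles near
baseline; relocalizers are multivariate outliers. Per replicate, location
and scatter of the delta vectors are estimated from the least-moving
`static_proportion` (default 0.75) of proteins, iteratively re-selected for
`outlier_iterations` (default 11) rounds; squared robust Mahalanobis
distances in the rank-5 sum-zero subspace (Helmert basis) are referred to
χ² with 5 df. Two numerical details make the χ² reference calibrated:

1. *Trimming consistency.* A covariance estimated from the 75% least
   distant points underestimates the true scatter; it is rescaled by the
   standard MCD-type factor α / F_{χ²_{d+2}}(χ²_{d,α}) with d = 5,
   α = 0.75 (≈1.38).
2. *Per-protein whitening.* Profile noise is strongly heteroscedastic
   across proteins. Under multiplicative intensity noise ε, a normalized
   profile p has first-order noise δ ≈ (diag(p) − p pᵀ) ε, so the delta
   covariance shape is A², A = diag(p) − p pᵀ, known per protein from its
   mean profile over all maps. Each delta vector is whitened by
   (Bᵀ A² B)^{−1/2} (B the Helmert basis; eigenvalues floored at 10⁻⁴ of
   the largest so fractions without signal do not explode). Whitening uses
   only the mean profile, never the between-condition difference, so
   planted or real shifts are untouched. The pooled robust scatter then
   absorbs the global noise scale. Without this step, peaked profiles
   (nucleus) and tail-heavy profiles (ribosome) would have systematically
   deflated/inflated p-values; with it, null p-values are uniform
   (KS ≈ 0.015 at n ≈ 1500 in the validation run).

A singular scatter matrix is ridge-regularized with a warning.

**Scores and hits.** Replicate p-values are Fisher-combined (−2Σln p ~
χ²₆), BH-adjusted across the tested universe, and −log₁₀-transformed into
M; M = 2 means movement at an estimated FDR of 1%, and the 5% FDR cut-off
is M = 1.3. R is the median of the three pairwise Pearson correlations of
the replicate deltas; a constant delta leaves R undefined and the protein
cannot be a hit. Hits require M > 1.3, R > 0.8 and p < 0.05 in at least 2
of 3 replicates. BH is applied per comparison (control vs each stressor
separately). Zero p-values are clamped to the machine minimum with a
warning.

## Compartment classification

Twelve classes (nucleus, cytosol, mitochondria, vacuole, plasma membrane,
Golgi, ER, ribosome, nuclear envelope, proteasome, lipid droplets,
peroxisomes). The SVM is RBF-kernel with pairwise-coupling probability
output (scores sum to 1); hyperparameters are drawn from C ∈ [1, 30]
(uniform) and gamma ∈ [1, 50] (log-uniform — the sampling law for a
scale-type parameter) for `svm_search_iterations` (default 5) candidates,
scored by stratified five-fold CV accuracy, and the winner refit with
probability calibration. Classes with fewer than 5 markers are excluded
with a warning. Probability ties in the argmax resolve to the
lexicographically first class and are flagged.

The seed training set takes the 100 most abundant profiled proteins of
each large reference class (cytosol, ER, mitochondria, nucleus, plasma
membrane, vacuole) and every profiled member of the small classes. The
refinement loop trains, classifies all profiled proteins, and rebuilds the
training set as correctly recalled markers plus non-markers whose
≥medium-confidence (score > 0.65) prediction matches the reference; it
stops when recall is 100% and nothing is added, and errors out with its
audit log after `marker_training_max_rounds` (default 20) rounds. The loop
never drops a correctly recalled marker, and rerunning it on its own
output is a no-op.

Benchmarking splits markers 80:20 (stratified), trains with CV on the 80%,
and averages per-class F1 over 20 random 75% subsamples of the test
predictions; lipid droplets and peroxisomes have too few members for an
informative test set and are excluded. Agreement with the reference drops
categories the SVM cannot produce (actin-associated, ambiguous, COPI,
COPII, ERGIC, unknown), merges endosomes→vacuole and cell wall→plasma
membrane, and accepts a "cytosol" prediction as a dual-localization match
when the measured cytosolic pool exceeds 30%.

## Pools, organelle shifts, ER cascade

Pool profiles weight normalized seven-fraction intensities by per-fraction
relative protein yields (one yield vector per experiment, the average
percentual recovery across replicates) and renormalize; entries partition a
protein's recovery, the seventh being the cytosolic pool. Pool-shift hits
need BH FDR < 5% on the Fisher combination of the two paired-t p-values,
p < 0.05 (DTT) and p < 0.1 (the noisier tunicamycin set), an absolute
change above 10 *percentage points* under both stressors (the axis unit of
the pool scale, not a relative change), and a consistent direction
(positive = toward the cytosol).

Organelle shifts compare per-replicate average marker profiles. The test
multiplies the smallest of the six datapoint-wise paired-t p-values by six
— a min-p Bonferroni-style correction implemented exactly as specified for
this fixed six-test family — and caps at 1. Datapoints that are
numerically identical across replicates get p = 1 (no change) or p = 0
(deterministic change) rather than an undefined t. The magnitude is the
mean L1 distance over cognate replicate pairs, binned at 0.1 (the typical
inter-replicate scatter)/0.2/0.3 into negligible/small/medium/large;
"shifted" requires Q < 0.05 and distance > 0.1. Lipid droplets and
peroxisomes are excluded (too few markers).

ER-redistribution candidates must (1) be MR hits, (2) have ΔcorrelER > 0,
where ΔcorrelER is the change, control → stress, of the Pearson
correlation between the protein's condition-average profile and the
average ER marker profile, (3) correlate with the stressed ER profile
above 0.75, and (4) have a post-ER secretory localization (signal peptide
and/or ≥1 transmembrane domain, no mitochondrial transit peptide, category
among ERGIC/Golgi/plasma membrane/cell wall/vacuole/endosomes).
Condition-average six-point profiles are used for the correlations — the
minimal reading of "profile correlation"; borderline cases that fail only
the correlation cut-off by ≤0.05 are emitted as a near-miss report rather
than rescued automatically. ER-lumenal proteins are the ER-category
entries with a signal peptide and no transmembrane domain.

## Abundance layer

Imputation draws missing log2 intensities per column from
Normal(mean − 1.8·sd, (0.3·sd)²) of the observed values — the left-censored
missingness model under which low-abundance proteins are replaced near the
detection limit. The volcano statistic is Student's pooled-variance
two-tailed t (the convention for this analysis style) plus the SAM-style
t′ = Δmean/(SE + S0), S0 = 0.1. The significance cut-off on |t′| is the
largest observed |t′| threshold at which the median permuted exceedance
count divided by the observed count stays ≤ the target FDR; at n = 3 + 3
all 20 balanced relabelings are enumerated, larger designs draw 250 random
ones. Raising S0 never increases |t′|.

The proteomic ruler: total protein mass per cell M = DNA pg × ΣI/ΣI_hist
(histones are stoichiometric with DNA; the histone id set is an explicit
input), copies ∝ I/MW scaled so Σcopies·MW/N_A = M, cell volume = M /
protein concentration, molar concentration = copies/(N_A·V). Copies are
invariant to global intensity rescaling. Supporting arithmetic: genome
mass = bp × 650 g·mol⁻¹ / N_A (0.013 pg for 12.1 Mbp); ploidy = DNA
pg/genome pg reported to one decimal (0.022/0.013 → 1.7); protein
concentration interpolates linearly between 94 g/l (haploid) and 79 g/l
(diploid) with the integer report *truncating* — the convention that
reproduces 83 g/l from the interpolated 83.5.

## Synthetic data: what it emulates, what it does not

Each of the 12 compartments has a hand-designed pellet template (pairwise
L1 distance ≥ 0.4; heavy organelles pellet early, ribosomes at 78k) and a
cytosol-leak share (≈0.9 for cytosolic proteins, 0.3 for mechanically
damaged nuclei, ≤0.1 for sealed organelles). Per protein:

- abundance log-uniform over four decades (10⁶–10¹⁰ intensity units,
  ≈10²–10⁶ copies/cell at 10⁴ units/copy), emulating the dynamic range of
  a yeast proteome;
- expected profile (1−α)·A + α·B for planted relocalizers (α is the
  mixing shift, applied in all stressed conditions), scaled by abundance
  and an optional log2 fold change;
- independent log-normal multiplicative noise per fraction with CV 10%
  (default `replicate_cv`), the standard model for LFQ intensities;
- deterministic left-censoring below `detection_threshold` (10⁵ units),
  matching the down-shifted-normal imputation assumption;
- MS/MS counts Poisson with mean 4 per decade of intensity above the
  threshold;
- yields per fraction summing to 0.90 (protein is lost in washes).

Random streams are keyed (seed, protein index), so output is bit-stable
under protein reordering and identical seeds give identical tables.

Not emulated: peptide-level effects and shared peptides,
match-between-runs artifacts, fraction-to-fraction noise covariance
(independence per fraction is assumed — the true covariance of the
instrument workflow is unknown), batch effects, and compartment-specific
missingness beyond the intensity threshold. Passing truth-recovery tests
therefore demonstrates that the statistics are calibrated and sensitive
under this noise model, not that real acquisitions meet its assumptions.

## Validation experiments and problem sizes

The reproduction script and the validation tests run: a 2000-protein
no-shift simulation (null calibration: pooled replicate p-values uniform,
hit count within twice the nominal 5% expectation of the tested universe);
2000 proteins with 100 planted relocalizers at α ∈ {0.5, 0.7, 1.0}
(sensitivity and empirical FDR over the tested universe — proteins that
the data-quality filters remove are a detectability question, not a test
of the statistic); 1500 proteins with 60 planted post-ER→ER movers at
α ∈ {0.7, 0.9}; a 1200-protein steady-state map for marker training and
the F1 benchmark; and 1000-protein full proteomes with 150 planted
abundance changes for the volcano layer. These sizes give stable
percentages at interactive runtimes while exercising every code path.

## Known limitations

- The robust outlier statistic is one member of the family consistent with
  its two published parameters (static proportion, iterations);
  calibration properties, not bit-equality with any particular
  implementation, define its correctness here.
- Single-label classification: dual localization is only expressed through
  the cytosolic-pool secondary annotation.
- The pool-shift test assumes both stressors were measured; proteins
  missing one stressor are tested but cannot become hits.
- The volcano permutation estimate of the FDR has the usual SAM behavior:
  with many strong effects the permuted null is inflated, making the
  threshold conservative.
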