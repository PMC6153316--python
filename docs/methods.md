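# Methods

`toxtempo` analyses dose × time transcriptomics screens of the kind used to
study chemical-induced hepatic steatosis in primary human hepatocytes:
compounds profiled at three dose levels (low/middle/high) plus matched
vehicle controls, at 2, 8 and 24 h, with two replicate arrays per cell, on
the log2 scale of probe-summarised intensities.  This note records the
models, the parameters that matter, the numerical conventions, and what the
synthetic generator does and does not emulate.

## Synthetic study generator

The generator exists so that every stage can be tested against known
ground truth.  The log2 value of gene *g* in sample *s* is

    y[g,s] = baseline[g] + batch[b(s)] + effect[g,s] + ε[g,s]

- **baseline**: N(8, 1.5²) per gene, a rough rendition of RMA log2
  intensities.
- **batch**: one batch per (compound, time) pair — arrays processed
  per experiment — with a scalar shift N(0, batch_sd²) shared by all genes
  on the array.  Because the shift is array-level, concerted quantile
  normalization removes it (up to a grand-mean constant that cancels in
  every contrast); it also cancels exactly between a treated cell and its
  matched control, which share the batch.  Gene-specific batch interactions
  are *not* simulated: within one compound, batch is confounded with time,
  so per-gene batch effects would be indistinguishable from genuine
  temporal signal in the per-compound regressions.
- **effect** (planted truth): for a response gene under a steatotic
  compound, `amplitude · direction · f(t) · g(dose)` with
  `f(t) = u(t)^degree` on unit-scaled time `u = (t − t_min)/(t_max −
  t_min)` (degree 1 or 2 per gene — the most a three-timepoint design can
  support) and `g(dose)` the dose rank mapped to {0, 1/3, 2/3, 1}.  Real
  doses are compound-specific, so a unitless monotone surrogate is used.
  The amplitude equals `effect_size` exactly, making noise-free checks
  sharp.  Compounds planted in the same class share the per-gene direction
  pattern; that sharing is the structure the compound clustering recovers.
- **confounder genes** (disjoint from response genes) are perturbed by
  *both* the negative-control and the steatotic compounds, so the
  negative-control subtraction filter has genuine work to do.
- **gene sets**: GMT-exported random sets, except a configurable fraction
  of *enriched* sets drawn (80%) from a coherent pool of response genes
  whose direction is +1 under every compound class; their mean fold change
  is therefore positive and grows with dose and time.
- **noise**: i.i.d. N(0, noise_sd²).

All randomness flows from one root seed through named substreams
(baseline, effects, membership, batch, noise), so components are
independently reproducible and `seed=k` is bit-stable across runs.

Defaults (chosen once as a realistic desk-scale rendition of such screens):
`noise_sd = 0.25` (residual array noise), `batch_sd = 0.3`,
`effect_size = 2.0` log2 units — a strongly deregulated gene, 8× the noise
sd — at 2000 genes and 8 + 3 compounds.  Counts are configuration, not
constants; full-scale designs (≈20k genes, 28 + 7 compounds) are reachable
through `SimConfig`.

What the generator does **not** emulate: probe-level effects and RMA
summarisation, intensity-dependent variance, correlated gene–gene noise,
compound-specific potency/kinetics, missing cells (real screens often have
compounds with fewer timepoints — those are exercised by truncating the
sample table).  Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under the design, not performance on
any particular real dataset.

## Preprocessing

Quantile normalization maps every array onto the across-array mean of
order statistics; ties receive the mean of the order statistics they span
(average-rank convention), making the transform deterministic and
idempotent.  Replicates are then averaged per (compound, dose, time,
batch) cell on the log2 scale — "average signal" is interpreted on the
log2 scale throughout, consistent with probe-summarised log2 input — and
log2 fold changes are the difference between a treated cell mean and its
matched control cell mean.

## Differential expression

Per gene, the contrast of a treated cell against its matched control is the
two-group linear model y = α + xβ + ε (an OLS t-test; `fit_gene_model`
additionally accepts batch dummies in the design).  With duplicate arrays
a condition-local test has only 2 residual df, so the pipeline default fits
a cell-means model per (gene, compound) — one mean per (dose, time) cell,
batches nested within cells and absorbed — and pools the residual variance
over the compound's cells (df = 12 at the canonical design).
`variance="per_condition"` restores the local test.

Deregulation requires both gates: adjusted p ≤ α (default 0.05) and
linear fold change ≥ 1.5, i.e. |log2FC| ≥ log2 1.5 ≈ 0.585.  Bonferroni is
the default adjustment with Benjamini–Hochberg as an option.  The default
family is *all* tests of the analysis (genes × conditions), so the
family-wise error of the union gene list — "deregulated in at least one
condition" — is controlled at α; `family="condition"` scopes the
correction per condition instead.  Genes meeting the criteria under the
negative-control compounds are removed from the steatotic list (set
difference), and their per-condition flags are cleared so pathway scoring
counts only outcome-specific deregulation.

A note on power: with two replicates per cell, the noncentrality of the
cell contrast is Δ/(σ√(1/2+1/2)) = Δ/σ regardless of variance pooling.  A
gene at Δ = 4σ against a Bonferroni threshold over thousands of tests
(z ≈ 4.2 even for the smallest family) therefore sits *below* the
detection boundary; such genes are reliably recovered only through the
temporal regression, which integrates all 24 samples of a compound.  This
is a property of the design, not of the implementation.

## Temporal selection

Per compound, each gene is regressed on standardized time (centered on the
mean of the distinct times, scaled by their range — conditioning matters
with times spanning 2–24 h), its square, dose dummies with control as
reference, and dose × time interactions; degree 2 and categorical dose are
the defaults (an ordinal encoding would impose linearity in dose rank the
data need not obey).  Stage one: the global F-test of the full model
against intercept-only, BH-corrected per compound (the analysis is
per-compound throughout, so the FDR family is too).  Stage two, applied to
the BH-passing candidates: backward stepwise elimination — repeatedly drop
the non-intercept term with the largest coefficient p-value above 0.05,
ties broken by dropping the higher-order term, then the later column — and
an R² ≥ 0.6 gate on the selected model.  Genes never reaching stage two
carry NaN R² and fail selection; no term hierarchy is enforced, so an
interaction can survive without its main effect.  Compounds whose sampling
cannot support the design (fewer distinct times than degree + 1, e.g. a
single-timepoint compound) are skipped and reported, not errored.  An
exclusion list (one gene per line, e.g. cell-cycle genes) is removed from
the final sets by plain set difference.

## Pathway scoring

PAGE: for one condition with global fold-change mean μ and sample sd σ
(ddof = 1), a set of m measured members with mean Sm scores
z = (Sm − μ)√m/σ, with a two-sided normal p.  Sets are restricted to
measured genes before anything is computed, and K (set size) always refers
to the restricted set.  A seeded gene-randomization permutation p is
available as a check on the parametric p.

GFE: `(k/K) · stat_mean`, where k counts the set's members flagged
deregulated in the condition (after negative-control subtraction) and
`stat_mean` is the set's mean log2 fold change.  The signed mean is the
default statistic so trajectories distinguish up- from down-regulation;
the PAGE z can be substituted (`stat="page_z"`), and outputs are labelled
with the statistic used.  Trajectories order GFE by time within each
(set, group, dose).  Per-compound points satisfy gfe = (k/K)·stat_mean
identically; per-cluster trajectories *average* the member compounds' GFE
at matching (dose, time), and since a mean of products has no single
(k, K, mean) decomposition those pooled rows carry NaN components.

Ranking filters PAGE results at p < 0.05 and orders by |z| with a
deterministic name tie-break.

## Compound clustering

Features are log2 fold changes per (gene, dose, time) slice; the default
slice is 24 h, all doses, restricted to the post-subtraction DEG union —
the late timepoint carries the developed response, and restricting to
deregulated genes keeps the distance from being dominated by noise
dimensions.  Compounds observed at fewer than two timepoints are excluded
up front.  Agglomeration uses Euclidean distances under the Ward.D2
criterion (Lance–Williams update on squared distances, heights on the
distance scale); ties in the merge criterion break on the
lexicographically smallest cluster-id pair, and compounds are canonically
sorted first, so the result is independent of input order and platform.
SER(k), the within-cluster sum of squared distances to centroids of the
k-cut, is computed for k = 1..10, and the chosen k maximises the second
difference SER(k−1) − 2·SER(k) + SER(k+1) — a deterministic reading of the
usual "compromise between k and low SER"; it is overridable by config.
This knee criterion is reliable when cluster separations are comparable
(as with signature-style sign patterns); with one dominant split it will
favour the dominant k, which is the honest reading of the curve.  The
dendrogram is exported as Newick with branch lengths derived from merge
heights.

## Determinism and problem sizes

Every stochastic component is seeded; two runs of the full pipeline with
one config produce byte-identical tables, and the run manifest (config
hash, seed, versions) suffices to reproduce a run.  Tests and the
acceptance script run the stages at reduced but non-trivial sizes chosen to
exercise the statistics honestly — 2000-gene null studies over 50 seeds for
family-wise error, 1000-gene studies over 20 seeds for recovery, 25
compounds in 4 planted classes for clustering — the package's own choice of
desk-scale study conditions.

## Known limitations

- Variance moderation (empirical-Bayes shrinkage) is deliberately absent:
  the deregulation test is a plain OLS t-test by design.
- The normal PAGE p ignores inter-gene correlation; the permutation option
  randomises gene labels, not samples.
- The GFE of a set with no measured members is reported absent, not zero.
- Quantile normalization assumes comparable global distributions across
  arrays; gross distributional pathologies (saturation, degradation) are
  out of scope, as are probe-level preprocessing and array QC.
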