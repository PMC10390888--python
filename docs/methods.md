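# Methods

## The NE score

The score of a sample is `(correl NE − correl non-NE)/2`, each term the
Pearson correlation between the sample's expression over the signature
genes and the signature's NE or non-NE group reference vector (the mean
expression of each gene in a reference NE or non-NE cell-line group).
Both correlations lie in [−1, 1], so the score does too; it inherits
Pearson's invariance under positive affine transforms of the profile and
of either reference vector, and swapping the two reference vectors negates
it exactly. A signature is a required input (the canonical one has 25 NE
and 25 non-NE genes, derived elsewhere from SCLC transcriptomes); any
signature of at least two genes with non-constant reference vectors is
accepted, since the two-gene antithetical case is the score's analytic
extreme and useful for validation.

Missing-data policy: signature genes absent or NaN in a profile are
dropped per sample, so different samples may use different gene subsets;
the count used is reported per sample. Samples with fewer than `min_genes`
usable genes (default 10) or a constant restricted profile are refused
with a diagnostic rather than scored as NaN — a constant profile has no
defined correlation, and silently propagating NaN corrupts downstream
selections. Correlation is Pearson throughout, never Spearman.

## Consistency meta-filter

For each screen feature measured in k datasets, every unordered dataset
pair contributes one Pearson r over cell lines measured in both (pairs
with fewer than `min_shared` = 10 shared lines are excluded but recorded:
correlations on fewer lines are too unstable to mean "consistency"). The
pair correlations are pooled on the Fisher-z scale with inverse-variance
weights 1/(n−3). Two conventions to note:

* a pair correlation of exactly ±1 (a dataset duplicated verbatim) has an
  infinite Fisher z; such values are clipped to ±(1 − 1e−12) before
  pooling, which round-trips to ±1 within float tolerance;
* the same cell line appears in many pairs, so the pair correlations are
  mildly dependent; pooling ignores this (a dependence-aware estimator is
  out of scope) — pooled estimates are honest, p-values slightly
  anti-conservative for large k.

Selection: dependency features at pooled r > 0.4 (strict); drug features
at Benjamini–Hochberg adjusted p < 0.05, adjusted jointly across all
features of the modality. BH is used wherever an adjusted p appears in
this package, and the procedure name is stamped into output provenance.

## Meta-analysis engine

`meta_pool` Fisher-z transforms per-study correlations, pools by inverse
variance (1/(n−3) per study), and back-transforms; the random-effects
model adds the DerSimonian–Laird τ² (floored at 0; defined as 0 for a
single study). 95% CIs and two-sided p-values use the normal
approximation on the z scale. The default model is random effects, since
per-study estimates in multi-cohort panels are visibly heterogeneous;
fixed-effect is available by flag. The engine was cross-checked against
R's `metafor` (`escalc(measure="ZCOR")` + `rma(method="FE"/"DL")`) and
agrees to 7 significant digits on the frozen test fixture; the test suite
carries the hand-computed value so the check runs without R.

Grouped pooling (`meta_by_group`) pools all (feature, study) records of a
group — e.g. all MEK inhibitors across all screens — jointly in one
meta-analysis, the most literal reading of summarizing a
mechanism-of-action class measured by several screens. Records within a
group are treated as independent studies.

`adjusted_association` is ordinary least squares of a gene's expression on
an intercept, the NE score and a 0/1 amplification covariate, refusing
fewer than 10 complete cases, constant covariates, or
|corr(score, amplification)| > 0.999 (the fit would be ill-conditioned and
the coefficients meaningless).

Bulk vs single-cell agreement averages each line's cell scores unweighted
(no quality weighting) and correlates the per-line means with the bulk
scores over lines having both; at least 4 such lines are required for the
correlation to be minimally meaningful.

## Clustering recipes

* expression: keep genes with sample standard deviation (n−1 denominator)
  strictly above 0.4 on the log2 scale, center genes, project samples on
  the top 10 principal components (no unit-variance scaling — the
  sd-based filter is only meaningful on the raw scale), then Ward.
* RPPA/metabolomics: Ward on all available features, unscaled by default
  (`standardize=True` z-scores features first).
* drug/dependency: Ward restricted to a consistency-filtered feature list,
  which the caller must supply — clustering unfiltered screen features is
  deliberately not offered through this recipe.

Ward linkage applies the minimum-variance criterion to Euclidean
distances (the "ward.D2" convention of scipy/R hclust on d²); exact
distance ties are broken by scipy's nearest-neighbor chain order, which is
deterministic given the input order. Partitions are invariant to sample
order in the absence of exact ties. Matrices with missing values are
refused by the core clustering step; the panel recipes drop incomplete
feature rows first.

## Vulnerability screen

Per gene, three Pearson correlations on pairwise-complete shared lines:
RNAi vs CRISPR effect scores, and each effect score vs the gene's own
expression. Selected ⇔ r(RNAi, CRISPR) > 0.4 AND both effect–expression
correlations < −0.4, all strict (the thresholds are configurable; strict
inequality is the documented boundary convention). Effect scores are more
negative for stronger dependency, so anticorrelation with expression means
"expressing lines need the gene". `min_n` defaults to 8: real screens can
contain under ten lines of a lineage of interest, so small n is surfaced
through the reported counts, not refusal. NE selectivity is then the
correlation of a selected gene's effect scores with NE scores; negative
values mark NE-selective dependencies.

## Synthetic panel generator

The generator plants exactly the structure the pipeline assumes, with
defaults chosen as the study conditions for all recovery tests:

* **Latent state.** 60 lines in four lineages (15 each), state drawn from
  a truncated normal on [−1, 1]: SCLC mean 0.6, neuroblastoma 0.5 (the two
  NE-high lineages), lung adenocarcinoma −0.5 and melanoma −0.4. One
  truncated-normal mechanism per lineage; within-line bimodality is
  available through a large single-cell within-line spread rather than a
  separate mixture knob.
* **Expression.** Signature genes load ±1 (`signature_effect`) on the
  state with N(0, 0.5) noise on a log2-like scale with per-gene baselines
  U(2, 8); 30 marker genes per lineage (+2 shift) give each lineage an
  identity beyond the shared NE axis, as real lineages have — without
  them, the two NE-high (and the two NE-low) lineages would be
  indistinguishable by design and lineage-recovery clustering would be
  testing an impossibility; 200 background genes are pure noise. The
  signature's reference vectors are the group means of the top and bottom
  state quartiles, emitted as a SignatureTable.
* **Omic features.** f = ρ·z + √(1−ρ²)·ε against the standardized state
  z; per block (RPPA, metabolites) 10 planted features with |ρ| ∈
  [0.4, 0.7] and 30 nulls.
* **Drug screens.** 4 datasets, each measuring a random 50 of the 60
  lines (pairwise overlaps ≈ 40). A consistent drug has one latent
  profile (optionally correlated with the state through its
  mechanism-of-action class: MEKi −0.4, HSP90i −0.4, BCLi +0.4, misc 0;
  lower value = more sensitive) observed per dataset as
  √rel·latent + √(1−rel)·ε, so the expected interstudy correlation equals
  the reliability (default 0.8). Null drugs are independent noise per
  dataset. Defaults: 20 consistent + 80 null.
* **Dependencies.** 10 selective genes: expression loads λ on the state
  (λ cycled over {0.9, 0.9, 0.9, −0.9, 0, 0} — strongly NE-selective,
  non-NE-selective, and lineage-agnostic cases), essentiality
  = −0.7·expression-component + noise, observed twice (RNAi, CRISPR) at
  reliability 0.8. Expected observed correlations: r(RNAi, CRISPR) = 0.8,
  r(effect, expr) = √0.8·(−0.7) ≈ −0.63, and for λ = 0.9 genes
  r(effect, NE state) ≈ −0.56. 40 null genes are noise throughout.
* **Amplification.** amp ~ Bernoulli(logistic(1.5·state)); the MYCN-like
  gene's expression is 2·amp + 1.5·state + N(0, 0.5) plus a baseline.
* **Single cells.** 30 cells per line; cell state = line state +
  N(0, σ_line) with σ_line ~ U(0.1, 0.4) (line-specific heterogeneity,
  so some lines genuinely mix NE-high and NE-low cells); profiles follow
  the bulk expression model over the signature plus 50 background genes;
  dropout zeroes each entry independently with probability 0.2.

All randomness flows from a single `numpy.random.default_rng(seed)`; equal
configs produce byte-identical panels. What the generator does **not**
emulate: count-level single-cell noise (library size, per-gene
overdispersion, gene-dependent dropout), copy-number segments, batch
effects, or correlated feature blocks within an omic panel. Recovery tests
passing here therefore demonstrate the pipeline's correctness on its own
assumptions, not robustness to those real-data complications.

## Validation conditions and numerical choices

The recovery suite runs at the defaults above with fixed seeds: NE-score
vs state Pearson ≥ 0.9; drug-consistency sensitivity ≥ 0.9 with ≤ 5 false
positives among 80 nulls; random-effects CI coverage ≥ 90% over 100
seed-swept replicates (4 studies of n = 40 at ρ = 0.4); amplification
model coefficients recovered within ±0.3 at n = 100 lines; dependency
screen sensitivity ≥ 0.8 / specificity ≥ 0.95; expression-recipe
clustering adjusted Rand index ≥ 0.7 against planted lineages. The
amplification-recovery check regresses on the latent state itself — the
generative covariate on whose scale the planted coefficients are defined;
the estimated score is validated separately by the ≥ 0.9 recovery bound.
In the noiseless limit the score is a smooth monotone but slightly
nonlinear function of the state (the gene-baseline vector contributes to
both correlations), so "perfect" recovery is asserted as Pearson = 1
within 1e−3, not exact equality.

Ties and degenerate inputs: constant vectors are errors wherever a
correlation is required; |r| = 1 inputs are errors in `meta_pool` (Fisher
z undefined) and clipped only inside the consistency filter as described;
sample alignment keeps the first argument's column order on the
intersection, making self-alignment the identity. Output floats are
serialized at 6 significant digits; TSV with empty-cell missing markers is
the canonical dialect.

## Limitations

Pooled consistency p-values ignore pair dependence (above). The CLI's
`simulate --config` accepts scalar top-level generator fields from
YAML/JSON; nested blocks (lineages, screens) are configured through the
Python API. The generator's dropout is gene-independent, adequate for
score-level tests but not for modeling detection bias. No survival
modeling ships with this package: the meta-analysis engine accepts
precomputed per-study effects from any source, but fitting (e.g. Cox
models) is left to dedicated libraries.
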