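# nehet

Quantitative analysis of neuroendocrine (NE) lineage heterogeneity across
cancer cell-line panels. Small-cell lung cancer and neuroblastoma cells can
occupy an NE or a non-NE ("variant") state, and the balance between the two
shapes molecular profiles, drug response and gene dependencies. `nehet`
implements the full comparative pipeline around a signature-based NE score:

* **NE scoring** — for a sample with expression profile *x* over a signature
  of 25 NE and 25 non-NE genes,

  `NE score = (correl NE − correl non-NE) / 2`

  where `correl NE` (`correl non-NE`) is the Pearson correlation between *x*
  and the signature's NE (non-NE) group reference vector. The score lies in
  [−1, +1]; positive predicts NE, negative non-NE. Works for bulk samples
  and single cells, with per-sample handling of missing signature genes.
* **Cross-dataset consistency filtering** — functional-screen features
  (drug sensitivities, gene effect scores) are noisy; for a feature measured
  in *k* datasets all C(k,2) interstudy Pearson correlations over shared
  lines are pooled by Fisher-z meta-analysis. Dependency features are kept
  at pooled r > 0.4; drug features at BH-adjusted p < 0.05.
* **Association & meta-analysis** — per-feature Pearson correlation with the
  NE score (exact t p-values, Benjamini–Hochberg adjustment), random- or
  fixed-effect Fisher-z pooling across studies (DerSimonian–Laird τ²),
  grouped pooling across compounds sharing a mechanism of action, an
  amplification-adjusted OLS model (expression ~ NE score + MYCN-style
  0/1 amplification), and bulk-vs-single-cell score agreement per line.
* **Panel clustering** — expression: genes with sd > 0.4, top 10 principal
  components, Ward linkage; RPPA/metabolomics: Ward on all features;
  drug/dependency: Ward on consistency-filtered features.
* **Vulnerability prioritization** — genes with RNAi–CRISPR agreement
  r > 0.4 and effect–expression anticorrelation r < −0.4 in both
  modalities, then ranked by NE-score selectivity of their effect scores.
* **Synthetic panel generator** — multi-study panels with a planted latent
  NE state (bulk expression, omic features, overlapping drug screens with
  controlled interstudy reliability, paired RNAi/CRISPR screens,
  amplification flags, per-line single-cell profiles with dropout), so the
  whole pipeline is testable end to end without any download.

Key estimators follow scikit-learn conventions (`NEScorer`,
`ConsistencyFilter`, `PanelClusterer`, `VulnerabilityScreen` with
`fit`/`transform`, `get_params`, fitted `*_` attributes); module-level
functions expose the same operations directly.

## Worked example

```python
import pandas as pd
from scipy import stats
from nehet import GeneratorConfig, generate_panel, score_matrix
from nehet.consistency import consistency_table, select_consistent
from nehet.association import meta_pool

panels = generate_panel(GeneratorConfig(seed=1))
scores = score_matrix(panels.bulk.matrix("expression"), panels.signature)
s = pd.Series(scores.score_map())
truth = pd.Series(panels.truth.state)
print(f"scored {len(s)} cell lines; Pearson(score, latent state) = "
      f"{stats.pearsonr(s[truth.index], truth).statistic:.3f}")
print(scores.to_frame().head(3).round(3).to_string(index=False))

records = consistency_table(panels.drug_datasets, min_shared=10)
selected = select_consistent(records, "drug")
hits = len(set(selected) & set(panels.truth.consistent_drugs))
print(f"consistency filter kept {len(selected)} of 100 drugs "
      f"({hits}/20 planted-consistent recovered)")

m = meta_pool([(0.3, 28), (0.6, 19)], model="random")
print(f"pooled r = {m.pooled_r:.3f}  95% CI [{m.ci_low:.3f}, {m.ci_high:.3f}]  "
      f"tau2 = {m.heterogeneity_tau2:.4f}")
```

prints

```
scored 60 cell lines; Pearson(score, latent state) = 0.991
sample_id  corr_ne  corr_non_ne  score  n_genes_used
 SCLC_L01    0.964        0.780  0.092            50
 SCLC_L02    0.961        0.695  0.133            50
 SCLC_L03    0.935        0.881  0.027            50
consistency filter kept 21 of 100 drugs (20/20 planted-consistent recovered)
pooled r = 0.440  95% CI [0.100, 0.688]  tau2 = 0.0223
```

The 60 synthetic lines span four lineages (two NE-high, two NE-low); the
score reconstructs each line's latent NE state almost perfectly. The
consistency filter recovers all 20 drugs planted with interstudy
reliability 0.8 with one false positive among 80 null drugs. The last line
pools two per-study correlations (r = 0.3 with n = 28 and r = 0.6 with
n = 19) under the DerSimonian–Laird random-effects model.

## Command line

```sh
nehet simulate --seed 1 --out fixtures/
nehet score --expr fixtures/bulk_expression.tsv \
            --signature fixtures/signature.tsv --out scores.tsv
nehet associate --features fixtures/bulk_rppa.tsv --scores scores.tsv \
                --out assoc.tsv
nehet consistency --datasets fixtures/drug_screen_1.tsv \
                  --datasets fixtures/drug_screen_2.tsv \
                  --modality drug --out consistency.tsv
nehet cluster --panel fixtures/bulk_expression.tsv --modality expression \
              --k 4 --out tree.json
nehet select-deps --rnai fixtures/rnai.tsv --crispr fixtures/crispr.tsv \
                  --expr fixtures/bulk_expression.tsv --scores scores.tsv \
                  --out vulns.tsv
nehet meta --records per_study.tsv --group-col group_id --out meta.tsv
```

Matrices are TSV (first column feature/gene id, header row sample ids; CSV
and GCT 1.2 accepted on read); every output gets a `.provenance.json`
sidecar with the tool version and parameters.

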