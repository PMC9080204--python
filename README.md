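# lggpc

Proteogenomic subtyping of diffuse low-grade glioma (LGG) cohorts.

Diffuse LGG splits into three molecular subtypes: **Type I**, IDH-mutant
with whole-arm 1p/19q codeletion (oligodendroglioma); **Type II**,
IDH-mutant 1p/19q-retained (astrocytoma); **Type III**, IDH-wildtype.
Bulk transcriptomes separate these groups sharply — largely because
losing one copy of arms 1p and 19q depresses every transcript on them —
but tandem-mass-tag (TMT) proteomes show the same structure only in
attenuated form. `lggpc` packages the downstream analyses needed to work
with that attenuation:

* **Differential protein abundance (DPA)** between subtypes: per-feature
  Welch t-test on log2 abundance, gated by fold change > 1.5 (strict) and
  Benjamini–Hochberg adjusted p, with a complete-case filter (no
  imputation) beforehand.
* **Chromosome-arm localisation**: per-arm up/down counts of significant
  features and a Fisher exact test for down-regulation enriched on 1p/19q.
* **Combined 1p19q z-score**: per sample, the mean z of 1p∪19q proteins
  against the normal-brain reference, z_fs = (x_fs − μ_f^NB)/σ_f^NB — a
  proteomic dosage readout of codeletion.
* **RNA–protein attenuation**: per-arm OLS of mean protein on mean RNA
  (R² = squared Pearson r), quantifying how much transcript dosage signal
  survives to protein.
* **Marker panel by directional concordance**: a protein becomes a
  subtype marker when ≥ 2 of the three pairwise contrasts place that
  subtype at the same extreme (two selection rules ship; see
  `docs/methods.md`).
* **Subtype classifier**: ridge-penalised multinomial logistic regression
  on the panel, stratified 10-fold cross-validation, pooled out-of-fold
  probabilities, one-vs-rest ROC and one-vs-one AUC per subtype pair.
* **A synthetic cohort generator** that reproduces the statistical shape
  of such a study (6 normal brain + 21/17/10 tumour samples, ~6000
  proteins, planted dosage attenuation, planted markers, tunable
  RNA–protein decoupling) with full ground truth, so every stage is
  testable without downloads.

## Worked example

```python
import numpy as np
from lggpc import (SimulationParams, simulate_cohort, de_test, localize_de,
                   combined_zscore, select_markers, summarize_panel,
                   cross_validate, arm_rna_protein_regression, TUMOUR_SUBTYPES)

protein, rna, samples, arms, truth = simulate_cohort(SimulationParams(seed=42))

r12 = de_test(protein, samples, "TYPE_I", "TYPE_II")
r13 = de_test(protein, samples, "TYPE_I", "TYPE_III")
r23 = de_test(protein, samples, "TYPE_II", "TYPE_III")
print(r12.n_significant, r13.n_significant, r23.n_significant)
# 130 65 40

print(localize_de(r12, arms).table.round(4))
#            n_up  n_down  down_fraction  fisher_odds_ratio  fisher_p
# arm_label
# 1p            0      24            1.0                inf    0.0001
# 1q            1       1            0.5             0.4382    0.5224
# 19p           0       0            NaN                NaN    1.0000
# 19q           0      26            1.0                inf    0.0000
# other        39      39            0.5             0.0196    0.0000

scores = combined_zscore(protein, samples, arms)
by = {s.sample_id: s.z_combined for s in scores}
for g in ("NORMAL", "TYPE_I", "TYPE_II", "TYPE_III"):
    print(g, round(float(np.mean([by[s] for s in samples.samples_of(g)])), 3))
# NORMAL 0.0, TYPE_I -0.692, TYPE_II 0.056, TYPE_III 0.073

panel = select_markers(r12, r13, r23)          # rule="any_two" by default
print(summarize_panel(panel))
#           n_up  n_down  n_total
# TYPE_I       8      17       25
# TYPE_II     11       9       20
# TYPE_III    10       5       15

ids = [s for g in TUMOUR_SUBTYPES for s in samples.samples_of(g)]
X = protein.data.loc[panel.feature_ids, ids].to_numpy().T
rep = cross_validate(X, samples.labels_for(ids), cv_folds=10,
                     ridge_lambda=1.0, seed=42)
print(rep.auc_pairwise)
# {('TYPE_I','TYPE_II'): 1.0, ('TYPE_I','TYPE_III'): 1.0, ('TYPE_II','TYPE_III'): 1.0}

print({r.arm_label: round(r.r_squared, 3)
       for r in arm_rna_protein_regression(rna, protein, samples, arms, "TYPE_I")})
# {'1p': 0.177, '1q': 0.194, '19p': 0.228, '19q': 0.212}
```

Reading the output: the significant-protein counts are modest (the
proteome is the attenuated view); down-calls pile onto 1p and 19q only in
the Type I contrast (Fisher p < 1e-3) — the codeletion signature; the
Type I group mean z-score sits ~0.7 reference SDs below normal brain
while the other subtypes sit near 0; the concordance panel recovers the
planted markers plus dosage-driven Type I down-markers; the planted
effects make all three subtype pairs fully separable (AUC 1.0 here —
real cohorts land lower); and per-arm RNA–protein R² ≈ 0.2 is the
attenuated coupling regime the generator is calibrated to.

## Command line

The same pipeline is scriptable as `lggpc`:

```bash
lggpc simulate --out sim/ --seed 42
lggpc run-all --protein sim/protein.tsv --samples sim/samples.csv \
      --arms sim/arms.tsv --rna sim/rna.tsv --seed 42 --out results/
```

`run-all` chains filter → de (3 contrasts) → arms → codel → panel →
classify → cluster, writes one TSV/JSON per stage plus `report.json`, and
is deterministic given the seed. Individual stages are available as
`filter`, `de`, `arms`, `codel`, `panel`, `classify`, `cluster`. Exit
codes: 0 success, 2 config error, 3 data error, 4 stage failure.

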