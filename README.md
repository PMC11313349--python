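# thermoshift

Sequence-based prediction of how a single missense mutation changes a
protein's melting temperature, with environmental covariates.

## The problem

A protein's thermostability is summarized by its melting temperature
Tm (°C), the midpoint of thermal unfolding.  A single amino-acid
substitution shifts it by ΔTm = Tm(mutant) − Tm(wild type).
Predicting ΔTm from sequence alone matters wherever structures are
unavailable — enzyme engineering, biopharmaceutical formulation,
interpretation of stability screens.  Crucially, ΔTm is not a function
of the sequence alone: the same mutation in the same protein yields
different ΔTm at different pH and different starting Tm, so a
predictor that ignores measurement conditions is fitting an average of
incompatible quantities.

`thermoshift` implements this prediction pipeline end to end:

1. **Curation** — per-source mutation tables are cleaned (unparseable
   mutations, missing labels, wild-residue mismatches, duplicates) and
   merged, then materialized into three dataset variants: *common*
   (conditions discarded, replicate ΔTm averaged per variant key),
   *tm* (wild-type Tm kept), *ph_tm* (pH and Tm kept).
2. **Feature extraction** — per record: AAindex property differences
   and pair-matrix lookups; residue frequencies in a 25-residue window
   around the site (20 columns); a 6×6 physicochemical group-transition
   one-hot (36); a PSSM partitioned into 20 sections with per-column
   means (400); seven whole-protein quantities (length, molecular
   weight, pI, atom count, extinction coefficient, instability index,
   aliphatic index); SIFT deleteriousness annotations (3);
   amino-acid-scale differences (57 in the default bundle); plus the
   variant's pH/Tm covariates.  A pluggable embedder backend adds
   pooled embedding vectors of the wild-type and mutant context window
   around the site (a deterministic mock backend ships with the
   package; protein-language-model backends plug into the same
   contract).
3. **Modeling** — recursive feature elimination (optionally with
   cross-validated choice of the retained count) over gradient-boosted
   regressors (LightGBM default, XGBoost supported), evaluated by
   MAE, RMSE, R² = 1 − SSres/SStot, and the Pearson correlation
   coefficient.

A synthetic-data generator produces datasets with the same statistical
structure (labels are a known sparse function of computable features
plus Gaussian noise), so the entire pipeline is exercisable and
testable without any external download.

## Worked example

Generate an environment-dependent synthetic dataset, build the
`ph_tm` design, select 20 features by RFE and cross-validate:

```python
from thermoshift import DeltaTmModel, SyntheticSpec, generate
from thermoshift.experiments import variant_design

spec = SyntheticSpec(n_proteins=40, seed=7)      # env-dependent labels
dataset = generate(spec)
table, y, groups = variant_design(dataset, "ph_tm")

model = DeltaTmModel(table, y, variant="ph_tm")
res = model.fit(selection="rfe", n_features=20, seed=7)
res.cross_validate(folds=10)
print(res.summary())
```

```
dTm regression results
==========================================================
algorithm               lightgbm
dataset variant         ph_tm
n observations          1256
n features (selected)   20 / 115
selection               rfe
seed                    7
config hash             9535af6bfcecf33d
----------------------------------------------------------
                    MAE     RMSE       R2      PCC
training          0.902    1.148    0.944    0.972
CV (pooled)       1.808    2.290    0.776    0.882
==========================================================
```

The pooled 10-fold cross-validated MAE of 1.81 °C sits just above the
2 °C noise floor the generator injected, and `res.feature_importances`
ranks exactly the planted signal carriers first — wild-type Tm, the
Kyte–Doolittle hydropathy difference and pH:

```
tm                                 67998.0
scale_hydropathy_kyte_doolittle    45654.2
ph                                  9318.6
```

The same workflow is available from the shell:

```sh
thermoshift simulate --out data/sim --preset env --seed 7
thermoshift curate   --fasta data/sim/proteins.fasta \
                     --mutations data/sim/mutations.tsv --out data/cur
thermoshift extract  --fasta data/sim/proteins.fasta \
                     --mutations data/cur/ph_tm.tsv --variant ph_tm \
                     --out data/features.tsv
thermoshift select   --features data/features.tsv --n-target 20 --out data/sel.json
thermoshift train    --features data/features.tsv --selection data/sel.json \
                     --variant ph_tm --out data/model.bundle
thermoshift evaluate --features data/features.tsv --out data/cv.json
thermoshift predict  --features data/features.tsv --model data/model.bundle \
                     --out data/predictions.tsv
```

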