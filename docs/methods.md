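# Methods

## Model

The target is ΔTm = Tm(mutant) − Tm(wild type) in °C for a single
missense mutation, treated as a tabular regression problem: a record
(protein sequence, substitution, optional pH and wild-type Tm) is
mapped to a named numeric feature vector and a gradient-boosted tree
ensemble is fitted to observed ΔTm.  Assumptions worth making
explicit:

- **Sequence-only.**  No structural input is used; all per-record
  information derives from the sequence, the substitution, precomputed
  homology artifacts (PSSM, SIFT scores) consumed from files, and the
  measurement conditions.
- **Conditions are covariates, not noise.**  The same variant measured
  at different pH/Tm legitimately has different ΔTm.  The three
  dataset variants encode three modeling stances: `common` averages
  replicate ΔTm per (protein, mutation) key and discards conditions;
  `tm` keeps wild-type Tm; `ph_tm` keeps both pH and Tm as features.
- **Missense only.**  Insertions, deletions and multi-residue changes
  are out of scope; mutation strings are `<wild><1-based position><mutant>`
  over the 20 canonical residues.  Sequences containing nonstandard
  letters (X, B, Z, U, O) are rejected with a logged warning rather
  than imputed, because every property lookup downstream assumes the
  canonical alphabet.

## Feature families

| family | columns | definition |
|---|---|---|
| AAindex | one per retained entry | kind 1: value(mutant) − value(wild); kinds 2/3: matrix cell [wild, mutant] |
| neighborhood | 20 | residue frequencies in the 25-residue window (site ± 12, clipped at termini, denominators = clipped size) |
| grouping | 36 | one-hot over 6×6 group transitions (hydrophobic V I L F M W Y C; negative D E; positive R K H; conformational G P; polar N Q S; other A T) |
| PSSM | 400 | positions partitioned into 20 contiguous near-equal sections (first L mod 20 sections get ⌈L/20⌉ rows); per section, mean of each of the 20 score columns |
| physicochemical | 7 | length, average molecular weight, theoretical pI, total atoms, molar extinction at 280 nm (Trp/Tyr/cystine), instability index, aliphatic index |
| SIFT | 3 | score, conservation median, aligned-sequence count |
| scales | 57 (default bundle) | scale(mutant) − scale(wild) per amino-acid scale |
| conditions | 0–2 | pH and/or wild-type Tm, per variant |

AAindex kind-1 entries with any missing value are dropped at load (the
standard elimination rule); matrix entries keep NaN cells and are only
rejected per record when a queried cell is NaN.  Mutation-difference
features (AAindex kind 1, scales) are antisymmetric under wild↔mutant
swap by construction.

Whole-protein quantities delegate to Biopython's ProtParam
implementation (average masses, Bjellqvist pI bisection, Guruprasad
instability matrix, W/Y/cystine extinction).  Total atom count (free
amino-acid formulas minus one three-atom water per peptide bond) and
the aliphatic index (X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu), mole
percent) are computed in-package.

The default scale bundle contains 14 published scales transcribed from
the literature (Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity,
Eisenberg / Fauchère–Pliska / Janin hydrophobicities, Rose buried
area, Grantham and Zimmerman polarity, Zimmerman bulkiness and pI,
residue mass, codon count, Chou–Fasman helix/sheet/turn propensities)
plus 43 deterministic synthetic stand-in scales (`synthetic_*`) that
fill the 57-slot default layout; real deployments should point the
loader at a full published scale export.  The bundled AAindex kind-2/3
fixtures are likewise synthetic matrices (so parsing, symmetrization
and NA policy are testable without redistributing the database).

**Missing resources.**  Per-extractor policy, explicit in the
configuration: records lacking a PSSM are dropped (default) or given a
substitution-matrix fallback PSSM (row i = BLOSUM62 row of residue i,
flagged `fallback` in provenance); records lacking SIFT scores are
dropped (default) or imputed with declared neutral values (score 1.0,
median 3.0, 0 sequences).  Nothing is imputed silently; feature tables
never contain NaN.

## Embedding context features

A context window of 25/50/100/200/500 residues (or the full sequence)
is centered on the mutation site; near a terminus it is shifted toward
the interior rather than padded, so the window always has full length
and contains the site.  Proteins shorter than the window are excluded
(reason `too_short`).  Wild-type and mutant subsequences over the same
coordinates are embedded by a backend implementing
`embed(sequence) -> (positions × embedding_length)` and pooled:

- `per_position` (default for fixed windows): mean over the embedding
  dimension → vector of length = context length;
- `per_dimension` (used automatically for full-length windows, whose
  position count varies between proteins): mean over positions →
  vector of length = embedding length.

The two pooled vectors are concatenated (default; 2k columns) or
differenced (k columns).  The bundled mock backend is a seeded
per-residue lookup table (default dimension 32): deterministic,
context-free, and therefore exactly localizable — with `diff`
combination only the mutated offset is nonzero, which the tests
exploit.  Real protein-language-model backends plug into the same
contract; any special tokens they emit must be stripped so matrix rows
align 1:1 with residues.  The test suite never requires model weights.

## Selection and regression

Recursive feature elimination refits the regressor and drops the 5%
of remaining features with the lowest gain importance per iteration
(at least one; never overshooting the target, so the final approach is
by single steps; ties break by column order).  RFECV computes the
elimination path down to the minimum count once, scores every visited
count by 5-fold CV MAE on the corresponding subset, and keeps the
count with the lowest CV MAE (ties → fewer features).

Both regressor families run with library default hyperparameters (only
seed, single-threading and verbosity pinned).  LightGBM is the package
default: in design benchmarks it was faster single-threaded, less
prone to fitting pure noise and closer to the ceiling on noiseless
signal than XGBoost defaults; XGBoost is selectable everywhere.

Cross-validation reports pooled out-of-fold metrics and per-fold
metrics with their mean.  Folds shuffle at record level by default; a
grouped mode keeps all rows of one group (protein, or variant key) in
a single fold.  Metrics on constant vectors (R², PCC) are reported as
NaN with a flag, excluded from fold means — never coerced to 0.  All
randomness (fold shuffles, estimator seeds) derives from one run seed
recorded in the model bundle.

## Synthetic data

The generator emulates a curated thermostability table: sequences
i.i.d. uniform over the 20 residues (defaults: 200 proteins, 60–250
residues), 10 substitutions per protein sampled uniformly with
mutant ≠ wild, and 1–5 measurement conditions per variant taken as
consecutive points on a pH 2–9 grid in 0.5 steps, with wild-type Tm
increasing in pH (slope 2–4 °C per pH unit around a per-protein
midpoint in 45–85 °C) — mirroring the granularity of published
replicate-condition series.  Labels are

    ΔTm = Σ_j w_j · f_j(record) + ε,    ε ~ N(0, sd²),  sd = 2 °C default,

with effect features restricted to quantities the extractors also
compute: Kyte–Doolittle hydropathy difference, side-chain charge
change, hydrophobic fraction of the 25-residue window, centered pH,
centered Tm, and a pH×Tm interaction.  The environment-dependent
preset weights are (−0.6, +1.2, +3.0, +1.0/pH unit, −0.25/°C, +0.02);
the 2 °C noise floor and these effect sizes give per-dataset signal
standard deviations of a few °C, comparable to the spread of measured
ΔTm tables.  A sequence-only preset zeroes the condition weights; a
null preset zeroes everything (pure noise).  Noise streams are keyed
by (seed, protein, mutation, condition), so label generation is
invariant to record order and byte-identical under one seed.  The
truth manifest records weights, per-record noiseless labels and the
seed.

What the generator does **not** emulate: realistic sequence
composition or conservation, structure-mediated stability physics,
heteroscedastic measurement error, or correlated effects between
neighboring sites.  Passing tests therefore demonstrate that the
pipeline recovers a known computable signal under realistic dataset
mechanics — not that it attains literature-level accuracy on real
proteins, which requires the real curated databases and a real
protein-language-model backend.

## Validation experiments

Problem sizes were chosen so the whole suite runs in minutes on one
CPU: ~2000 condition rows per dataset (67 proteins × 10 variants × 1–5
conditions), 20 replicate datasets where replication is reported,
10-fold CV, and the fast deterministic feature set (scales, group
transitions, neighborhood frequencies, conditions) for the benchmark
designs.

- **Metric correctness** — MAE/RMSE/R²/PCC agree with brute-force
  formula transcriptions to 1e−10 over 1000 random pairs, and with
  scipy/scikit-learn implementations; R² goes negative when
  predictions are worse than the observed mean.
- **Environment ordering** — on environment-dependent data, mean
  pooled CV MAE orders ph_tm ≤ tm ≤ common, with ph_tm beating common
  by a wide relative margin (~0.4 observed): conditioning on pH and Tm
  removes variance that the common variant's averaging cannot.
- **Selection recovery** — RFE at the true support size recovers the
  5 informative of 50 columns (observed recovery 1.0 over 20
  replicates); RFECV's chosen count is never below the true support.
- **Learnability** — noiseless labels yield CV R² ≥ 0.95; pure-noise
  labels yield mean CV R² within ±0.15 of zero.  These two checks use
  folds grouped by (protein, mutation) key: replicate condition rows
  of one variant are near-duplicate feature rows, and with row-level
  folds a booster can memorize a training replica's independent noise
  label for its test replica — the statistic would then measure
  duplication leakage rather than learnability.  Keyed grouping is the
  same device the curation split uses to prevent condition-level
  leakage.

## Numerical choices and edge cases

- Canonical per-residue column order is the PSI-BLAST ASCII order
  `ARNDCQEGHILKMFPSTWYV` everywhere a 20-vector appears.
- Duplicate collapsing compares pH and Tm at one decimal place (the
  printed precision of source tables); cross-source duplicates average
  ΔTm and concatenate source tags.
- The `common` label aggregate is the arithmetic mean over conditions
  (median available as an option).
- Train/test splits and grouped CV operate on (protein, mutation)
  keys, so replicate conditions never straddle a split.
- Sequences shorter than 20 residues cannot be PSSM-sectioned and are
  dropped with reason `sequence_too_short`; proteins shorter than the
  context length are excluded from embedding features (`too_short`).
- Prediction aligns columns by name; a `ph_tm` model tolerates a
  missing pH column by injecting the neutral default 7.0 with a
  warning; any other missing column is an error listing all absentees.
- Constant training labels produce constant predictions; empty tables
  and non-finite labels are rejected.

## Known limitations

- The bundled scale set and AAindex matrices are partly synthetic
  stand-ins (clearly labelled); results on real data require the real
  resources.
- The mock embedder carries residue-identity information only; it
  cannot express context dependence, so embedding features add little
  beyond substitution identity until a real backend is plugged in.
- PSI-BLAST and SIFT4G are consumed from files, never executed; the
  fallback PSSM is a homology-free approximation and is flagged as
  such in provenance.
- Default hyperparameters are deliberate (matching the upstream
  protocol of evaluating both boosting libraries untuned); no
  hyperparameter search is provided.
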