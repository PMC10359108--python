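# Methods

This note documents the models, conventions and design choices behind
`synpair`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the desk-scale experiments do and do not show.

## Problem setting

Drug-combination screens report, per (drug1, drug2, cell line) triple, a
synergy score (ZIP or S_mean) quantifying deviation from a
non-interaction reference, plus each drug's single-agent response
(relative inhibition, RI — the normalized area under the log-dose
response curve). Screens are sparse and contain inconsistent replicates.
The package treats scores and RI as given labels (it does not compute
them from dose–response surfaces) and addresses transductive imputation:
all drugs and cell lines are seen in training; unmeasured triples are
predicted.

## Preprocessing pipeline (`synpair.data`)

1. **Gene filtering.** A gene is removed if strictly more than 75% of
   cell lines have expression below 1 (log2(RPKM+1) units), then — among
   survivors — if its across-CCL variance is strictly below 0.8. Ties are
   retained; boundary semantics follow the wording "more than" / "smaller
   than". The filter is order-stable and idempotent.
2. **Z-scoring.** Each gene is standardized over all CCLs present in the
   matrix (transductive; a per-fold refit is possible by re-running the
   pipeline per training fold, but is not the default since all cell
   lines are seen during training by construction of the task).
3. **Signature consensus.** Replicate drug signatures (per signature cell
   line) are averaged element-wise; per-drug features concatenate the
   consensus signatures in a fixed signature-cell-line order.
4. **Replicate-consistency filter.** Synergy measurement groups —
   keyed by (unordered pair, CCL, score type) — are kept iff (a) the
   majority sign covers ≥ 60% of replicates and (b) the replicate
   standard deviation is ≤ 0.1. The kept group's consensus score and RI
   values are replicate medians. Score types are filtered independently.
5. **Assembly and augmentation.** Samples present in all three sources
   become triples `x = [drug1 | drug2 | ccl]` with targets
   (synergy, RI1, RI2); records failing the intersection are counted,
   not silently dropped. Every sample then gains an order-swapped mirror
   (drug blocks swapped, RI targets swapped, synergy unchanged).

Numerical conventions, chosen where the procedure leaves them open and
exposed in `FilterConfig`:

- **Variance/SD convention**: sample (`ddof=1`) throughout, the default
  of mainstream statistics stacks. Singleton replicate groups get SD 0 —
  one measurement carries no inconsistency evidence.
- **Zero scores** count toward the non-negative class in the sign rule;
  a zero is not evidence of antagonism.
- **Canonical pair key** is the lexicographically sorted id pair; records
  are re-oriented to canonical order (swapping RI1/RI2) before grouping,
  so replicates reported in either drug order are pooled correctly.
- The replicate-SD gate of 0.1 is strict on raw synergy scales; it is a
  configuration value, not a constant.
- Missing values in input matrices are rejected rather than imputed.

## Model (`synpair.model`, `synpair.nn`)

The default architecture is described in the README. The network engine
is a compact numpy implementation of dense stacks (affine → activation →
inverted dropout), explicit backpropagation, and Adam/Adamax with bias
correction. Choices that the architecture description leaves open:

- **Loss weighting**: plain mean of squared errors over all task outputs
  (equal weights). With a width-3 output this weights synergy and both RI
  tasks equally.
- **Early stopping**: MSE monitored on a 10% carve-out of the training
  data, patience 10 epochs, best-epoch weights restored. Configurable.
- **Initialization**: uniform fan-in, `U(±1/√fan_in)` for weights and
  biases, fully seeded. Two runs with the same seed and data produce
  identical histories (single-threaded numpy arithmetic is
  deterministic per call sequence).
- **Batching**: samples are reshuffled every epoch from the run seed; a
  sample and its mirror are not forced into the same batch (both orders
  are in the training set already).
- **Learning rate 0** is permitted as a null update for diagnostics.
- Dropout uses inverted scaling, so prediction-time passes are
  deterministic and bit-reproducible.

**Ablation variants** (`make_ablation_spec`) rearrange the encoder set
(triple only; CCL+pair; CCL+triple; per-drug encoders with CCL, triple
or pair; single-task predictor). Hidden widths for encoders without a
stated reference width default to (1024, 2048) for CCL and per-drug
encoders; the two re-sized triple-only variants default to (3072, 4096)
and (2048, 4096, 2048, 4096). All widths are configurable per spec, so
exact alternative widths can be dropped in.

**Symmetric inference**: imputation predicts both drug orders and
averages the synergy outputs, making the prediction exactly invariant to
drug order even though the trained network is not hard-constrained to be.

**Estimator interface**: `SynergyRegressor` is a scikit-learn
estimator (`fit`/`predict`/`get_params`, clonable), so model selection
utilities and the package's own cross-validation treat it and any
baseline regressor uniformly.

## Evaluation (`synpair.evaluation`)

- **Splitters** deal grouping units (unordered (pair, CCL) triples, or
  unordered pairs) round-robin into k folds after a seeded shuffle; fold
  sizes differ by at most one unit, no stratification. In
  leave-triple-out a sample and its mirror share a fold (otherwise
  near-duplicates leak across the split and inflate metrics). In
  leave-pair-out, only identical pairs are grouped — two pairs sharing a
  single drug may split across folds, matching the stated definition of
  the split.
- **Metrics**: RMSE, Pearson, Spearman (average ranks on ties) on the
  synergy task; constant vectors yield NaN correlations with a warning.
- **Binarization**: scores > +t are synergistic, < −t antagonistic, the
  closed band [−t, +t] is discarded as low-confidence (at t = 0 exactly
  the zeros are discarded). AUROC uses the rank (Mann–Whitney)
  formulation and is computed per fold, aggregated mean ± SD like the
  regression metrics.
- **Grid search** enumerates the 576-point grid: learning rate
  (0.01/0.001/0.0001) × optimizer (Adam/Adamax) × input activation
  (linear/ReLU) × batch size (64/128) × dropout (on/off) × 12
  width/depth presets (width scale 0.5/1/2 × encoder depth 2/3 ×
  predictor depth 2/3 — the preset axis is this package's
  parameterization of the width/depth options). Each combination is
  scored on one grouped held-out split by default (full CV behind a
  flag); runs with non-finite losses are flagged non-converged and
  excluded from the ranking rather than erroring out.

## Discovery (`synpair.discovery`)

Candidate enumeration takes drugs appearing in at least a fraction
(default 10%) of the measured distinct pairs, forms all unordered pairs ×
cell lines, and subtracts measured triples. The pan-CCL screen keeps
pairs whose *minimum* imputed score across all cell lines is strictly
above a threshold (default 2). Tissue-specific ranking keeps pairs that
are nowhere antagonistic within the tissue (minimum within-tissue score
strictly > 0), ranks by mean(within) − mean(outside), and attaches a
one-sided Mann–Whitney U p-value (within greater) — exact null
distribution when both groups have ≤ 8 tie-free observations, otherwise
the normal approximation with continuity and tie correction — with
Benjamini–Hochberg adjustment across exactly the ranked family.

## Synthetic worlds (`synpair.synthetic`)

Ground truth is a symmetric bilinear-plus-additive function of latent
drug factors f(·) and CCL factors g(·) (standard normal, 8 dimensions by
default), rescaled once per world so scores have SD ≈ 10 and span
roughly [−30, 30] — the magnitude range of the binarization threshold
grid. RI truth is an affine function of a drug–CCL interaction with
center 50 and SD ≈ 15 (a 0–100-like scale). Observables:

- **Expression**: 60% informative genes (affine in g(c), positive scale),
  25% lowly expressed, 15% expressed-but-flat, so both gene filters have
  nontrivial work; values are non-negative like log2(RPKM+1) data.
- **Signatures**: linear images of f(d) per signature cell line with
  replicate noise (SD 0.05), 1–3 replicates.
- **Measurements**: 1–4 replicates of truth + N(0, noise_sd) per sampled
  triple; a configured fraction of groups is corrupted — sign flips on
  about half the replicates, or spread inflation (SD 2.0) — and always
  receives ≥ 2 replicates, because a singleton group cannot violate
  either consistency rule. Corrupted groups are rejected by the filters
  at ≥ 95% under the default settings; drug order within records is
  randomized to exercise canonicalization.

Defaults (200 genes, 12 CCLs, 30 drugs, 50 landmark genes, noise SD 1.0,
10% inconsistent) exercise the filters realistically: with noise SD 1.0
the strict 0.1 replicate-SD gate rejects most multi-replicate groups,
which mirrors how strict that gate is on raw synergy scales. The
*learnability study* configuration (`learnability_config`) instead uses
noise SD 0.05 — below the gate, so consistent groups survive — and 40
drugs × 15 CCLs so the pipeline yields the 4,000 samples the study
trains on.

What passing on synthetic data shows — and does not: the generator's
synergy function is smooth and low-rank in well-encoded latents, with
modest noise; recovery (held-out PCC ≥ 0.8 for the width/8 model)
demonstrates that the architecture, pipeline, splitters and training
loop are wired correctly and can learn a symmetric interaction function.
It does not demonstrate performance on real transcriptomic data, whose
covariance structure, batch effects and label noise the generator does
not emulate.

Two desk-scale observations worth recording:

- The label-shuffled null model converges to near-constant predictions;
  its held-out PCC is then dominated by random-projection noise of order
  1/√(latent dimension) (≈ ±0.2), not by predictive skill. The seeded
  study reports 0.186.
- On this synthetic task the single-task variant reaches a *lower*
  synergy MSE than the multitask model. With equal-weight MSE and RI
  targets on a much larger numeric scale (≈ 50 ± 15 vs synergy ≈ 0 ± 10),
  the auxiliary tasks dominate the loss at desk scale. Both values are
  reported side by side; the multitask benefit claimed for the full-scale
  task is not expected to reproduce under these conditions.

## Scale of the bundled experiments

The bundled studies are sized for a single CPU: the learnability study
trains the width/8 model (~0.7M parameters at synthetic input sizes) on
3,200 samples for up to 120 epochs; grid-search demonstrations evaluate
a handful of combinations with a reduced epoch budget. Full-width
training on real corpora (61M parameters, ~86k samples) uses the same
code paths but is out of scope here, as are: computing ZIP/S_mean/RI
from raw dose–response data, chemical fingerprint generation from
structures, probe-to-gene mapping, and batch correction.

## Known limitations

- The numpy engine is single-device and unoptimized relative to a GPU
  framework; it exists for dependency-free correctness, not speed.
- Checkpoints store the exact weights but reconstruct optimizer state
  afresh; resuming training restarts the optimizer.
- The replicate-SD gate interacts with measurement noise scale; users
  filtering raw-scale scores should revisit `max_replicate_std`.
- Leave-pair-out groups identical pairs only; generalization to pairs
  sharing one drug with training pairs is easier than to fully novel
  chemistry, and the splitter does not control for that.
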