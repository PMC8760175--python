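# Methods

## Problem and model

`aievote` treats AIE-vs-ACQ prediction as binary molecular classification
with AIE (the minority class) positive. The pipeline has four stages:
featurization, optional multi-modal fusion, per-voter tuning, and
majority-vote ensembling, all evaluated under nested cross-validation.

### Feature modes

Four hashed binary fingerprints, all folded to 2048 bits so modes are
directly comparable in width:

| mode | generator | parameters (default) |
|---|---|---|
| `morgan` | RDKit Morgan generator | radius 2 (ECFP4-equivalent) |
| `daylight_path` | RDKit path fingerprint | bond paths 1–7 |
| `atom_pair` | RDKit atom-pair generator | folded to 2048 bits |
| `torsion` | RDKit topological torsion | 4 heavy atoms per torsion |

The Morgan radius is not fixed by the reference protocol; 2 is the field's
default and is configurable. "Daylight" fingerprints are proprietary; the
hashed linear-path fingerprint is the standard openly available stand-in
and is what the RDKit path generator explicitly emulates. Fingerprints are
presence/absence bits (no counts) stored dense — 2048 columns is small.

The `quantitative` mode is a 108-vector of RDKit descriptors: 20
composition-level (masses, electron/heteroatom/H-bond tallies, rotatable
bonds, simple group counts) and 88 graph-level (chi/kappa connectivity,
Balaban J, Bertz CT, TPSA/LabuteASA/logP/MR, ring-system census, E-state
extrema, the SlogP/SMR/EState-VSA partitions, Morgan bit densities). The
exact membership is a package choice (`aievote.descriptors`), curated to
exclude families that return NaN on ordinary organics (partial-charge
extrema, BCUT2D) or overflow (Ipc); any ordered RDKit descriptor list can
be substituted via configuration. Descriptor failures are hard errors
naming descriptor and record — never silently imputed.

### Fusion (multi-modal features)

For a fingerprint block X (n × 2048): PCA with k = min(n, p) components
(scikit-learn, full SVD solver). At full rank the projection is a rotation
of the centered data: explained-variance ratios sum to 1 (machine
precision; asserted at 1e-9), pairwise distances are preserved, and the
training reconstruction error is < 1e-8 relative. The quantitative block
is z-scored per column with training statistics (population σ); a constant
column maps to 0 rather than NaN, keeping the width fixed at k + 108.

Fit scope: by default fusion statistics are fitted **once on the full
dataset before cross-validation** — this is the only reading under which a
2048-bit block on 356 molecules yields exactly 356 PCA dimensions and a
464-wide fused vector. It leaks unsupervised statistics (not labels)
across folds; a `fold_safe` switch refits fusion inside every outer
training fold for a leakage-free protocol. Both scopes are recorded in the
run manifest. For new molecules the fused width is fixed by the fitted
model, never by the batch.

### Classifier families and grids

Learners are scikit-learn estimators; this package owns only the grids,
the selection loop and the uniform voting interface. Search grids
(`full` preset): LR regularization C, 7 log-spaced points over 1e-3…1e3;
KNN neighbors {3,5,7,9,11,13,15,17,18} (the even 18 kept verbatim),
Euclidean, uniform weights; GB min-samples split/leaf {0.1…0.5} (step
0.1), depth {3,5,7}, subsample {0.5,0.75,0.95}; RF min-samples split
{2,4} × estimators {10,50,100,200,500}; MLP initial learning rate 5
log-spaced points over 1e-5…1e-1, α {1e-5,1e-4,1e-3}. Where the protocol
gives a range without a point count, the discretization above is the
package's choice.

Fixed, unsearched settings (documented in every manifest): LR liblinear
solver, max_iter 5000; GB learning rate 0.1 with 50 trees; MLP one hidden
layer of 100 units, adam, max_iter 300, no early stopping; RF/GB split
criteria at library defaults.

Tuning: exhaustive search over the grid's Cartesian product in declared
order, scored by mean stratified inner 5-fold accuracy (configurable to
F1), ties kept by the earliest grid point for reproducibility, winner
refitted on the whole training split. Hyperparameters are re-tuned inside
every outer fold. The search loop is hand-written rather than
`GridSearchCV` to pin the tie-break order.

A `reduced` preset caps every hyperparameter at two candidates (LR C
{0.1, 10}; KNN k {5, 11}; GB depth {3, 5} with split 0.2/leaf 0.1/
subsample 0.95; RF estimators {50, 100}; MLP learning rate {1e-3, 1e-2})
for desk-scale runs; which preset ran is always in the manifest.

### Ensemble

One voter per (family, mode): 5 × 5 = 25 single-modal, 5 × 4 = 20
multi-modal. Voting is over hard labels; the majority wins. The AIE vote
fraction is used as the ensemble score for ROC/AUC — hard votes have no
native score, and the vote fraction is the canonical soft surrogate; this
is an interpretation, flagged as such. Odd panels cannot tie; for even
panels the default tie policy predicts the training-majority class (ACQ
at the reference class balance), flags the record, and can be switched to
always-AIE or always-ACQ.

### Evaluation

Outer stratified 10-fold CV with a single fold split shared by all
methods (paired comparability); stratification is a package choice
justified by the 134/222 imbalance. Per cell and fold: training accuracy
of the refitted model on its own outer-training split, and test accuracy
/ AUC / F1. Aggregation: mean ± sample (n−1) std over folds, skipping
folds where a ratio is undefined; plus confusion counts pooled over all
outer test predictions. Undefined ratios (zero denominators) are reported
as `None`/`undefined`, never coerced to 0. AUC is computed by
`roc_auc_score` and property-tested against a brute-force pair-counting
oracle at 1e-12. The false-positive rate is FP/(TN+FP). Rendered tables
round to 4 decimals; JSON keeps full precision.

## Synthetic data generator

The generator stands in for the curated literature dataset (which is
hosted externally) as a structural/statistical testbed. Defaults are the
study shape: 356 unique molecules, 134 AIE / 222 ACQ, zero label noise.

Planted rule: **AIE iff (# aryl rotors ≥ 3) and (largest bond-fused ring
system < 3 rings)**, where an aryl rotor is a benzene or naphthalene unit
whose only connection to the rest of the molecule is one acyclic single
bond. This caricatures restriction-of-intramolecular-rotation (rotor-rich
propellers emit in aggregates) versus planar π-stacking quenchers; it is
chemistry-flavoured, not photophysics. Tetraphenylethylene and
triphenylamine label AIE; pyrene, anthracene and biphenyl label ACQ.

Assembly: propeller proposals (olefinic / amine / methane / styryl /
benzene cores bearing 3–5 phenyl or naphthyl blades, optionally
decorated), planar proposals (7 fused polycyclic cores with 0–3 small
substituents at random aromatic CH positions) and low-rotor proposals.
Candidates are sanitized by RDKit, canonicalized, deduplicated, labeled
by the rule, and routed into whichever class quota is still open
(rejection sampling; exact counts before noise, error if quotas cannot be
filled). Label noise then flips each label independently with probability
ε, so the expected positive count is n₊(1−2ε) + nε. Everything is
deterministic under the config seed.

What passing tests on this generator do **not** show: real AIE prediction
accuracy. The planted rule is a deterministic function of substructure
counts visible to every feature mode, so high ensemble accuracy
demonstrates that the pipeline's plumbing (featurization → fusion →
tuning → voting → CV) can recover a learnable structure–label rule at the
study's size and imbalance — not that the learned models transfer to
experimental photophysics. Real data also contain label noise,
activity cliffs and scaffold redundancy the generator only partially
mimics (duplicates are removed, but congeneric series are not modelled).

## Reproducibility and problem sizes

A global seed fans out to per-stage seeds via
`(seed · 1000003 + crc32(stage)) mod 2³¹`; fold splits, tuning shuffles
and stochastic learners all derive from it, and deterministic families
(LR, KNN) produce byte-identical CV reports across runs. The test suite
exercises the full protocol at the reference scale (n = 356, outer 10-fold,
inner 5-fold, 20-voter multi-modal ensemble) with the `reduced` grid
preset, and smaller configurations (n = 60–120, 2–5 outer folds)
elsewhere; these sizes are the package's own desk-scale choices.

## Known limitations

- The descriptor list matches the published dimensionality (20 + 88),
  not a published membership; results on real data will differ with a
  different list.
- Fusion's default full-dataset fit scope is deliberately leaky (see
  above); use `fold_safe` for honest generalization estimates.
- The ensemble AUC from vote fractions is coarsely quantized (21 levels
  for 20 voters).
- No applicability-domain handling: molecules far outside the training
  distribution (non-rotor AIEgens, organometallics) get votes like any
  other input.
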