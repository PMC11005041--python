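# Methods

## Overview

`toxscope` implements a consensus QSAR workflow for binary toxicity
classification with human-interpretable, atom-level explanations.  The
pipeline has four stages:

1. **Representation.** Compounds are parsed from SMILES, standardized
   (largest covalent fragment kept, RDKit canonicalization, stereochemistry
   retained) and encoded as three binary fingerprint families: Morgan
   (radius 2, 1024 bits), an RDKit topological path fingerprint (1–7 bond
   subgraphs, 2048 bits) and an 881-bit substructure key.
2. **Models.** For each fingerprint family, four classifiers — random
   forest, SVM, k-nearest neighbours and a multilayer perceptron — are
   tuned by exhaustive grid search under repeated random-holdout
   cross-validation (20 folds, each an independent random 80/20 resample of
   the training set) scored by the Matthews correlation coefficient (MCC),
   then refit on the full training set.  Every model emits a probability
   score PS ∈ [0, 1]; a compound is labeled toxic when PS ≥ 0.5.
3. **Consensus.** Every subset of k ≥ 2 of the 12 models is a candidate
   consensus: its consensus score CS is the arithmetic mean of member PSs,
   toxic iff CS ≥ 0.5.  All Σₖ C(12, k) = 2¹² − 13 = 4083 combinations are
   evaluated on the held-out test set and ranked by MCC; ties prefer fewer
   members (cheaper prediction), then lexicographic member order.
4. **Explanation.** For each member of the best combination, per-bit Shapley
   values are estimated with Kernel SHAP and retro-mapped onto atoms via the
   fingerprint bit-to-atom maps; per-model atom weights are averaged over
   the consensus members and rendered on the structure.

## Fingerprints and bit-to-atom maps

Morgan and path fingerprints come from RDKit's fingerprint generators; their
`bitInfo` outputs provide the hashed environments (atom, radius) and bond
paths that set each bit, from which the contributing atom sets are derived.
Hash collisions are retained as separate *occurrences* of a bit — the atom
weighting formula normalises by the occurrence count, so collisions do not
inflate attributions.

The 881-bit substructure key is implemented in-package
(`toxscope/_pubchem.py`).  It follows the section layout of the public
CACTVS/PubChem substructure key — hierarchic element counts (bits 0–114), a
ring-system block (bits 115–262) organised by ring size (3–10), occurrence
count and seven saturation/aromaticity/heteroatom flavors, then atom pairs,
nearest-neighbour patterns, bond-specific pairs and SMARTS substructure
patterns with occurrence thresholds (bits 263–880).  The per-bit catalogue
is this package's own deterministic curation: every bit has an explicit,
matchable definition, so on-bits can always be traced to atoms by
substructure matching.  Ring-block bits have no per-bit SMARTS; they are
matched at the ring level and grouped into clusters of bits that describe
the same ring flavor and differ only in occurrence count.  Key properties
(length 881, determinism, occurrence consistency, cluster disjointness over
115–262) are asserted in the test suite.

Standardization scope: salts/solvates are stripped to the largest covalent
fragment; tautomers are not canonicalized; stereochemistry is retained
(fingerprints of the families used here are insensitive to it, so the choice
does not affect model inputs).

## Models and tuning

The default grids are:

| model | grid |
|---|---|
| RF  | `max_features` ∈ {sqrt, log2, all}; 100 or 500 trees |
| KNN | 1–15 neighbours; uniform or distance weighting |
| MLP | hidden layers: all 1–3-deep combinations of {100, 200, 1000} neurons; solver ∈ {lbfgs, adam, sgd}; activation ∈ {identity, logistic, tanh, relu}; initial learning rate ∈ {0.01, 0.001, 0.0001} |
| SVM | kernel ∈ {linear, rbf}; C ∈ {0.1, 1, 10, 100} |

The SVM kernel/C candidate values and the MLP depth bound (≤ 3 hidden
layers) are this package's defaults where the method leaves them open.  SVM
probabilities are Platt-calibrated because the consensus averages raw PSs;
KNN's PS is the (optionally distance-weighted) toxic fraction among the k
neighbours, the natural probability analogue of its vote.  All stochastic
steps take explicit seeds; classification always derives from PS with the
inclusive 0.5 threshold, identical for single models and consensus.

A reduced "fast" grid profile (same structure, 1–6 points per model) is
provided for desk-scale runs; the CV protocol (20 random 80/20 holdouts,
MCC scoring) is unchanged.  Cross-validation folds are *repeated holdout*
resamples, not a partition — two folds may share test compounds.

Metrics: precision, recall, specificity, accuracy and MCC are computed from
the confusion counts by their printed formulas.  A zero factor in the MCC
denominator yields MCC = 0; a zero denominator in precision/recall/
specificity yields NaN, which ranking treats as undefined.  MCC is
cross-checked in the tests against scikit-learn's independent
correlation-based implementation.

## Kernel SHAP

The `shap` dependency is not required: Kernel SHAP is implemented in
`toxscope/explain.py`.  The coalition game is interventional,
v(S) = E_b[f(x_S, b_{\bar S})], with the expectation over a seeded background
subsample of the training set (default 50 compounds; the bundled study runs
use 20).  Features identical between the explained compound and every
background row are excluded and scored 0.  When the number of varying
features is ≤ 13 the full coalition space is enumerated and the weighted
regression recovers *exact* Shapley values (verified against a brute-force
subset-enumeration oracle in the tests); otherwise coalitions are sampled
size-stratified under the Shapley kernel (complete size levels from the
extremes inward while the budget allows, random subsets for the remainder;
default budget 2M + 2048 for M varying features).  Local accuracy — scores
plus the background expectation equal the model's PS — is enforced exactly
by the constrained regression.

## Atom retro-mapping

For a feature f with signed score s_f, occurrences each covering n_Atoms
atoms, and n_occ occurrences in the molecule, every atom of every occurrence
receives s_f / (n_Atoms × n_occ); an atom's weight fw is the sum over the
features containing it.  Consequences asserted in the tests: for
non-overlapping, single-occurrence, mappable features the atom weights
conserve the total feature score; an atom contained only in positively
scored features never becomes negative.

Before retro-mapping the substructure key, the redundant ring-count block is
collapsed: within each cluster of ring bits encoding the same ring flavor,
only the *highest* signed score is retained (ties keep the lowest bit
index), the other member scores are zeroed and keep no atom correspondence.
The signed maximum (rather than maximum magnitude) is the toolkit's
convention; for the usual case of a positively scored ring system the two
coincide.

Per-model attributions live in each model's own bit space; the molecule's
atoms are the common denominator, so the final weight map is the per-atom
arithmetic mean over the consensus members.  Rendering colors atoms red
(toward toxicity) or blue (toward nontoxicity) with intensity ∝ |fw|, and a
JSON sidecar always carries the raw weights.

## Synthetic data

The generator (`toxscope/synthetic.py`) assembles molecules from a fixed
grammar of 20 drug-like scaffolds (12 aromatic + 8 aliphatic/saturated
heterocyclic) and ~36 substituents, with an optional second substitution
site.  The label is the presence of a planted toxicophore — by default an
aromatic nitro group, `c[N+](=O)[O-]` — XOR a seeded noise flip.  Defaults
mirror curated endpoint tables: 70% nontoxic / 30% toxic, noise 0.  The
grammar yields ~950 distinct toxicophore-bearing and ~8400 clean structures,
enough for endpoint-table-sized datasets (n ≈ 2850).

What the fixtures do and do not show: labels are a *deterministic* function
of a single substructure that all three fingerprint families encode
explicitly, so noise-free datasets are linearly separable and near-perfect
MCC is expected — real endpoints, with heterogeneous mechanisms and noisy
assays, are far harder and typically top out well below that.  Passing the recovery tests demonstrates that the machinery
(training, consensus selection, Shapley estimation, retro-mapping) is
correct, not that the models would perform comparably on real toxicity
data.

## Study problem sizes

The bundled end-to-end study (tests and `scripts/acceptance.py`) uses
n = 300 compounds (80/20 split), the fast grid profile with 20-fold CV, a
10-round y-randomization control on a balanced n = 1000 dataset, and SHAP
with a 20-compound background.  These sizes were chosen to keep a full run
at desk scale (minutes) while leaving every protocol element — fold count,
scoring, exhaustive 4083-combination scan, explanation pipeline — identical
to the full-scale method.

The y-randomization control needs special care about sample size.  For an
i.i.d. chance classifier on m test compounds the per-round |MCC| would
concentrate around √(2/(π·m)); here, however, a model trained on shuffled
labels predicts structurally similar compounds alike, so its test
predictions are correlated within scaffold families and per-round |MCC|
has a wider spread than the i.i.d. rate suggests (the *signed* MCC stays
centred on zero at every size, confirming the absence of residual signal).
Measured chance-level mean |MCC| over 10 rounds is ≈ 0.15–0.20 for a
60-compound test set and ≈ 0.10 for a 200-compound one, which is why the
control uses the larger balanced dataset.

## Numerical choices and edge cases

- PS/CS thresholding is inclusive at 0.5 everywhere.
- Consensus ranking treats NaN MCC as −∞; tie-breaks are deterministic
  (fewer members, then lexicographic member ids).
- Unparsable SMILES fail individually with the offending input echoed;
  batch operations collect per-record failures and continue.
- Duplicate structures with conflicting labels are removed entirely during
  refinement (no adjudication).
- The eye-irritation rule reads the conjunctiva/cornea/iris list as
  ANY-damage ⇒ toxic, the GHS-style reading; skin and oral thresholds are
  strict inequalities (score > 2.3, LD50 < 2000 mg/kg).
- The random split is plain (non-stratified), by record, reproducible by
  seed.

## Known limitations

- The substructure key's bit catalogue is structurally faithful to the
  public 881-bit layout but not bit-for-bit identical to the official
  table; models trained with it are internally consistent but their bit
  indices are not interchangeable with other software's PubChem
  fingerprints.
- Kernel SHAP for KNN members is the runtime bottleneck (each masked
  evaluation is a full neighbour search); explanations take tens of seconds
  per compound for KNN-containing consensuses.
- No applicability-domain analysis and no global feature-importance
  summaries; explanations are per-compound and local.
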