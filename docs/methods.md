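# Methods

## The problem and the modelling approach

A T-cell receptor (TCR) recognises a peptide presented by an MHC molecule
through six hypervariable loops: CDR1/2/3 on each of the α and β chains.
CDR3, created by stochastic V(D)J recombination, contacts the peptide;
CDR1/2 are germline-encoded by the V gene and contact mostly the MHC.
Given repertoires of peptide-annotated TCRs, the package addresses binary
specificity prediction — does this TCR bind that peptide? — with two
predictors deliberately kept side by side:

* a **nearest-neighbour similarity baseline**: the score of a query TCR
  for a peptide is its maximum kernel similarity to that peptide's known
  binders.  Zero parameters; any learned model that cannot beat it has
  learned nothing beyond sequence similarity.
* a **per-loop 1D-convolutional network**, trained per peptide
  (peptide-specific) or over all peptides with the peptide as an extra
  input (pan-specific).

## The k-mer similarity kernel

Gap-penalised alignment is inappropriate for CDR3 junctions (they are not
related by descent), so similarity is alignment-free.  For sequences
`s, t`:

    K(s,t) = Σ_{k=1..min(|s|,|t|)} Σ_{i,j} Π_{p=0..k-1} exp(β · B62(s[i+p], t[j+p]))
    sim(s,t) = K(s,t) / sqrt(K(s,s) · K(t,t))

with BLOSUM62 and β = 0.11387 (the constant published with the TCRMatch
tool; it keeps normalised scores in a usable (0,1] range).  The double sum
is evaluated with the suffix-product recurrence
`S[i,j] = E[i,j]·(1 + S[i+1,j+1])`, `K = Σ S[i,j]` (each residue pair
visited once; numba-jitted), and the literal k-mer enumeration is kept in
the test suite as the independent oracle.  An additive variant (plain sum
of substitution scores over k-mer pairs) is available via
`KernelParams(form="additive")` for comparison; it is not the default
because its normalisation is not bounded by 1.

A whole TCR is compared as the weighted mean of per-loop similarities.
Defaults: [1,1,4] per chain (CDR3 weighted four times CDR1/2) for
prediction; (0,0,1,0,0,1) — the plain CDR3 α/β average — for redundancy
reduction.

**Scale of the kernel, an important practical note.**  Under this kernel a
single random substitution in a 13-mer already drops the normalised
similarity to ≈0.5–0.8 (conservative substitutions score highest).  A
redundancy threshold of 0.95 therefore removes only near-identical CDR3
pairs — re-deposited clonotypes — not single-substitution variants.  The
synthetic generator and the test expectations are designed around this
measured scale.

## Data curation

Filtering (in order): records missing either CDR3 chain; cross-reactive
TCRs (identical six-loop sequences annotated to more than one peptide —
all of their rows); CDR3 lengths outside 6–20; peptides with fewer than
100 positives (configurable downward for small synthetic studies).

Hobohm-1 reduction: records sorted by descending CDR3α+β length (ties
broken lexicographically by (CDR3β, CDR3α) for determinism), greedily kept
iff strictly below the threshold against everything already kept: 0.95 for
positives, 0.9 for the negative pool.  The output is verified brute-force
in the tests: no kept pair reaches the threshold.

Partitioning: records (or single-linkage clusters, when pre-clustering is
enabled) are shuffled by seed and dealt round-robin into 6 partitions
(5 cross-validation + 1 evaluation), balancing counts within ±1.
Pre-clustering is off by default, matching the executed study design; the
flag exists because cluster-aware splitting is the stricter protocol.

Negatives: per positive, 5 true negatives (background TCRs paired with the
positive's peptide, sampled without replacement per peptide so no
duplicate (TCR, peptide) row can arise) and 5 swapped negatives (the
positive TCR paired with up to 5 other peptides, never one it is positive
for).  Generated negatives inherit their source positive's partition, so a
mispaired copy of a TCR can never sit on the other side of the
train/evaluation boundary.

Full-chain reconstruction stitches `v[:i] + cdr3 + j[g:]`, where `i`
indexes the rightmost cysteine within the last six V residues (the
conserved junction cysteine, which VDJdb-style CDR3 strings already carry
as their first residue) and `g` the glycine after the first F/W-followed-
by-G within the first 11 J residues.  Records failing reconstruction or
CDR1/2 annotation (gene missing from the table after allele stripping) are
dropped and counted, never imputed.

## The CNN

Inputs are left-zero-padded to 10 (CDR1/2), 20 (CDR3), 13 (peptide) and
encoded as BLOSUM50 rows divided by 5 (the divisor keeps inputs O(1); it
is configurable).  Per input block: 1D convolutions with 16 filters for
each kernel size in {1,3,5,7,9} (same-padding), sigmoid activation, global
max-pool over length; pooled features concatenated (480 for six loops),
then a 32-unit hidden layer and a single sigmoid output.  Sigmoid is used
in all layers by default, with ReLU available as an option.

Training: Adam (lr 0.001, standard moment defaults), binary cross-entropy,
batch size 64, up to 200 epochs with early stopping (patience 25, best
validation weights restored; both configurable).  Nested cross-validation:
for k partitions, one network per ordered (outer-test, inner-validation)
fold pair trained on the remaining k−2 folds — k(k−1) networks, 20 for
k=5 — whose predictions are averaged at inference.

The network is implemented directly on numpy (im2col convolution, analytic
backward pass, Adam) — at this size (≈10⁵ parameters) a tensor framework
buys nothing, and the pure-numpy path keeps training bitwise-reproducible
from the seed on any machine.  Gradients are verified against central
finite differences in the test suite.

## Evaluation protocols

* **AUC** via the Mann–Whitney pair count (ties count half) — exact, no
  interpolation ambiguity.
* **AUC 0.1**: trapezoidal area under the empirical ROC for FPR ≤ 0.1,
  divided by 0.1.  Vertical ROC climbs exactly at the cut-off contribute
  zero width (the staircase integral); a tie block straddling the cut-off
  is interpolated linearly.  All ties gives 0.05, perfection 1.0.
* **PPV**: fraction of positives among the top-n predictions, n = number
  of positives; stable descending sort, so tied scores keep input order.
* **Reports**: per peptide and per task (positives vs true negatives;
  positives vs swapped negatives), aggregated as the plain mean and the
  positive-count-weighted mean over peptides.
* **Bootstrap comparison**: record indices resampled jointly n times;
  p = fraction of resamples where the first model's AUC is smaller than
  the second's (ties half).  Self-comparison gives exactly 0.5; a
  uniformly better first model gives 0.  Degenerate single-class
  resamples are redrawn and logged.
* **Percentile rank**: fraction of a background repertoire scoring
  strictly above the query (0 = best).  Calibration makes scores
  comparable across peptide-specific models whose raw score scales
  differ.
* **Peptide-target ranking**: every positive TCR scored by every
  peptide's model; rank of the true peptide reported, with score
  categories top_TP/second_TN (correct top-1) and top_FP/FN (incorrect).
  With percentile ranks the ordering is ascending instead.
* **Distance-to-training curves**: each evaluation record's similarity to
  its nearest neighbour anywhere in the training set (positives and
  negatives) is computed with the same weighted kernel; records above a
  similarity cap are removed and the AUC recomputed per cap, after first
  dropping positives with a percentile rank above 0.3 when a calibration
  is supplied (noise suppression; negatives are never rank-filtered).
  Thresholds default to 10 values spanning 0.89–0.98; synthetic studies
  pass a wider span matching the synthetic similarity scale.

## The synthetic generator

The generator emulates what real peptide-annotated repertoires look like,
so that pipeline behaviour on it transfers qualitatively:

* **Founder clonotype families** (default 25 per peptide): binders of one
  peptide cluster in sequence space (convergent recombination).  Each
  positive copies a random founder and mutates internal non-motif CDR3
  residues at the diversification rate (default 0.10).  Without this
  structure a nearest-neighbour baseline has nothing to find — an i.i.d.
  motif-implanted background yields chance-level similarity AUC under the
  measured kernel scale.
* **A conserved CDR3β motif** per peptide (4-mers by default), implanted
  at a founder-specific internal position and mutated per residue at the
  motif mutation rate (default 0.15).  This is the learnable signal; the
  motif dial monotonically controls baseline performance.
* **V-gene usage skew**: each peptide draws V genes from a concentrated
  Dirichlet distribution over 40 genes per chain; one peptide carries an
  explicit 85% single-gene α bias (mirroring the known TRAV bias of
  melanoma-epitope binders), which is what makes CDR1/2 informative.
* **Clonotype re-deposits** (default 10% of positives): identical CDR3
  pairs with re-drawn gene annotations — similarity exactly 1 under the
  CDR3-only measure, the redundancy the 0.95 Hobohm threshold exists to
  remove.  A single-substitution variant would sit near 0.85 and
  legitimately survive that threshold.
* **Background pool** (default 4000): motif-free random TCRs, uniform
  gene usage, the source of true negatives and rank calibrations.

CDR3s follow the junction convention (conserved C first, F/W last,
lengths 10–16 within the admissible 6–20), and generated germline tables
guarantee the reconstruction anchors, so generated data survives every
curation step.  Amino acids are uniform over the 20 letters elsewhere.

What the generator does **not** emulate: biophysical V(D)J recombination
statistics, position-dependent amino-acid frequencies, MHC restriction,
cross-reactivity, or annotation noise.  Tests passing on this data show
the pipeline's mechanics and its qualitative behaviours (signal recovery,
redundancy removal, distance-dependent degradation of the baseline); they
do not certify real-data AUC levels.

`perturb_positives` injects evaluation records at a controlled distance
from training: a fixed number of CDR3 substitutions outside the motif
window, with gene annotations permuted across records (a distant TCR would
not share its source's exact genes).  This drives the distance-to-training
analyses.

## Problem sizes in the shipped tests

The test suite runs the full study at 4 peptides × 200 positives with
5 true and 5 (capped to 3) swapped negatives per positive.  The
signal-recovery checks train one network per peptide on a single
train/validation split (partitions 0–3 / 4) and evaluate on partition 5,
rather than the full 20-network nested-CV ensemble per peptide; the
nested-CV machinery itself is exercised and counted on a smaller corpus.
Networks train for up to 30 epochs with patience 10 in these checks.  At
the evaluation-partition size this yields per-peptide AUC noise of a few
hundredths; chance-level controls are therefore asserted on means over
three controls (single-control null AUC has standard deviation ≈0.05).

## Numerical and design notes

* Strict inequality at the Hobohm threshold (a pair exactly at the
  threshold is discarded) — the conservative reading.
* Hobohm for negatives uses the same CDR3-only similarity as for
  positives, threshold 0.9; cross-set (negative-vs-positive) redundancy is
  not filtered.
* The maximum (not mean) over the database is the baseline prediction.
* Ensemble member seeds derive from the configuration seed and the fold
  pair through `SeedSequence`, so ensembles are reproducible and members
  independent.
* Early stopping uses a patience counter on validation loss with best
  weights restored; a fixed-patience rule is one of several defensible
  readings of "early stopping monitoring the validation loss".
* `Repertoire` containers may hold duplicate records (curation needs to
  see them); uniqueness over (six loops, peptide) is enforced at the IO
  and generator boundaries.
* Substitution matrices are loaded from Biopython's bundled NCBI-format
  files; no matrix data is vendored.

## Known limitations

* The pan-specific mode is implemented and tested structurally, but the
  shipped synthetic studies exercise peptide-specific models, which is
  also where the method's conclusions apply at current data scales.
* Kernel batch routines support the default product kernel only; the
  additive and capped-k variants run through the scalar path.
* No GPU path and no hyperparameter search: the models are small by
  design, and the package's point is protocol, not architecture.
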