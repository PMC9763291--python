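# tcrpred

Prediction of T-cell receptor (TCR) specificity for peptide–MHC (pMHC)
targets, with the data curation and evaluation machinery the problem
demands.  The package is aimed at immunoinformaticians who work with paired
α/β TCR repertoires annotated against peptides and want to (i) build
leakage-free training corpora from heavily redundant public data, (ii)
train and baseline specificity predictors, and (iii) evaluate them the way
the field should: against a similarity baseline and as a function of
distance to the training data.

## What is in the box

**Similarity kernel.** TCR loops arise from stochastic V(D)J recombination,
so gap-penalised alignment scores are meaningless for them.  Sequences are
compared with an alignment-free k-mer kernel: for every k from 1 to the
shorter sequence length, all k-mer pairs contribute the product over
aligned positions of exp(β·B62(x,y)), with B62 the BLOSUM62 matrix and
β = 0.11387.  The normalised similarity

    sim(s,t) = K(s,t) / √(K(s,s)·K(t,t)) ∈ (0, 1]

equals 1 only for identical sequences.  A whole receptor is compared as a
weighted mean over its six CDR loops (default weights [1,1,4] per chain —
CDR3 counts four times CDR1/2).

**Curation.** Hobohm-1 redundancy reduction (records sorted by combined
CDR3 length, kept only if below a similarity threshold to everything kept
so far; 0.95 for positives, 0.9 for the negative pool), optional
single-linkage pre-clustering, balanced partitioning into 5
cross-validation + 1 evaluation partitions, and negative construction:
5 *true negatives* (background TCRs paired with the peptide) and 5
*swapped negatives* (positive TCRs mispaired with other peptides) per
positive.

**Similarity baseline.** A peptide's prediction for a query TCR is its
kernel similarity to the nearest neighbour among that peptide's training
positives.  No parameters, peptide-specific by construction, and the
yardstick every learned model must beat.

**CNN.** Each input sequence (six CDR loops; plus the peptide in
pan-specific mode) is left-zero-padded (10 for CDR1/2, 20 for CDR3, 13 for
peptides), BLOSUM50-encoded, and processed by its own 1D-convolution block
(16 filters × kernel sizes {1,3,5,7,9} = 80 filters per input), max-pooled
over length, concatenated, and fed through a 32-unit hidden layer to a
single sigmoid output.  Training: Adam (lr 0.001), binary cross-entropy,
up to 200 epochs with early stopping, under nested 5-fold cross-validation
(one network per ordered fold pair → 20 networks), ensembled by averaging.

**Evaluation.** AUC (Mann–Whitney), AUC 0.1 (partial ROC area below FPR
0.1, normalised), PPV (positives among the top-n, n = #positives), mean and
positive-count-weighted mean across peptides, a paired bootstrap AUC test,
percentile-rank calibration against a background repertoire, peptide-target
ranking (top_TP / second_TN / top_FP / FN score categories), and AUC as a
function of the similarity cap between evaluation and training records.

**Synthetic data.** A generator that emulates the structure such studies
exploit — founder clonotype families (convergent recombination), a
conserved CDR3β motif per peptide, antigen-driven V-gene usage skew
(including an 85% single-gene bias mirroring the known melanoma-epitope
TRAV bias), clonotype re-deposits, and a motif-free background pool — so
the entire pipeline is testable without any external download.

## Worked example

```python
import tcrpred as tp

# synthetic study: 4 peptides x 200 positive TCRs + 4000 background TCRs
table = tp.generate_gene_table(seed=7)
positives, background = tp.generate_repertoire(tp.SynthConfig(seed=7), table)
print(f"{len(positives)} positives, {len(background)} background TCRs")

reduced = tp.hobohm1_reduce(positives, threshold=0.95)
print(f"Hobohm 1 at 0.95 kept {len(reduced)} of {len(positives)}")
reduced = tp.partition_data(reduced, tp.RedundancyConfig(seed=7))

pep = "GILGFVFTL"
mine = tp.Repertoire([r for r in reduced if r.peptide == pep])
train = tp.Repertoire([r for r in mine if r.partition != 5])
held = tp.Repertoire([r for r in mine if r.partition == 5])
db = tp.PeptideDatabase(pep, train)
pos_scores = tp.predict_set(held, db)
neg_scores = tp.predict_set(background[3000:3300], db)
print(f"{pep}: baseline AUC = {tp.auc(pos_scores, neg_scores):.3f} "
      f"({len(held)} held-out positives vs 300 background TCRs)")
```

Output:

```
860 positives, 4000 background TCRs
Hobohm 1 at 0.95 kept 783 of 860
GILGFVFTL: baseline AUC = 0.993 (35 held-out positives vs 300 background TCRs)
```

The generator emitted 860 records because 10% of the 800 positives were
re-deposited as near-duplicate clonotypes; Hobohm-1 removes them (and a few
coincidentally close pairs).  The baseline separates held-out binders from
background TCRs almost perfectly because binders of the same peptide
cluster into sequence families — exactly the property that makes redundancy
handling and distance-aware evaluation necessary on real data.

The same pipeline is scriptable end to end from a YAML configuration:

```sh
tcrpred simulate --config config.yaml   # gene table + repertoires
tcrpred prepare  --config config.yaml   # filter, Hobohm, partition, negatives
tcrpred train    --config config.yaml   # nested-CV CNN ensembles per peptide
tcrpred predict  --config config.yaml   # score the held-out partition
tcrpred baseline --config config.yaml   # nearest-neighbour baseline scores
tcrpred evaluate --config config.yaml   # per-peptide AUC/AUC0.1/PPV report
tcrpred rank     --config config.yaml   # peptide-target ranking
```

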