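# tcrlatent

Predicting which epitopes a T cell receptor recognizes from its CDR3β
sequence, with a coordinated-representation neural model: CDR3β sequences are
embedded as **points** and epitopes as **diagonal Gaussians** in a shared
latent space, and the binding score is the Gaussian density of the CDR3β
embedding under the epitope's distribution.

The package is aimed at computational immunologists working with
TCR–epitope binding data (VDJdb/IEDB/McPAS/PIRD-style exports of positive
pairs plus an ambient repertoire of non-binding CDR3β sequences). It covers
the full workflow: curation filters, CDR3β standardization, balanced
train/test assembly, model training, the two canonical evaluation tasks,
maximum-entropy MCMC interpretation of the trained model, and comparison of
the inferred position salience with TCR–pMHC crystal-structure distances.

## The model

Each sequence is encoded as a fixed-shape matrix of min–max-scaled Atchley
factor scores (five physicochemical factors plus a real-residue indicator;
20×6 for CDR3β, 10×6 for epitopes, placeholder rows `(0.5,…,0.5,0)` pad
shorter sequences). Two networks are trained jointly:

- the **CDR3β embedding network** *f*: sequence matrix → point *f(x)* ∈ ℝ³²;
- the **epitope mapping network**: sequence matrix → *μ(y), σ(y)* ∈ ℝ³²,
  defining a diagonal Gaussian N(μ(y), Σ(y)) over the same space.

The unnormalized binding affinity is

    p(x, y) = exp(−½ (f(x) − μ(y))ᵀ Σ(y)⁻¹ (f(x) − μ(y))) / √((2π)^k |Σ(y)|)

computed in log space throughout (k = 32 densities underflow otherwise).
Training minimizes batch-all **Triplet Loss** (anchors and positives share an
epitope; negatives are other classes or ambient sequences) plus λ × the
**negative log likelihood** −log p(x, y) over binding pairs, with the CDR3β
network shared between both terms.

Two evaluation settings follow from one trained model: **Task 1** scores a
repertoire against one epitope and reports AUC; **Task 2** assigns each
binder to the argmax-affinity epitope and reports accuracy plus a
row-normalized confusion matrix.

For interpretation, a Metropolis chain samples fixed-length CDR3β space with
stationary law ∝ p(x, y)^β, mutating one inner position at a time (the
conserved terminal C and F are fixed). Position-wise KL divergence of the
sampled residue distributions from uniform quantifies how salient each
position is to the model; Jensen–Shannon clustering of runs, uniqueness
ranking against alternative epitopes, Atchley-factor heatmaps, and the
salience-rank vs. structure-distance correlation build on the same runs.

## Worked example

Everything below runs on synthetic data with known ground truth — three
epitope classes of 300 CDR3β sequences whose binding signal is a 3-residue
motif implanted at positions 6–8 (90% of sequences), plus a diverse ambient
pool:

```bash
tcrlatent simulate --seed 7 --out fixtures/
tcrlatent preprocess --pairs fixtures/pairs.tsv --k 10 \
    --out-fixed fixed.tsv --out-unfixed unfixed.tsv --report properness.tsv
tcrlatent train --pairs fixed.tsv --negatives fixtures/ambient.txt \
    --epochs 50 --seed 0 --test-negatives 2000 --out model.npz
tcrlatent eval --model model.npz --pairs fixed.tsv \
    --negatives fixtures/ambient.txt --test-negatives 2000 --task both
```

The eval step prints (seed 0):

```
task1   ELAGIGILTV   auc=0.9996   n_pos=60   n_neg=2000
task1   GILGFVFTL    auc=0.9992   n_pos=60   n_neg=2000
task1   NLVPMVATV    auc=0.9981   n_pos=60   n_neg=2000
task2   accuracy=0.9611
```

Task 1 AUC near 1 means held-out binders of each epitope outscore virtually
every ambient sequence. Task 2 accuracy sits close to the ceiling for these
conditions: ~10% of sequences carry no motif and are intrinsically
unassignable beyond the 1/3 chance level (5-fold cross-validated accuracy is
~0.92 on average).

The same model can then be interpreted:

```bash
tcrlatent interpret --model model.npz --pairs fixed.tsv \
    --epitope GILGFVFTL --length 14 --beta 16 --steps 5000 \
    --seeds 20 --runs-per-seed 5 --out interp/
```

which writes the representative position-frequency matrix (consumable by
standard logo renderers) and the per-position KL profile; on the fixture the
implanted positions 6–8 carry the top KL values.

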