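# tcalign

Alignment of unequal-length time-course gene expression profiles with hidden
Markov models, and classification of developmentally driven genes by how well
their profiles align.

## The problem

In longer-term time-course expression experiments the same biological process
can unfold at different rates under different conditions — two field sites, two
seasons, two strains. Each gene then has a *pair* of expression profiles of
unequal length (the motivating case: T₁ = 19 and T₂ = 17 weekly measurements of
grape berry development at two vineyards), and an integrated analysis needs a
common alignment of the two time axes. The data are too sparse in time for
interpolation or continuous warping: what is needed is a coarse, discrete,
*shared* alignment, plus a way to tell which genes actually follow the common
developmental program and which are driven by site-specific factors.

## The model

Each pair of scaled profiles (w₁..w_T, c₁..c_{T₂}) is modelled as two emission
sequences of a single latent state sequence S₁..S_T with N discrete states
(distinct quantitative expression levels), initial distribution a, transition
matrix A, and Gaussian emissions b(x | μ_j, σ²_j) with σ²_j ≥ 0.001. The long
profile occupies every state position (τ₁,ₜ = t); the short profile skips a set
of **gap positions** — for T − T₂ = 2, positions 1 < g₁ < g₂ ≤ T — shared by
*all* genes, with the first time points constrained to align. The
log-likelihood for K pairs is

ℓ(λ, g₁, g₂) = Σₖ log Σ_{s₁..s_T} p(s₁..s_T) · Πₜ b(wₜ | s_{τ₁,ₜ}) · Πₜ b(cₜ | s_{τ₂,ₜ})

Fitting is a robust **two-step** procedure: (1) estimate λ = {a, A, B} by
Baum-Welch pooled over every *individual* profile from both sites, ignoring
the pairing — this is insensitive to pairs that do not align; (2) evaluate
ℓ(λ̂, g₁, g₂) for all C(T−1, 2) gap pairs and take the argmax. The full MLE
λ̂\*(g₁, g₂) (EM on the alignment model at fixed gaps) is also provided; on
contaminated data its emission variances inflate, which is itself diagnostic.

Per gene, alignment quality is the **Hamming distance** H(k) between the joint
Viterbi path and the two individually decoded paths at their mapped positions
(0 ≤ H ≤ T₁ + T₂). Genes with H(k) ≤ 10 are classified as developmentally
driven; with external labels the classifier's ROC/AUC is computed with −H(k)
as the score.

## Worked example

```python
from tcalign import synthetic
from tcalign.model import AlignmentHMM

ds = synthetic.generate_dataset(K=500, contamination_fraction=0.3, seed=42)
res = AlignmentHMM(ds.pairs, n_states=5).fit()
print(res.summary())
```

```
Alignment HMM results
======================================================
pairs:            500  (T1=19, T2=17)
states:           5
method:           two_step
gap positions:    (2, 11)
surface size:     153 gap sets
peak sharpness:   8360.73
EM iterations:    53 (converged: True)
log-likelihood:   -2011.5082
------------------------------------------------------
state   mean      variance
    1   0.0011    0.0105
    2   0.2513    0.0095
    3   0.4996    0.0108
    4   0.7500    0.0109
    5   1.0030    0.0097
```

Despite 30 % of the pairs being non-alignable, the two-step fit recovers the
generating gap positions (2, 11) and the five evenly spaced state means with
near-true variances (0.01). `res.diagnostics()` returns the per-gene pair
log-likelihood, H(k) and label; `res.roc(ds.labels())` scores the Hamming
classifier against the ground-truth contamination flags:

```python
curve, auc = res.roc(ds.labels())
# AUC of the Hamming classifier vs ground truth: 0.999
```

`res.plot_surface()` renders the gap log-likelihood heat-map and
`res.plot_pair(gene_id)` a pair's aligned profiles with its joint Viterbi path.

## Command line

The same steps are exposed as a CLI over TSV/JSON files:

```sh
tcalign simulate  --n-pairs 1000 --contamination 0.3 --seed 1 --outdir sim/
tcalign fit       sim/pairs.tsv --outdir fit/
tcalign align     sim/pairs.tsv fit/params.json --gaps 2,11 --outdir aligned/
tcalign diagnose  sim/pairs.tsv fit/params.json --gaps 2,11 --outdir diag/
tcalign preprocess long_site.tsv short_site.tsv --outdir prep/
tcalign robustness --fractions 0,0.2,0.4,0.6,0.8 --outdir rob/
```

Every command writes a resolved config next to its outputs; reruns with the
same inputs and seed are byte-identical.

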