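# pottsfocus

Sparse Potts fitness prediction from multiple sequence alignments, with an
explicit quantity-relevance trade-off: estimate how the predictive accuracy
of a K-link Potts model depends on how many sequences you train on (B) and
how close they are to your wild type (D), then pick the sub-alignment that
maximizes it.

## Who this is for

Anyone scoring single-point mutations of a protein from its family
alignment — deep-mutational-scan analysis, variant prioritization, protein
engineering — who wants to know *which sequences to train on* rather than
always using the full alignment, and how that answer changes with model
complexity.

## The model

A K-link Potts model over Q = 20 amino acids assigns

    log P(s) = sum_i h_i(s_i) + sum_{(i,j) in L} J_ij(s_i, s_j) + const,

with couplings restricted to K selected pairs (K = 0 is the independent-site
profile model).  The predicted effect of the mutation `wt_i -> a` is the
log-probability difference

    E^_ia = h_i(a) - h_i(wt_i) + sum_{j ~ i} [J_ij(a, wt_j) - J_ij(wt_i, wt_j)],

and performance rho is the Spearman correlation with measured effects.
Links are chosen by pseudolikelihood DCA (Frobenius norm of the coupling
blocks in zero-sum gauge); the retained couplings are re-inferred in a
closed two-site form.

The mean squared prediction error decomposes into a squared bias and a
variance:

* `sigma^2` — closed-form sampling variance, computed from the alignment's
  (regularized) frequencies; proportional to 1/B and growing with K.
* `mu^2 ~ J0 * D` — systematic error from epistasis the model cannot
  express; the bias factor J0 decreases with K and is fittable from data by
  maximizing `|Spearman(rho, J0 D + sigma^2)|` across sub-alignments.

Focusing — discarding sequences beyond a distance cutoff from the wild
type — trades bias against variance; the package predicts the best cutoff
either from the fitted J0 (`d_bv`) or, without any experimental data, from a
signal-to-noise heuristic (`d_snr`, threshold 3).

Everything is validated on a self-contained lattice-protein landscape
(27-mers on the 3x3x3 cube, 103,346 compact folds, Miyazawa-Jernigan
contact energies) where the exact effect of every mutation is computable.
See `docs/methods.md` for the full model description and the desk-scale
caveats.

## Worked example

Score mutations of a wild type from an aligned FASTA and fit a model:

```bash
pottsfocus infer family.fasta --wt wt_id -k 8 -o model.npz
pottsfocus predict model.npz family.fasta --wt wt_id -o predictions.csv --scan scan.csv
```

From Python, the lattice bench reproduces the whole analysis without any
input files:

```python
from pottsfocus.bench import run_validation_bench

res = run_validation_bench(seed=1)
for k, m in res.metrics["per_k"].items():
    print(f"K={k:2d}  |R|(rho, mu2+sigma2)={m['r_rho_vs_mse']:.2f}  "
          f"R(mu2, D)={m['r_mu2_vs_d']:.2f}  R(sigma2)={m['r_sigma2']:.2f}")
```

prints (seed 1, desk-scale settings)

```
K= 0  |R|(rho, mu2+sigma2)=0.94  R(mu2, D)=0.99  R(sigma2)=0.98
K= 8  |R|(rho, mu2+sigma2)=0.88  R(mu2, D)=0.70  R(sigma2)=0.88
K=24  |R|(rho, mu2+sigma2)=0.88  R(mu2, D)=-0.16  R(sigma2)=0.83
```

Reading the columns: the performance of each K-link model across a grid of
sub-alignments is explained by the sum of its ground-truth squared bias and
variance (first column, anti-correlation magnitude); the squared bias of the
profile model is cleanly linear in the mean Hamming distance D (second
column); and the closed-form variance estimate tracks the measured one
(third column).  For the coupled models (K > 0) the second column degrades
at this bench's small training sizes (B <= 300): coupling-estimation
systematics improve with data diversity faster than un-modeled epistasis
grows, inverting the large-B relationship — see the limitations section of
`docs/methods.md`.

Focusing on the same landscape (independent model, sweep of the distance
cutoff) gives an interior optimum and working heuristics:

```
d_opt=11 (rho=0.932)   d_bv=10   d_snr=9 (rho=0.909)   full MSA rho=0.885
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the contact count shared by all compact folds
(after enumerating and cross-checking the full repertoire) and the
bias-variance correlations of the lattice bench above.  Runtime is around
ten minutes on one core.
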