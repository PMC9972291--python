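# ipolng

Probabilistic non-negative factorization of single-cell multiomics count
data. The package implements two related latent-factor models and
everything needed to benchmark them end to end: a generative simulator,
preprocessing, Leiden clustering with a resolution search, and the ARI /
RAGI evaluation metrics.

## The models

**PoLNG** (one modality). For a cells-by-features count matrix
`W ∈ N^{I×J}` with per-cell sequencing depths `s_i = Σ_j w_ij`:

    l_ik ~ Gamma(α_ik, β_ik)                      (shape–rate)
    θ_k  = softmax(θ̃_k),  θ̃_k ~ N(μ_k, Σ_k)      (diagonal Σ_k)
    w_ij ~ Poisson( s_i Σ_k l_ik θ_kj )

`L` is a non-negative cell embedding whose rows softly sum to 1 (the
depth factor `s_i` absorbs library size), and each row of `Θ` lies on the
probability simplex, so high entries mark factor-specific features. The
softmax-basis Logit-Normal prior on `Θ` keeps the simplex constraint while
allowing unconstrained optimization.

**iPoLNG** (two modalities, same cells). Each modality gets its own
loadings `L^(m)` and `Θ^(m)`; a shared embedding `L` ties them together:

    l_ik ~ InverseGamma(α_ik, β_ik)
    l^(m)_ik | l_ik ~ Gamma(α₀^(m), α₀^(m) / l_ik)
    w^(m)_ij ~ Poisson( s^(m)_i Σ_k l^(m)_ik θ^(m)_kj )

so `E[l^(m)|l] = l` and `var[l^(m)|l] = l²/α₀^(m)`: a large `α₀` marks a
low-noise modality. `α₀^(m)` is calibrated automatically by fitting PoLNG
per modality and regressing the variational variance of the loadings on
their squared mean (90% quantile regression through the origin); the
joint fit is warm-started from the least-noisy modality's fit.

Inference is stochastic variational inference: Adam ascent on a
one-sample pathwise ELBO estimate (Gaussian location–scale and implicit
Gamma/Inverse-Gamma reparameterization, closed-form KL terms), 3,000
epochs at learning rate 0.1 by default, fully deterministic given a seed.
Point estimates are the variational modes. Cells with all-zero counts in
a modality (including deliberately masked cells) drop out of that
modality's likelihood, which is how partially observed datasets are
integrated.

## Worked example

```python
import numpy as np
from ipolng import (FactorConfig, make_truth, simulate_multiome, fit_ipolng,
                    leiden_cluster_to_k, adjusted_rand_index)

# 5 clusters (403/219/396/169/440 cells), RNA-like + epigenome-like counts
truth = make_truth(seed=11)
W_rna, W_epi, labels = simulate_multiome(truth, hierarchical=True)

fit = fit_ipolng(W_rna, W_epi, FactorConfig(K=5, epochs=600, seed=1),
                 polng_epochs=400)
print("alpha0:", [round(a, 1) for a in fit.alpha0])

clusters = leiden_cluster_to_k(fit.L_hat, target_k=5, seed=0)
print("ARI:", adjusted_rand_index(labels, clusters.labels))
```

Output:

```
alpha0: [13.6, 13.3]
ARI: 1.0
```

The calibrated `alpha0` values say both simulated modalities carry
comparable noise (the generator used `alpha0 = (10, 10)`), and the Leiden
partition of the shared embedding recovers the five ground-truth cell
clusters exactly.

The same workflow is available from the shell:

```bash
ipolng simulate --config sim.yaml --seed 3 --out data/
ipolng fit --rna data/rna --epi data/epi -K 5 --epochs 600 --seed 1 --out fit/
ipolng evaluate --embedding fit/L_hat.tsv --labels data/truth_labels.tsv \
    --target-k 5 --seed 0
```

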