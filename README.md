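# mklselect

Objective selection of relevant **information sources** in binary
classification, for multimodal biomedical data where each source is a named
block of features — an EEG electrode's wavelet statistics, one MRI
sequence's radiomic descriptors — and the question is *which sources does
the classifier actually need?*

## The method

Each of the P sources gets its own Gaussian kernel whose bandwidth is set
per sample by **local scaling**: σᵢ is the Euclidean distance from sample i
to its K-th nearest neighbour within that source's feature space, and

K(xᵢ, xⱼ) = exp( −‖xᵢ − xⱼ‖² / (2 σᵢ σⱼ) ).

The per-source kernels are fused as a weighted sum
K_η = Σₘ ηₘ Kₘ with the weights η constrained to the unit ℓp ball — the
simplex for p = 1, which drives the weights of uninformative sources to
exactly zero. Training alternates an SVM dual solve (libsvm SMO on the
combined precomputed Gram) with the closed-form update
ηₘ ∝ ‖wₘ‖^(2/(p+1)), where ‖wₘ‖² = ηₘ² Σᵢⱼ αᵢαⱼyᵢyⱼ Kₘ(xᵢᵐ, xⱼᵐ), until η
stabilises. The trained η ranks the sources; dropping them from least to
most relevant yields an elimination curve and a minimal source subset with
its reduction rate 1 − n_selected/n_total.

Because local scaling is defined on the training set only, three algorithms
assign bandwidths to unseen samples: (1) K-th-nearest-training-sample
distance, (2) the σ of the nearest support vector, (3) the nearest support
vector's mean σ pooled over its non-SV neighbourhood. Hyperparameters
(C, K, τ) can be tuned by particle-swarm optimization against a 10-fold
cross-validated geometric mean of sensitivity and specificity, and a
Fisher-score feature-selection baseline is included for comparison.

## Worked example

```python
import mklselect as m

ds = m.make_multisource(m.recovery_spec(seed=1))     # 2 informative + 6 noise sources
train, test = m.split_dataset(ds, m.SplitSpec(seed=1))
train, (test,) = m.standardize(train, [test])

results = m.MKLSourceSelection(train, m.MKLConfig(p=1, K=7)).fit()
print(results.summary())
print(results.score_report(test))

curve = m.elimination_curve(results, train, test)
n_star, sources, report = m.select_minimal(curve)
print(f"minimal subset: n={n_star} sources={sources}")
print(f"reduction rate: {m.reduction_rate(n_star, ds.n_sources):.2f}")
```

Output:

```
MKL-SVM source selection results
============================================
sources: P=8   train samples: N=160
penalty: l1   C=1   K=7   tau=0.001   prediction algorithm: 1
outer iterations: 38 (converged)   support vectors: 49
--------------------------------------------
kernel weights (source relevance, descending):
  inf0             eta = 0.810902
  inf1             eta = 0.189098
  noise5           eta = 0.000000
  noise3           eta = 0.000000
  ...
============================================
accuracy=100.00% sensitivity=100.00% specificity=100.00% geo-mean=100.00%
minimal subset: n=1 sources=['inf0']
reduction rate: 0.88
```

The ℓ1 penalty zeroed all six noise sources; the two informative sources
hold all the weight, and a single source already attains the full model's
held-out accuracy, so 7 of 8 sources (88%) can be discarded.

The same pipeline is available from the shell:

```bash
mklselect synth --out data/ --seed 1
mklselect train --manifest data/manifest.yaml --out run/ --p 1 --K 7
mklselect curve --run run/
mklselect tune  --manifest data/manifest.yaml --out tuned.json
mklselect baseline --manifest data/manifest.yaml --out baseline/
```

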