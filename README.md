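# cpifusion

Predicting compound–protein interaction (CPI) affinity by fusing **local**
and **global** views of both the small molecule and the protein target, with
a transfer-learning protocol for small single-target activity sets and a
virtual-screening rank-and-filter cascade. The package is aimed at
computational chemists and machine-learning practitioners who want a
self-contained, dependency-light CPI regression pipeline that runs on a
laptop CPU and is testable end-to-end on synthetic data.

## The model

The regressor maps a pair (compound, protein) to a scalar affinity *y*
(a KIBA score or pEC50 = −log₁₀ EC50[M]) through four specialized heads:

| head | input | architecture | width |
|---|---|---|---|
| compound local | SMILES label-encoded to length 100 (0 = pad) | embedding (128) → 1-D convs (32/64/96 filters, kernels 4/6/8) → global max pool | 96 |
| protein local | sequence label-encoded to length 1,000 (A=1…Y=20, X=21) | embedding (128) → 1-D convs (32/64/96, kernels 4/8/12) → global max pool | 96 |
| compound global | ECFP4 fingerprint (1,024 bits) ⊕ molecular descriptors (z-scored, null columns dropped) | fully connected + ReLU | 512 |
| protein global | sequence descriptors: AAC (20) + dipeptide (400) + CTD (147) | fully connected + ReLU | 512 |

The four outputs are concatenated — **1,216** dimensions — and passed
through a fully connected fusion stack (1024 → 512 → 1, dropout 0.1).
Training minimizes MSE with Adam; the dataset is split into one-sixth test
plus 5-fold cross-validation over the remainder. Evaluation reports

- MSE = Σᵢ(yᵢ − ŷᵢ)²/m
- CI = Σ_{yᵢ>yⱼ} h(ŷᵢ − ŷⱼ)/Z with h(x) = 1, ½, 0 for x >, =, < 0
  (pairwise ranking consistency)
- R² = 1 − Σ(y − ŷ)²/Σ(y − ȳ)²
- PCC (Pearson correlation of y and ŷ)

For a small target task (e.g. ~245 pEC50 measurements against one kinase),
a model pretrained on a large CPI benchmark is **fine-tuned** end-to-end at
a reduced learning rate, reusing the output head. Screening a compound
library then proceeds: rank by predicted pEC50 → keep the top 10% → keep
rows with docking score < −7 and QikProp #stars < 5 (strict) → optional
Lipinski rule-of-five annotation.

The network (embedding, masked 1-D convolutions, max-over-time pooling,
dense fusion, backpropagation, Adam) is implemented directly on NumPy in
float32; padding positions are masked out of the convolutions and the
pooling, so predictions are exactly invariant to padding length.

## Worked example

```python
import numpy as np
from cpifusion import (generate_cpi_dataset, make_split, fit_on_dataset,
                       TrainConfig, evaluate)

# 2,000 synthetic interactions whose affinity depends jointly on a
# carboxyl-motif x sequence-motif match (local) and on MW x hydrophobicity
# (global), noise sd 0.25
dataset, truth = generate_cpi_dataset(200, 20, density=0.5, seed=11)
split = make_split(dataset, seed=0)

result = fit_on_dataset(dataset, split.train_indices_for_fold(0), split.folds[0],
                        train_config=TrainConfig(max_epochs=30, patience=6, seed=0))
X_test, y_test = result.model.featurizer.transform(dataset, split.test_indices)
report = evaluate(y_test, result.model.predict(X_test))
print({k: round(v, 3) for k, v in report.as_dict().items()})
```

prints (about 3 minutes on one CPU core):

```
{'mse': 0.102, 'ci': 0.901, 'r2': 0.942, 'pcc': 0.971}
```

i.e. on held-out pairs the model explains ~94% of the affinity variance,
ranks pairs correctly with probability ~0.90, and its errors (MSE 0.10)
approach the injected noise floor (σ² = 0.0625).

The same pipeline is scriptable from the shell:

```bash
cpifusion simulate --n-compounds 200 --n-proteins 20 --seed 11 --out-prefix sim
cpifusion train sim_cpi.csv --epochs 30 --seed 0 --model-out model.ckpt
cpifusion screen library_predictions.csv --fraction 0.10 --out hits.csv
```

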