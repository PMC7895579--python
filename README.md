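# inrnn — interval neutrosophic rough neural networks

`inrnn` is a classifier for uncertain tabular data, built for fetal-state
assessment from cardiotocography (CTG) recordings: 21 continuous features
per recording, three strongly imbalanced classes — Normal, Suspicious,
Pathologic (NSP). It targets clinical-decision-support settings where a
hard class label alone hides how unsure the model is, and works on any
dataset with the same shape.

## The model

The building block is the **rough neuron**: a neuron holding two weight
vectors, a lower set `W_L` and an upper set `W_U`. Both produce a
pre-activation from the same inputs,

    I_L = Σ_j W_Lj·o_j,    I_U = Σ_j W_Uj·o_j,

and after the sigmoid `f(x) = 1/(1 + e^{−λx})` the smaller activation
becomes the lower output and the larger the upper output (the branches
swap freely between weight sets):

    O_L = min(f(I_L), f(I_U)),   O_U = max(f(I_L), f(I_U)),   O = O_L + O_U.

A rough neural network (RNN) stacks rough hidden layers between a
conventional input layer and a conventional sigmoid output layer, with
the hidden width set by the Baum–Haussler heuristic
`N_hn = N_train·Te/(N_in + N_out)`. Training is plain stochastic
backpropagation of the squared error `0.5·Σ(T − O)²`.

The **interval neutrosophic** layer trains *two* such networks on the
same data: a true-membership network targeting one-hot class codewords,
and a false-membership network targeting their bitwise complements. For
a new instance each class `c` gets a triple

    T_c  (true net score),   F_c  (false net score),   I_c = 1 − |T_c − F_c|,

so the indeterminacy `I_c` is high exactly where the two networks fail to
disagree — the uncertainty boundary zone. Hard decisions binarize per
class (`bit_c = 1` iff `T_c > F_c`) and resolve the codeword: one set bit
names the class, an all-zero codeword falls back to the class of maximum
indeterminacy, and multiple set bits resolve by the largest margin
`T_c − F_c`.

The evaluation stack provides the confusion matrix (rows actual, columns
predicted), micro accuracy, per-class and support-weighted
precision/recall/F1, one-vs-rest ROC AUC by the rank statistic, and
stratified k-fold cross-validation with leakage-safe per-fold min–max
normalization.

## Worked example

```python
import numpy as np
from inrnn import (generate_separable, RNNConfig, fit_dual, predict,
                   cross_validate)

ds = generate_separable(300, seed=1)          # 3 balanced, well-separated classes
config = RNNConfig(max_epochs=100, target_mse=5e-3, gamma=0.5)
dual = fit_dual(ds, config.with_seed(11))     # true + false membership nets

labels, records = predict(dual, ds.features)
r = records[0]
print(ds.labels[0], "->", labels[0])
for i, c in enumerate("NSP"):
    print(f"  {c}: T={r.T[i]:.5f}  I={r.I[i]:.5f}  F={r.F[i]:.5f}")
print("training accuracy:", np.mean(np.array(labels) == ds.labels))

result = cross_validate(ds, config, k=5, seed=1)
print(f"5-fold CV accuracy: {result.aggregate.accuracy:.1f}%")
```

prints

```
N -> N
  N: T=0.98922  I=0.01836  F=0.00758
  S: T=0.31826  I=0.31827  F=1.00000
  P: T=0.00002  I=0.17563  F=0.82439
training accuracy: 1.0
5-fold CV accuracy: 99.0%
```

The first instance is confidently Normal: the true net scores N high
(0.989), the false net scores it low (0.008), so indeterminacy is tiny
(0.018). The S row shows the other regime — true and false scores that
do not strongly oppose each other leave a visible indeterminacy (0.318),
flagging the class the model is least sure about even while the hard
decision is correct.

The same pipeline is scriptable from the shell:

```
inrnn simulate --n 425 --seed 7 -o data.csv
inrnn train    --data data.csv --gamma 0.5 --epochs 100 --seed 1 -o model.json
inrnn predict  --model model.json --data data.csv -o predictions.csv
inrnn crossval --data data.csv --k 5 --gamma 0.5 --epochs 100 --seed 1 -o cv/
```

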