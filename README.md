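# mirdescribe

Interpretable structural descriptions of precursor microRNA (pre-miRNA)
from the latent space of a disentangling variational autoencoder.

Pre-miRNAs fold into hairpins — a base-paired stem around an unpaired
terminal loop — and hairpin shape is what distinguishes them from other
small RNAs. Black-box classifiers detect pre-miRNA well but do not say
*what* makes a molecule a pre-miRNA. This package implements a framework
that does: it renders each molecule's secondary structure as a 100×25
five-color bar image `x` together with a binary bond-strength vector `m`
(1 where a column holds a Watson-Crick pair), learns three disentangled
latent subspaces — z_m (shape/bond strength), z_y (class), z_x (residual)
— with conditional priors, inverse autoregressive flows and auxiliary
classifiers, and then grows a decision tree over z_m whose splits are
linear SVMs trained to predict interpretable structural features
(pair fraction, length, bulges, …) from the latents. The root-to-leaf
paths that end in pre-miRNA-majority leaves read out as a structural
description such as

    pair_fraction > 0.71  AND  total_length > 61  AND  NOT max_bulge_size > 4

The model maximizes a DIVA-style objective: an evidence lower bound with
per-subspace KL terms

    L = E_q[log p(x|z_m, z_y, z_x)]
        − β_m KL(q(z_m|x) ‖ p(z_m|m))
        − β_x KL(q(z_x|x) ‖ N(0, I))
        − β_y KL(q(z_y|x) ‖ p(z_y|y))

plus auxiliary terms α_y1·E[log q(y|z_y)] + α_y2·E[log q(y|z_m)] +
α_m·E[log q(m|z_m)]. Everything runs on a self-contained numpy autodiff
engine — no GPU or deep-learning framework required — and all data are
synthetic hairpins/decoys from the bundled generator, so the whole study
is reproducible from a seed. See `docs/methods.md` for the model,
encoding conventions and design choices.

## Worked example

```python
import numpy as np
from mirdescribe import (GeneratorConfig, generate_dataset, encode_image,
                         decode_image, DivaVAE, ModelConfig)

records = generate_dataset(GeneratorConfig(n_samples=500, seed=11))
img, m = encode_image(records[0])
assert decode_image(img).sequence == records[0].sequence  # exact codec

model = DivaVAE.from_records(records, ModelConfig.desk())
results = model.fit(seed=0, epochs=10)
print(results.summary())
```

prints (abridged):

```
DIVA-style VAE results
====================================================
scale preset        desk
latent dims         3 x 8
IAF                 2 blocks, hidden 32
beta (m, x, y)      0.5, 0.5, 0.5
alpha (y1, y2, m)   12.0, 12.0, 1.0
n samples           500
epochs run          10
final train loss    560.575
final val loss      547.226
final recon loglik  -498.802
final KL (m,x,y)    5.872, 12.745, 6.826
```

The loss is −F (the negated objective); it falls monotonically through
the early epochs. After training, a held-out linear probe for the class
label on z_m or z_y is far more accurate than on z_x (0.98 / 0.97 vs 0.78
on this run) — the class and shape subspaces, not the residual one, carry
the label, which is what makes the description tree over z_m work:

```python
from mirdescribe import (build_feature_table, binarize_features,
                         LatentDescriptionTree, TreeConfig)
table = build_feature_table(records)
tree = LatentDescriptionTree(
    results.encode_latents()["z_m"], model.labels,
    binarize_features(table), TreeConfig(max_depth=5, min_samples=10,
                                         min_acc=0.8)).fit()
print(tree.summary())       # descriptions with support and purity
```

A thin CLI mirrors the stages: `mirdescribe simulate / encode / train /
tree / describe / run` (see `mirdescribe --help`).

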