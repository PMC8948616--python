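"""Supervised JVAE: joint reconstruction + classification, then latent probing.

A joint VAE with one continuous (style) node and class-matched discrete
nodes is trained with reconstruction + KL (beta-annealed) + cross-entropy
on the discrete logits.  Latent traversals are decoded and matched to
labeled reference samples to ask which class each discrete node encodes.
"""

import numpy as np

import metabodl as m
from metabodl.disentangle import discrete_node_labels

rng = np.random.default_rng(0)
centers = np.array([[0.2] * 15, [0.5] * 15, [0.8] * 15])
X = np.vstack([rng.normal(c, 0.06, (30, 15)) for c in centers])
y = np.repeat([0, 1, 2], 30)

cfg = m.TrainConfig(iterations=30_000, seed=0)
result = m.train_reconstruction((X, y), m.LatentSpec(n_continuous=1, n_discrete=3),
                                cfg, loss_kind="MSE", supervision="full",
                                test_data=(X, y), n_classes=3)

acc = np.mean(result.model.predict_labels(X) == y)
print(f"discrete-latent classification accuracy: {acc:.3f}")
print(f"reconstruction Euclidean distance (per sample): "
      f"{result.test_report['EuclideanDist']:.3f}")

grid = m.continuous_traversal_grid()
print(f"continuous traversal: 16 points from {grid[0]:.3f} to {grid[-1]:.3f} "
      "(central 90% of the standard-normal prior)")

node_labels = discrete_node_labels(result.model, X, [f"class_{c}" for c in y])
n_unique = m.count_unique_labels(node_labels)
print(f"nearest-reference label per discrete node: {node_labels}")
print(f"unique labels across discrete nodes: {n_unique} of 3 "
      "(3 = fully disentangled: each node decodes to a different class)")
print("a low count despite high classification accuracy means the decoder")
print("routes class information through the continuous node instead of the")
print("discrete ones - class and style stay intermixed in the latent space")
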