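"""Evaluate the three training loss components on a phantom bundle.

Shows the exact quantities the optimizer balances: soft-Dice segmentation
loss, the beta-VAE objective (reconstruction + KL), and the adjacency
penalty that keeps decoded points closely spaced.
"""

import numpy as np

from atm.losses import (
    LossWeights,
    adjacency_regularizer,
    dice_segmentation_loss,
    total_loss,
    vae_loss,
)
from atm.phantom import default_specs, make_subject

subject = make_subject([default_specs(n_points=32)[0]], rng_seed=1)
bundle = subject.bundles["arc_left"].as_array()
gt = subject.gt_occupancy["arc_left"].data.astype(float)

# a deliberately poor "prediction": the ground truth blurred and damped
rng = np.random.default_rng(0)
pred = np.clip(gt * 0.7 + rng.uniform(0, 0.1, gt.shape), 0, 1)
l_seg = dice_segmentation_loss(gt, pred, e=1e-6)
print(f"Dice loss of a damped/noisy segmentation: {l_seg:.4f} "
      "(0 = perfect overlap, 1 = none)")

# VAE loss with a jittered reconstruction and a mildly non-standard posterior
recon = bundle + rng.normal(0, 0.5, bundle.shape)
mu = rng.normal(0, 0.3, (len(bundle), 8))
sigma = np.full((len(bundle), 8), 0.9)
l_vae = vae_loss(bundle, recon, mu, sigma, beta=1.0)
print(f"VAE loss (sum-squared mm error + KL, per streamline): {l_vae:.1f}")

l_adj = adjacency_regularizer(bundle)
print(f"adjacency penalty of the ground truth: {l_adj:.3f} "
      "(mean + max of the average inter-point gap, mm)")

print(f"total with reference weights (1, 1, 1): "
      f"{total_loss(l_seg, l_vae, l_adj, LossWeights()):.1f}")
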