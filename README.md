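# atm-tract

Anatomy-to-tract mapping: generation of white-matter streamline bundles
directly from a 3-D anatomical volume, without diffusion imaging or
point-to-point streamline propagation.

## The problem

Tractography normally propagates streamlines step by step through a fiber
orientation field estimated from diffusion MRI, which makes it fragile in
crossing/kissing/bending-fiber regions and dependent on diffusion data
quality.  This package takes the generative alternative: learn, from
paired (anatomical volume, curated bundle) examples, a conditional
distribution over whole streamlines, and synthesize an entire bundle for
a new subject in one shot from its anatomy alone.  It is aimed at people
studying bundle-generation methodology: everything runs on synthetic
phantoms that the package itself generates, so there is no external data
dependency.

## The model

A streamline is a sequence of K 3-D points **s** = {(x_i, y_i, z_i)},
i = 1..K, in world mm (K = 128 canonically).  Four jointly-trained
networks:

- anatomy encoder **a** = E_A(x) over the volume x (strided 3-D convs);
- segmentation decoder x̃ = D_A(**a**) predicting the bundle's binary
  occupancy map, trained with smoothed soft-Dice loss
  L_SEG = 1 − 2(Σ x̂·x̃ + e)/(Σ x̂² + Σ x̃² + e);
- streamline encoder E_S(s; **a**) → (μ_s, σ_s), a diagonal-Gaussian
  posterior over a latent code, conditioned on **a** through FiLM
  (per-channel γ(a)·h + β(a)) layers;
- streamline decoder s̃ = D_S(z_s, **a**), with z_s = μ_s + ε ⊙ σ_s,
  ε ~ N(0, I).

The VAE objective is
L_VAE = (1/N) Σ_n [‖s_n − s̃_n‖² + β·KL(q(z|s_n) ‖ N(0, I))], and an
adjacency penalty L_ADJ = mean_n B(s_n) + max_n B(s_n), with B(s) the
average distance between consecutive points, keeps decoded points closely
spaced.  The total is λ_SEG·L_SEG + λ_VAE·L_VAE + λ_ADJ·L_ADJ (all
weights 1 by default, β = 1), optimized with Adam; the checkpoint with
the lowest validation loss is kept.

At inference, the training streamlines' posterior means define a Gaussian
KDE in latent space (Scott's-rule bandwidth); sampling that density and
decoding under a new subject's anatomical features yields its bundle,
which is then filtered (brain mask, 20 mm minimum length) and trimmed at
the white-matter boundary, with brainstem/cerebellum and
hemisphere-crossing exemptions.

Evaluation covers six families: bundle adjacency (minimum-direct-flip
streamline distances), voxel overlap/overreach/Dice, valid/invalid
streamline ratios, tract-orientation-distribution angular correlation
(spherical harmonics, l ≥ 2), bundle geometry (length, span, volume,
surface area), and parcellation connectomes with graph metrics (density,
characteristic path length, global efficiency, modularity).

## Worked example

`examples/03_train_and_generate.py` trains on 4 phantom subjects and
generates a bundle for a held-out subject (about two minutes on one CPU
core):

```
trained 60 epochs; best validation epoch 59 (total loss 202.55)
generated 300 streamlines; 300 survive filtering/trimming ({'outside_brain': 0, 'too_short': 0, 'trimmed_away': 0})
held-out subject: voxel Dice 0.463, overlap 0.328, overreach 0.090, bundle adjacency 1.000, segmentation Dice 0.828
```

Voxel Dice/overlap measure how much of the true bundle's voxel footprint
the generated streamlines recover; overreach is the spill outside it
(relative to the footprint size); bundle adjacency of 1.0 means every
generated streamline lies within 5 mm (minimum-direct-flip distance) of
the ground-truth bundle and vice versa; segmentation Dice scores the
occupancy map predicted directly by D_A.  The other examples build a
phantom (`01`), evaluate the loss components on known inputs (`02`), and
run all six metric families against a deliberately degraded bundle
(`04`).

A command-line interface mirrors the pipeline stages:

```bash
atm phantom --config cfg.yaml --out phantoms/
atm run --config cfg.yaml --out run/          # phantom -> train -> generate -> postprocess -> evaluate
atm postprocess --in b.trk --brain-mask brain.nii.gz --wm-mask wm.nii.gz --out clean.trk
atm evaluate --pred clean.trk --gt gt.trk --gt-mask mask.nii.gz --out report.json
```

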