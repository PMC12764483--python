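# Methods

## The model

The package learns a mapping from a 3-D anatomical intensity volume to a
bundle of white-matter streamlines, replacing point-to-point streamline
propagation with whole-bundle generation.  A streamline is an ordered
sequence of K 3-D points in world millimetres (RASMM); the canonical
point count is K = 128, configurable (the desk-scale experiments below use
K = 32).

Four sub-networks are trained jointly, one model per bundle:

* **Anatomy encoder `E_A`** — a stack of stride-2 3-D convolutions over the
  intensity volume.  Its output is the *anatomical feature* representation
  `a`: a fixed-length conditioning vector (projection of the deepest
  feature map) together with the encoder's multi-scale feature maps.
* **Segmentation decoder `D_A`** — mirrored upsampling convolutions that
  reconstruct the bundle's binary voxel occupancy map from `a`.  The
  decoder consumes the multi-scale maps through skip connections; its Dice
  loss is what forces `E_A` to localize the bundle.  Without the skips the
  prediction has to pass entirely through the coarse bottleneck and
  plateaus near voxel Dice 0.75 on phantoms; with them it reaches 0.9+.
* **Streamline encoder `E_S`** — stride-2 1-D convolutions over the K x 3
  coordinate sequence, FiLM-modulated per channel by the conditioning
  vector, ending in a head that outputs the diagonal-Gaussian posterior
  (mu, sigma) over a low-dimensional latent code.  Positivity of sigma is
  enforced by exponentiating a log-sd head clamped to [log 1e-4, log 10].
* **Streamline decoder `D_S`** — the mirror image: a linear projection of
  the latent code to a coarse sequence, then upsampling 1-D convolutions
  with FiLM after every block, ending in a 3-channel head.  Coordinates
  pass through a fixed normalization (grid centre, half-extent scale) at
  the network boundary; losses are computed in millimetres.

During training the latent sample is `z = mu + eps * sigma` with
`eps ~ N(0, I)` (the reparameterization trick).  Validation and embedding
extraction use `z = mu` (no sampling), so those paths are deterministic.

FiLM layers are initialized to the identity modulation (gamma = 1,
beta = 0), so conditioning starts neutral and is learned.

### Losses

With lambda_SEG = lambda_VAE = lambda_ADJ = 1 and beta = 1 (the reference
settings, all configurable):

* segmentation: smoothed soft Dice,
  `1 - 2 (sum gt*pred + e) / (sum gt^2 + sum pred^2 + e)`, with
  e = 1e-6 by default — small enough not to bias the loss, large enough to
  avoid 0/0 on empty maps;
* VAE: per-streamline sum-of-squares reconstruction error over all 3K
  coordinates plus beta times the closed-form KL of the posterior from
  N(0, I), averaged over the batch.  The squared error is the *sum*, not
  the per-point mean: the literal squared norm.  This only rescales the
  balance against the other terms and is documented here because other
  implementations sometimes normalize per point;
* adjacency: for each streamline the average distance between the K - 1
  consecutive point pairs; the penalty is the batch mean plus the batch
  max of these averages.  The defining sum runs over the K - 1 existing
  pairs with a 1/(K - 1) prefactor, i.e. exactly the average gap.

### Training

Adam (betas 0.9/0.999, eps 1e-8) with one optimization step per subject
per epoch (single-subject batches; each step subsamples the subject's
streamlines).  The reference learning rate is 1e-4 with 1000 epochs and
3000 streamlines per bundle; the desk-scale configuration uses 1e-3,
100-150 epochs and 100-200 streamlines per step so a run fits in a few
minutes of one CPU core — at 1e-4 the same optimum is approached but far
outside that budget.  The checkpoint with the lowest total validation
loss is kept (ties to the earlier epoch).  All randomness (subsampling,
reparameterization draws) comes from a single seeded generator; two runs
with the same seed produce bitwise-identical histories.

Network arithmetic runs in float64 by default; the experiment driver
switches to float32, which halves CPU time and does not change any
qualitative outcome.  A finite-difference check of every layer's gradient
is part of the test suite (run in float64).

### Generation

After training, the posterior means of the training streamlines (encoded
under their own subject's anatomy) form the latent support cloud.  The
sampling density is a Gaussian-mixture KDE with one component per
embedding and a shared per-dimension bandwidth from Scott's rule,
`sd_d * n^(-1/(d+4))` (overridable scalar).  A new bundle for anatomy `x`
is generated by sampling latent vectors from the KDE — pick a support
point uniformly, add kernel noise — and decoding each conditioned on
`E_A(x)`.  The latent density itself is unconditional; only the decoder
sees the anatomy.  Population-level inference averages co-registered
volumes voxelwise (clipped to [0, 1]) and conditions on the average.

### Filtering and trimming

Generated bundles pass three rules: (i) discard streamlines with any
point outside the brain mask (an `endpoint`-only variant is available);
(ii) discard streamlines shorter than 20 mm; (iii) trim terminal points
outside the white-matter mask, except for streamlines with an endpoint in
an exception region (brainstem/cerebellum stand-in labels) or with
endpoints on opposite sides of the mid-sagittal plane, which pass
unchanged.  The WM "surface" is realized as the binary WM mask: a point
is beyond the surface iff its containing voxel is 0.  Trimming removes
only terminal excursions, never interior dips, and streamlines left with
fewer than two points are removed.  Both passes are idempotent.

## Coordinates and rasterization

World mm everywhere; voxel coordinates only at format boundaries.  Voxel
indexing is 0-based and a voxel's extent is the half-open unit cube
centred on its world coordinate (`floor(A^-1 p + 0.5)`).  Occupancy maps
are rasterized by segment-voxel traversal (Amanatides-Woo 3-D DDA), not
point membership, so long segments cannot skip voxels; segments that only
graze a voxel corner (zero intersection length) do not mark it, which
makes the voxel set identical to a dense point-sampling oracle.
Resampling to K points is linear interpolation at equal arc-length steps
along the input polyline, preserving endpoints exactly.  Re-applying the
resampler re-parameterizes by the new polyline's own chords, so exact
idempotence holds only for equal-chord inputs; on smooth densely-sampled
curves the drift is O(spacing^3 x curvature^2), far below a voxel.

## The phantom generator

Phantom subjects emulate the structure the mapping assumes: a
co-registered anatomical volume with paired curated bundles, ground-truth
masks and a parcellation.  What it emulates, and what it does not:

* **Grid**: 32^3 voxels at 1 mm isotropic — a desk-scale stand-in for a
  1 mm whole-head grid.  The brain mask is a superellipsoid (exponent 4, a
  rounded box), its white-matter core a concentric superellipsoid united
  with the dilated bundle tubes so every ground-truth point lies in WM.
* **Bundles**: centerlines from closed-form families (straight, circular
  arc, U-shape = arc of extent pi, helix) posed by a rotation and centre.
  Individual streamlines add a smooth low-order transverse offset —
  Gaussian coefficients on the first four cosine harmonics, projected
  perpendicular to the local tangent and capped at the tube radius — so
  they are differentiable curves filling a tube, never white noise.
  Radial (perpendicular) offsets widen the tube without shortening
  streamlines; default geometry keeps every unjittered streamline longer
  than 20 mm so the length filter is non-destructive on ground truth.
* **Contrast**: three tissue levels (background 0, grey-matter shell 0.5,
  WM 0.75) plus brighter bundle tubes (0.95), Gaussian-smoothed
  (sigma 0.7 voxels) with additive Gaussian noise (sd 0.02), clipped to
  [0, 1].  The brighter tube is the phantom's stand-in for the anatomical
  cues that make tract inference from structure possible at all; real
  T1-weighted contrast carries that information far more subtly, so
  passing on phantoms demonstrates the machinery, not clinical-grade
  inference.
* **Population variability**: per-subject Gaussian jitter (default sd
  0.75 mm, truncated at 2 sigma so every subject fits the shared grid) on
  bundle centres and primary sizes.  Subjects share the grid and
  parcellation topology, emulating co-registered data; no registration is
  performed anywhere.
* **Parcellation**: eight octant labels of the brain mask plus two
  inferior exception labels standing in for brainstem and cerebellum —
  enough structure for connectome metrics, no neuroanatomy.
* **Endpoint regions**: spheres around the head/tail endpoint centroids,
  sized to cover all endpoints, used by the validity metrics.
* Not modelled: diffusion signal, MR artifacts, surface meshes (the WM
  boundary is a mask), realistic cortical geometry.

## Evaluation metrics

* **Bundle adjacency (BA)**: symmetric fraction of streamlines whose
  minimum MDF distance (mean pointwise distance, minimized over flip) to
  the other bundle is below a threshold; default 5 mm, the customary
  value for this distance.
* **Coverage**: overlap = |C∩G|/|G|, overreach = |C\G|/|G| (may exceed
  1), Dice = 2|C∩G|/(|C|+|G|).  An alternate `dice_mode="harmonic"`
  (harmonic mean of overlap and 1/(1+overreach)) exists but is
  non-default: a harmonic mean of a similarity and an error rate is not a
  well-formed similarity score.
* **Validity**: a streamline is valid iff for some bundle its endpoints
  land one in each endpoint region and at least f = 0.9 of its points lie
  in the bundle mask (f configurable).  VS + IS = 1 identically.
* **Orientation**: tract orientation distribution maps accumulate each
  segment's in-voxel length times a real, even-order spherical-harmonic
  basis (lmax = 8) at its sign-normalized direction; antipodal symmetry
  is inherent to even orders.  The angular correlation coefficient is the
  per-voxel cosine similarity of coefficients of order l >= 2, averaged
  over voxels where the reference map is nonzero; voxels where either
  restricted vector vanishes contribute 0.
* **Geometry**: mean arc length, mean endpoint span, occupied-voxel
  volume, and surface area as exposed voxel faces (6-connectivity) times
  the face area; absolute percent differences are taken against the
  ground-truth bundle's values.
* **Connectivity**: endpoint-label streamline counts over the
  parcellation (background endpoints uncounted; normalization divides by
  the *total* streamline count), Pearson correlation of strictly-upper
  triangles, and graph summaries with reciprocal-weight edge lengths:
  density (undirected), characteristic path length (mean shortest path
  over connected pairs), global efficiency (mean inverse shortest path
  over all pairs, 0 for disconnected — the standard definition, not
  "inverse of CPL"), and Newman modularity of a deterministic greedy
  partition, checked against exhaustive partition search on small graphs.

## Desk-scale experiment

The bundled experiment driver trains one arc bundle on 8 phantom subjects
(validating on 2, testing on 1 held out), latent dimension 8, K = 32,
120 epochs at learning rate 1e-3 with 200 streamlines per step, then
generates 500 streamlines for the held-out subject, post-processes them
and runs all metric families.  One run takes about four minutes on one
CPU core.  Typical held-out results: thresholded segmentation Dice
0.87-0.93, generated-bundle voxel Dice 0.54-0.75, bundle adjacency 1.0.
These show the full pipeline learns subject-specific conditioning on
phantom contrast; they say nothing about real-data performance.

## Known limitations

* Phantom contrast makes bundle location visibly brighter than
  surrounding WM; real anatomical inference is much harder.
* The latent cloud of a small model trained briefly under-disperses:
  generated bundles cover the core of the tube more densely than its
  fringe (overlap < 1 with near-zero overreach after trimming).
  Longer training widens coverage.
* The validity ratio of generated bundles is sensitive to the endpoint
  regions' size; generated endpoints spread more than ground truth's.
* TOD angular correlation of generated bundles is limited by voxels the
  generated bundle misses (they contribute 0); it rises with coverage.
* One model per bundle (the default); a shared-architecture multi-bundle
  variant would amortize the anatomy encoder but is not implemented.
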