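"""Latent-space density estimation and conditional bundle synthesis.

After training, the posterior means of the training streamlines form an
empirical cloud in latent space.  A Gaussian kernel density estimate over
that cloud (one component per embedding, shared per-dimension bandwidth
from Scott's rule by default) defines the sampling distribution; new
bundles are generated by drawing latent vectors from it and decoding them
conditioned on the anatomy of the target subject (or of a population
template volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from atm.io import StreamlineSet, Volume3D
from atm.model import AtmModel, Checkpoint
from atm.phantom import PhantomSubject


@dataclass
class LatentDensity:
    """Gaussian-mixture KDE: one kernel per support point."""

    support: np.ndarray  # (n, d) training embeddings
    bandwidth: np.ndarray  # (d,) per-dimension kernel sd

    def __post_init__(self) -> None:
        self.support = np.atleast_2d(np.asarray(self.support, dtype=np.float64))
        self.bandwidth = np.broadcast_to(
            np.asarray(self.bandwidth, dtype=np.float64), (self.support.shape[1],)
        ).copy()
        if self.support.shape[0] < 1:
            raise ValueError("need at least one support point")
        if np.any(self.bandwidth <= 0):
            raise ValueError("bandwidth must be positive")

    @property
    def dim(self) -> int:
        return self.support.shape[1]

    def pdf(self, points: np.ndarray) -> np.ndarray:
        """Mixture density at the given (m, d) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        diff = (pts[:, None, :] - self.support[None, :, :]) / self.bandwidth
        log_norm = -0.5 * self.dim * np.log(2 * np.pi) - np.sum(
            np.log(self.bandwidth)
        )
        comp = np.exp(-0.5 * np.sum(diff**2, axis=2) + log_norm)
        return comp.mean(axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw: pick a support point uniformly, add kernel noise."""
        idx = rng.integers(0, len(self.support), size=n)
        noise = rng.standard_normal((n, self.dim)) * self.bandwidth
        return self.support[idx] + noise


def scott_bandwidth(embeddings: np.ndarray) -> np.ndarray:
    """Scott's rule per dimension: ``sd_d * n^(-1/(d+4))``.

    Dimensions with zero spread fall back to the mean positive bandwidth
    (or 1e-6 if the whole cloud is a single point).
    """
    emb = np.atleast_2d(embeddings)
    n, d = emb.shape
    sd = emb.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
    h = sd * n ** (-1.0 / (d + 4))
    if np.all(h <= 0):
        return np.full(d, 1e-6)
    h[h <= 0] = h[h > 0].mean()
    return h


def fit_latent_kde(
    embeddings: np.ndarray, bandwidth_rule: str | float = "scott"
) -> LatentDensity:
    """Fit the latent sampling density over training embeddings.

    ``bandwidth_rule`` is ``"scott"`` or an explicit positive scalar used
    for every dimension.
    """
    emb = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if emb.size == 0:
        raise ValueError("embeddings are empty")
    if not np.all(np.isfinite(emb)):
        raise ValueError("embeddings contain non-finite values")
    if isinstance(bandwidth_rule, str):
        if bandwidth_rule != "scott":
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        h = scott_bandwidth(emb)
    else:
        h = np.full(emb.shape[1], float(bandwidth_rule))
    return LatentDensity(support=emb, bandwidth=h)


def embed_training_streamlines(
    model: AtmModel, subjects, bundle_name: str, max_per_subject: int | None = None
) -> np.ndarray:
    """Posterior means of training streamlines under their own anatomy."""
    chunks = []
    for subject in subjects:
        batch = subject.bundles[bundle_name].as_array()
        if max_per_subject is not None:
            batch = batch[:max_per_subject]
        a = model.encode_anatomy(subject.t1_like)
        post = model.encode_streamlines(batch, a).numpy()
        chunks.append(post.mu)
    return np.concatenate(chunks, axis=0)


def sample_bundle(
    checkpoint: Checkpoint | AtmModel,
    density: LatentDensity,
    x: Volume3D,
    n: int,
    seed: int = 0,
    chunk: int = 512,
) -> StreamlineSet:
    """Generate ``n`` streamlines for the anatomy ``x``.

    Latent vectors are drawn from ``density`` and decoded conditioned on
    the anatomical features of ``x``.  Deterministic given ``seed``.
    """
    model = checkpoint.build_model() if isinstance(checkpoint, Checkpoint) else checkpoint
    if density.dim != model.config.latent_dim:
        raise ValueError(
            f"density dim {density.dim} != model latent dim {model.config.latent_dim}"
        )
    rng = np.random.default_rng(seed)
    a = model.encode_anatomy(x)
    lines: list[np.ndarray] = []
    remaining = n
    while remaining > 0:
        m = min(chunk, remaining)
        z = density.sample(m, rng)
        out = model.decode_latents(z, a).data
        lines.extend(np.asarray(s, dtype=np.float64) for s in out)
        remaining -= m
    return StreamlineSet(
        lines, reference_affine=x.affine.copy(), reference_shape=x.shape
    )


def population_template(volumes: list[Volume3D]) -> Volume3D:
    """Voxelwise mean of co-registered intensity volumes, clipped to [0,1]."""
    if not volumes:
        raise ValueError("no volumes given")
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            raise ValueError("volumes must share grid and affine")
    mean = np.mean([v.data for v in volumes], axis=0)
    return Volume3D(np.clip(mean, 0.0, 1.0), affine=first.affine.copy(), kind="intensity")
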