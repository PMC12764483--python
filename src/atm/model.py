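"""The anatomy-to-tract network.

Four coupled sub-networks:

* anatomy encoder ``E_A``: strided 3-D convolution stack over the intensity
  volume; its deepest map is flattened and projected to the fixed-length
  conditioning vector, and the per-level maps are kept as the multi-scale
  part of the anatomical features ``a``;
* segmentation decoder ``D_A``: mirrored upsampling stack reconstructing the
  bundle occupancy map from ``a``, consuming the multi-scale maps through
  skip connections (trained with Dice loss; its gradient shapes what ``a``
  encodes);
* streamline encoder ``E_S``: strided 1-D convolutions over the K-point
  coordinate sequence, FiLM-modulated by ``a``, producing the diagonal
  Gaussian posterior (mu, sigma) over the latent code;
* streamline decoder ``D_S``: upsampling 1-D convolutions from the latent
  code back to a K x 3 coordinate sequence, FiLM-modulated by ``a`` after
  every block.

Latent samples use the reparameterization ``z = mu + eps * sigma`` with
``eps ~ N(0, I)``.  Streamline coordinates are mapped to a normalized frame
(grid-centred, half-extent-scaled) at the network boundary; all losses and
outputs are in world mm.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from atm.io import StreamlineSet, Volume3D
from atm.nn import Adam, Conv1d, Conv3d, FiLM, Linear, Module, Tensor, UpConv3d
from atm.nn.tensor import upsample_nearest

_SIGMA_MIN, _SIGMA_MAX = 1e-4, 10.0


class ConfigError(ValueError):
    """Raised on shape/configuration mismatches."""


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``latent_dim`` defaults to the reference 64; the desk-scale experiments
    in the test-suite use 8.  ``n_points`` (K) must be divisible by 8
    because the streamline coder halves/doubles the sequence three times.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    latent_dim: int = 64
    cond_dim: int = 32
    n_points: int = 128
    anat_channels: tuple[int, ...] = (8, 16, 32, 32)
    line_channels: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.cond_dim < 1 or self.line_channels < 1:
            raise ConfigError("dimensions must be positive")
        if self.n_points % 8 != 0 or self.n_points < 8:
            raise ConfigError("n_points must be a positive multiple of 8")
        if any(s % (2 ** len(self.anat_channels)) for s in self.grid_shape):
            raise ConfigError(
                "grid_shape must be divisible by 2^levels of the anatomy encoder"
            )
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.anat_channels = tuple(int(c) for c in self.anat_channels)


@dataclass
class AnatomicalFeatures:
    """Conditioning representation extracted by the anatomy encoder.

    ``vector`` (1, cond_dim) conditions the streamline coder through FiLM;
    ``maps`` are the encoder's multi-scale feature volumes, consumed by the
    segmentation decoder through skip connections.
    """

    vector: Tensor
    maps: list[Tensor] = field(default_factory=list)


@dataclass
class GaussianPosterior:
    """Diagonal Gaussian posterior q(z | s, a): mean and sd vectors."""

    mu: np.ndarray | Tensor
    sigma: np.ndarray | Tensor

    def numpy(self) -> "GaussianPosterior":
        mu = self.mu.data if isinstance(self.mu, Tensor) else np.asarray(self.mu)
        sig = self.sigma.data if isinstance(self.sigma, Tensor) else np.asarray(self.sigma)
        return GaussianPosterior(mu, sig)


class AtmModel(Module):
    """The full anatomy-to-tract network (see module docstring)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.anat_channels
        c = config.line_channels
        k = config.n_points

        # anatomy encoder: len(ch) strided conv levels, pool, project
        self.enc_convs = [
            Conv3d(1 if i == 0 else ch[i - 1], ch[i], 3, rng, stride=2)
            for i in range(len(ch))
        ]
        # segmentation decoder: project, mirrored upsampling convs with
        # skip connections from the encoder's multi-scale feature maps
        self.bottom_shape = tuple(s // 2 ** len(ch) for s in config.grid_shape)
        nb = int(np.prod(self.bottom_shape))
        self.enc_proj = Linear(ch[-1] * nb, config.cond_dim, rng)
        self.dec_proj = Linear(config.cond_dim, ch[-1] * nb, rng)
        rev = list(reversed(ch))  # skip-map channels, deep to shallow
        dec_out_ch = rev[1:] + [rev[-1]]
        dec_in_ch = [ch[-1] + rev[0]] + [
            dec_out_ch[i - 1] + rev[i] for i in range(1, len(rev))
        ]
        self.dec_convs = [
            UpConv3d(dec_in_ch[i], dec_out_ch[i], 3, rng) for i in range(len(rev))
        ]
        self.dec_out = Conv3d(dec_out_ch[-1], 1, 3, rng)

        # streamline encoder: 3 strided conv blocks with FiLM
        self.line_enc_convs = [
            Conv1d(3 if i == 0 else c, c, 3, rng, stride=2) for i in range(3)
        ]
        self.line_enc_films = [FiLM(config.cond_dim, c, rng) for _ in range(3)]
        self.enc_head = Linear(c * (k // 8), 2 * config.latent_dim, rng)

        # streamline decoder: project, 3 upsampling conv blocks with FiLM
        self.dec_head = Linear(config.latent_dim, c * (k // 8), rng)
        self.line_dec_films = [FiLM(config.cond_dim, c, rng) for _ in range(4)]
        self.line_dec_convs = [Conv1d(c, c, 3, rng) for _ in range(3)]
        self.line_out = Conv1d(c, 3, 3, rng)

        # fixed world<->normalized coordinate map (grid centre, half extent)
        self._centre = (np.asarray(config.grid_shape, dtype=np.float64) - 1) / 2.0
        self._scale = np.asarray(config.grid_shape, dtype=np.float64) / 2.0

    # -- coordinate frame ----------------------------------------------------

    def normalize_points(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=np.float64) - self._centre) / self._scale

    def denormalize(self, pts):
        return pts * self._scale + self._centre

    # -- anatomy branch -------------------------------------------------------

    def encode_anatomy(self, x: Volume3D | np.ndarray) -> AnatomicalFeatures:
        """Anatomical features: conditioning vector + multi-scale maps."""
        data = x.data if isinstance(x, Volume3D) else np.asarray(x)
        if tuple(data.shape) != self.config.grid_shape:
            raise ConfigError(
                f"volume shape {data.shape} != configured grid {self.config.grid_shape}"
            )
        h = Tensor(data[None, None, :, :, :])
        maps = []
        for conv in self.enc_convs:
            h = conv(h).leaky_relu()
            maps.append(h)
        vector = self.enc_proj(h.reshape(1, -1))
        return AnatomicalFeatures(vector=vector, maps=maps)

    def decode_segmentation(self, a: AnatomicalFeatures) -> Tensor:
        """Soft occupancy prediction on the input grid, values in [0, 1]."""
        from atm.nn.tensor import concat

        ch_last = self.config.anat_channels[-1]
        h = self.dec_proj(a.vector).reshape(1, ch_last, *self.bottom_shape).leaky_relu()
        for conv, skip in zip(self.dec_convs, reversed(a.maps)):
            h = conv(concat([h, skip], axis=1)).leaky_relu()
        return self.dec_out(h).sigmoid().reshape(self.config.grid_shape)

    # -- streamline branch ----------------------------------------------------

    def encode_streamlines(
        self, batch: np.ndarray, a: AnatomicalFeatures
    ) -> GaussianPosterior:
        """Posterior for a batch of streamlines, (N, K, 3) world mm."""
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 2:
            batch = batch[None]
        if batch.shape[1] != self.config.n_points:
            raise ConfigError(
                f"streamlines have K={batch.shape[1]}, model expects "
                f"{self.config.n_points}"
            )
        h = Tensor(self.normalize_points(batch).transpose(0, 2, 1))  # (N,3,K)
        for conv, film in zip(self.line_enc_convs, self.line_enc_films):
            h = film(conv(h), a.vector).leaky_relu()
        n = h.shape[0]
        stats = self.enc_head(h.reshape(n, -1))  # (N, 2*latent)
        d = self.config.latent_dim
        mu = stats[:, :d]
        log_sd = stats[:, d:].clamp(np.log(_SIGMA_MIN), np.log(_SIGMA_MAX))
        return GaussianPosterior(mu, log_sd.exp())

    def decode_latents(self, z: Tensor | np.ndarray, a: AnatomicalFeatures) -> Tensor:
        """Decode latent codes (N, latent_dim) to streamlines (N, K, 3) mm."""
        z = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
        if z.shape[-1] != self.config.latent_dim:
            raise ConfigError(
                f"latent dim {z.shape[-1]} != configured {self.config.latent_dim}"
            )
        c = self.config.line_channels
        k8 = self.config.n_points // 8
        n = z.shape[0]
        h = self.dec_head(z).reshape(n, c, k8)
        h = self.line_dec_films[0](h, a.vector).leaky_relu()
        for conv, film in zip(self.line_dec_convs, self.line_dec_films[1:]):
            h = upsample_nearest(h, 2, (2,))
            h = film(conv(h), a.vector).leaky_relu()
        out = self.line_out(h).transpose(0, 2, 1)  # (N, K, 3) normalized
        return out * self._scale + self._centre


# ---------------------------------------------------------------------------
# Functional surface


def encode_anatomy(x: Volume3D, model: AtmModel) -> AnatomicalFeatures:
    return model.encode_anatomy(x)


def decode_segmentation(
    a: AnatomicalFeatures, model: AtmModel, grid_affine=None
) -> Volume3D:
    pred = model.decode_segmentation(a)
    affine = np.eye(4) if grid_affine is None else grid_affine
    return Volume3D(pred.data, affine=affine, kind="intensity")


def film_modulate(h, a, film: FiLM):
    """Apply one FiLM layer: ``gamma(a) * h + beta(a)`` per channel."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    a = a if isinstance(a, Tensor) else Tensor(np.atleast_2d(a))
    return film(h, a)


def encode_streamline(
    s: np.ndarray, a: AnatomicalFeatures, model: AtmModel
) -> GaussianPosterior:
    return model.encode_streamlines(np.asarray(s)[None], a)


def reparameterize(post: GaussianPosterior, epsilon):
    """``z = mu + eps * sigma`` elementwise; works on arrays and tensors."""
    eps = epsilon if isinstance(epsilon, (Tensor, np.ndarray)) else np.asarray(epsilon)
    return post.mu + eps * post.sigma


def decode_streamline(z, a: AnatomicalFeatures, model: AtmModel) -> np.ndarray:
    out = model.decode_latents(z, a)
    return out.data[0]


# ---------------------------------------------------------------------------
# Checkpointing


@dataclass
class Checkpoint:
    """Weights + config + training manifest, saved as a single .npz."""

    config: ModelConfig
    state: dict[str, np.ndarray]
    manifest: dict = field(default_factory=dict)

    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        arrays = {f"param/{k}": v for k, v in self.state.items()}
        meta = {
            "format_version": self.FORMAT_VERSION,
            "config": asdict(self.config),
            "manifest": self.manifest,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            state = {
                k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")
            }
        cfg = meta["config"]
        cfg["grid_shape"] = tuple(cfg["grid_shape"])
        cfg["anat_channels"] = tuple(cfg["anat_channels"])
        config = ModelConfig(**cfg)
        return cls(config=config, state=state, manifest=meta.get("manifest", {}))

    def build_model(self) -> AtmModel:
        model = AtmModel(self.config)
        model.load_state_dict(self.state)
        return model
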