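"""Network building blocks on top of the autodiff tensor.

Layers follow the channels-first convention: sequences are (N, C, L),
volumes are (N, C, D, H, W).
"""

from __future__ import annotations

import numpy as np

from atm.nn.tensor import Tensor, conv_nd, pad_nd, upsample_nearest


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        from atm.nn.tensor import get_default_dtype

        for name, p in params.items():
            arr = np.asarray(state[name], dtype=get_default_dtype())
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_scale: float | None = None, zero_init: bool = False):
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / n_in)
        w = np.zeros((n_in, n_out)) if zero_init else rng.normal(0, scale, (n_in, n_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution over (N, C, L) with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Tensor(
            rng.normal(0, scale, (c_in * kernel, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        x = pad_nd(x, self.pad, (2,))
        return conv_nd(x, self.weight, self.bias, self.kernel, self.stride)


class Conv3d(Module):
    """3-D convolution over (N, C, D, H, W) with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * kernel**3))
        self.weight = Tensor(
            rng.normal(0, scale, (c_in * kernel**3, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        x = pad_nd(x, self.pad, (2, 3, 4))
        return conv_nd(x, self.weight, self.bias, self.kernel, self.stride)


class UpConv3d(Module):
    """Nearest-neighbour x2 upsampling followed by a 3-D convolution."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv3d(c_in, c_out, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(upsample_nearest(x, 2, (2, 3, 4)))


class FiLM(Module):
    """Feature-wise linear modulation: ``out = gamma(a) * h + beta(a)``.

    ``gamma`` and ``beta`` are per-channel affine functions of the
    conditioning vector ``a``.  Initialized to the identity modulation
    (gamma = 1, beta = 0) so conditioning starts neutral.
    """

    def __init__(self, cond_dim: int, n_channels: int, rng: np.random.Generator):
        self.n_channels = n_channels
        self.gamma = Linear(cond_dim, n_channels, rng, zero_init=True)
        self.gamma.bias = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Linear(cond_dim, n_channels, rng, zero_init=True)

    def forward(self, h: Tensor, a: Tensor) -> Tensor:
        if h.shape[1] != self.n_channels:
            raise ValueError(
                f"FiLM channel mismatch: features have {h.shape[1]} channels, "
                f"layer modulates {self.n_channels}"
            )
        g = self.gamma(a)  # (N_a, C) or (C,)
        b = self.beta(a)
        # broadcast over trailing spatial dims of h: (N, C, *spatial)
        extra = h.ndim - 2
        shape = (-1, self.n_channels) + (1,) * extra
        return g.reshape(shape) * h + b.reshape(shape)
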