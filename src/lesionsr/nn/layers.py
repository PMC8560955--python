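"""Layer modules built on the autograd tensors.

Small torch-like Module hierarchy: parameters are named Tensors collected
recursively, initialisation follows the He-style rule sd = sqrt(2/m) with
m = f^2 * n_f (a paper-literal variant sd = 2/m is selectable), and every
module's forward is deterministic given its weights, the training flag
and an explicit RNG for dropout.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, dropout, leaky_relu, spp_pool

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "InstanceNorm2d",
    "SPPPool",
    "init_sd",
]


def init_sd(filter_size: int, n_filters: int, rule: str = "sqrt_2_over_m") -> float:
    """Weight-init standard deviation from m = f^2 * n_f.

    ``sqrt_2_over_m`` is the He rule sqrt(2/m) (default); ``2_over_m`` is
    the literal 2/m variant.
    """
    m = filter_size**2 * n_filters
    if m <= 0:
        raise ValueError("m = f^2 * n_f must be positive")
    if rule == "sqrt_2_over_m":
        return float(np.sqrt(2.0 / m))
    if rule == "2_over_m":
        return float(2.0 / m)
    raise ValueError(f"unknown init rule {rule!r}")


class Module:
    def modules(self):
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield attr
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                params[key] = attr
            elif isinstance(attr, Module):
                params.update(attr.named_parameters(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{key}.{i}."))
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state/parameter name mismatch: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 init_rule: str = "sqrt_2_over_m"):
        rng = rng or np.random.default_rng(0)
        sd = init_sd(kernel, c_out, init_rule)
        self.weight = Tensor(
            rng.normal(0.0, sd, (c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution via zero-upsampling + flipped-kernel convolution.

    Output spatial size is ``stride * input`` for kernel 2*stride and
    padding stride/2 (the configuration used in the reconstruction head).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 init_rule: str = "sqrt_2_over_m"):
        rng = rng or np.random.default_rng(0)
        sd = init_sd(kernel, c_out, init_rule)
        # stored in conv_transpose layout (Cin, Cout, kh, kw)
        self.weight = Tensor(
            rng.normal(0.0, sd, (c_in, c_out, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        s, k, p = self.stride, self.kernel, self.padding
        up = x.zero_upsample2d(s)
        # trim the trailing inserted zeros so out = (H-1)*s + 1 samples
        up = up.crop2d((up.shape[-2] - (s - 1), up.shape[-1] - (s - 1)))
        w = self.weight.flip((2, 3)).transpose((1, 0, 2, 3))
        return conv2d(up, w, self.bias, stride=1, padding=k - 1 - p)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        sd = float(np.sqrt(2.0 / n_in))
        self.weight = Tensor(rng.normal(0.0, sd, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.shift = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centred = x - mu
        var = (centred**2).mean(axis=(2, 3), keepdims=True)
        return centred / (var + self.eps).sqrt() * self.gain + self.shift


class SPPPool(Module):
    def __init__(self, levels: tuple[int, ...] = (4, 2, 1)):
        if not levels or list(levels) != sorted(levels, reverse=True) or min(levels) < 1:
            raise ValueError("spp levels must be nonempty, strictly decreasing, >= 1")
        if len(set(levels)) != len(levels):
            raise ValueError("spp levels must be strictly decreasing")
        self.levels = tuple(int(l) for l in levels)

    def output_length(self, channels: int) -> int:
        return channels * sum(l * l for l in self.levels)

    def __call__(self, x: Tensor) -> Tensor:
        return spp_pool(x, self.levels)


# re-exported activations for convenience
leaky_relu = leaky_relu
dropout = dropout
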