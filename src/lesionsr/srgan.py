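"""Cycle-consistent super-resolution GAN with an SPP discriminator.

Two generators are trained jointly — G maps degraded (LR) patches toward
high-resolution appearance, F maps HR patches toward LR appearance — with
a discriminator for each domain.  Because LR inputs live on the HR pixel
grid (nearest-neighbour pre-upsampling in the degradation pipeline), both
generators are same-grid image-to-image networks.

The training objective combines four terms:

* least-squares adversarial losses for both mappings,
* an l1 cycle-consistency loss, F(G(lr)) ~ lr and G(F(hr)) ~ hr,
* an l1 identity loss, G(hr) ~ hr and F(lr) ~ lr,
* a joint sparsifying (anisotropic total-variation) loss on G's output,

weighted 1 / 0.5 / 1e-5 for cycle / identity / TV by default.  Training
follows the two time-scale update rule: the generators' Adam learning
rate is half the discriminators' (gamma_G = gamma_D / 2), with
beta1 = 0.5, beta2 = 0.9.

The spatial pyramid pooling (SPP) layer in the discriminators turns any
admissible feature-map size into a fixed-length descriptor, so lesion
patches of different sizes can train one network.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dense,
    InstanceNorm2d,
    Module,
    SPPPool,
    Tensor,
    concat,
    dropout,
    leaky_relu,
)
from .nn.layers import init_sd
from .preprocess import PatchPair

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LossWeights",
    "TrainConfig",
    "ModelBundle",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "build_model",
    "adversarial_loss",
    "cycle_loss",
    "identity_loss",
    "jst_loss",
    "total_loss",
    "init_weights",
    "train",
    "super_resolve",
    "save_checkpoint",
    "load_checkpoint",
    "SMOKE_GENERATOR",
    "SMOKE_DISCRIMINATOR",
    "SMOKE_TRAIN",
]


def _default_filters() -> tuple[int, ...]:
    # taper 64 -> 16 across the twelve feature blocks
    return tuple(int(round(v)) for v in np.linspace(64, 16, 12))


@dataclass(frozen=True)
class GeneratorConfig:
    n_feature_blocks: int = 12
    conv_kernel: int = 3
    filters_per_block: tuple[int, ...] = field(default_factory=_default_filters)
    leaky_slope: float = 0.1
    dropout_rate: float = 0.8  # fraction dropped, as printed; configurable
    skip_concat: bool = True
    recon_filters: tuple[int, int] = (24, 8)  # network-in-network branch widths
    global_residual: bool = False  # output = input + correction (residual learning)
    init_rule: str = "sqrt_2_over_m"

    def validate(self) -> None:
        if self.n_feature_blocks < 1:
            raise ValueError("n_feature_blocks must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.filters_per_block) != self.n_feature_blocks:
            raise ValueError(
                f"filters_per_block has {len(self.filters_per_block)} entries "
                f"for {self.n_feature_blocks} blocks"
            )
        if any(f < 1 for f in self.filters_per_block):
            raise ValueError("filter counts must be >= 1")


@dataclass(frozen=True)
class DiscriminatorConfig:
    n_blocks: int = 4
    conv_kernel: int = 4
    filters: tuple[int, ...] = (32, 64, 64, 64)
    strides: tuple[int, ...] = (2, 2, 1, 1)
    instance_norm: bool = True
    leaky_slope: float = 0.1
    spp_levels: tuple[int, ...] = (4, 2, 1)
    dense_units: tuple[int, int] = (64, 1)
    init_rule: str = "sqrt_2_over_m"

    def validate(self) -> None:
        if len(self.filters) != self.n_blocks or len(self.strides) != self.n_blocks:
            raise ValueError("filters and strides must have n_blocks entries")
        if not self.spp_levels or list(self.spp_levels) != sorted(
            set(self.spp_levels), reverse=True
        ):
            raise ValueError("spp_levels must be nonempty, strictly decreasing, >= 1")
        if min(self.spp_levels) < 1:
            raise ValueError("spp_levels must all be >= 1")


@dataclass(frozen=True)
class LossWeights:
    lambda_cycle: float = 1.0
    lambda_identity: float = 0.5
    lambda_jst: float = 1e-5

    def validate(self) -> None:
        if min(self.lambda_cycle, self.lambda_identity, self.lambda_jst) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    lr_d: float = 1e-5
    lr_g: float | None = None  # None -> lr_d / 2 (two time-scale update rule)
    beta1: float = 0.5
    beta2: float = 0.9
    epochs: int = 100
    batch_size: int = 16
    adversarial_weight: float = 1.0  # 0 disables the GAN terms (ablations)
    lr_decay: str | None = None  # None (constant) or "linear" (to lr/epochs)
    seed: int = 0

    @property
    def gen_lr(self) -> float:
        return self.lr_d / 2.0 if self.lr_g is None else self.lr_g

    def validate(self) -> None:
        if self.lr_d < 0 or self.gen_lr < 0:
            raise ValueError("learning rates must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class Generator(Module):
    """Same-grid image-to-image generator.

    Feature extraction: ``n_feature_blocks`` 3x3 conv + bias + leaky ReLU +
    dropout blocks whose outputs are all concatenated (dense skip
    connections).  Reconstruction: two network-in-network 1x1 branches, a
    stride-2 convolution paired with a stride-2 transposed convolution
    (net output grid equals the input grid), and a final merging
    convolution down to one channel.  Odd input sides are zero-padded to
    even before the stride-2 pair and cropped back after.
    """

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        k = cfg.conv_kernel
        pad = k // 2
        self.blocks = []
        c_in = 1
        for f in cfg.filters_per_block:
            self.blocks.append(Conv2d(c_in, f, k, padding=pad, rng=rng,
                                      init_rule=cfg.init_rule))
            c_in = f
        c_cat = sum(cfg.filters_per_block) if cfg.skip_concat else c_in
        fa, fb = cfg.recon_filters
        self.branch_a = Conv2d(c_cat, fa, 1, rng=rng, init_rule=cfg.init_rule)
        self.branch_b1 = Conv2d(c_cat, fb, 1, rng=rng, init_rule=cfg.init_rule)
        self.branch_b2 = Conv2d(fb, fb, 3, padding=1, rng=rng, init_rule=cfg.init_rule)
        self.down = Conv2d(fa + fb, fa + fb, 3, stride=2, padding=1, rng=rng,
                           init_rule=cfg.init_rule)
        self.up = ConvTranspose2d(fa + fb, fa + fb, 4, stride=2, padding=1, rng=rng,
                                  init_rule=cfg.init_rule)
        self.merge = Conv2d(fa + fb, 1, 3, padding=1, rng=rng, init_rule=cfg.init_rule)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        if x.data.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N,1,H,W) input, got {x.shape}")
        slope = self.cfg.leaky_slope
        rng = rng or np.random.default_rng(0)
        h, w = x.shape[-2:]

        feats = []
        out = x
        for block in self.blocks:
            out = leaky_relu(block(out), slope)
            out = dropout(out, self.cfg.dropout_rate, rng, training)
            feats.append(out)
        cat = concat(feats, axis=1) if self.cfg.skip_concat else out

        a = leaky_relu(self.branch_a(cat), slope)
        b = leaky_relu(self.branch_b2(leaky_relu(self.branch_b1(cat), slope)), slope)
        y = concat([a, b], axis=1)
        pad_h, pad_w = h % 2, w % 2
        if pad_h or pad_w:
            y = y.pad2d((0, pad_h, 0, pad_w))
        y = leaky_relu(self.down(y), slope)
        y = leaky_relu(self.up(y), slope)
        if pad_h or pad_w:
            y = y.crop2d((h, w))
        out = self.merge(y)
        if self.cfg.global_residual:
            out = out + x
        return out


class Discriminator(Module):
    """Patch discriminator: conv blocks, SPP, two dense layers -> scalar score.

    The SPP layer makes the score independent of the input patch size, as
    long as the final feature map is at least ``max(spp_levels)`` on each
    side (see :meth:`min_input_size`).
    """

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        k = cfg.conv_kernel
        self.convs = []
        self.norms = []
        c_in = 1
        for f, s in zip(cfg.filters, cfg.strides):
            self.convs.append(Conv2d(c_in, f, k, stride=s, padding=1, rng=rng,
                                     init_rule=cfg.init_rule))
            self.norms.append(InstanceNorm2d(f) if cfg.instance_norm else None)
            c_in = f
        self.spp = SPPPool(cfg.spp_levels)
        d1, d2 = cfg.dense_units
        self.dense1 = Dense(self.spp.output_length(c_in), d1, rng=rng)
        self.dense2 = Dense(d1, d2, rng=rng)

    def min_input_size(self) -> int:
        """Smallest square input whose final feature map admits the SPP."""
        need = max(self.cfg.spp_levels)
        size = need
        for s in reversed(self.cfg.strides):
            k = self.cfg.conv_kernel
            # invert out = floor((in + 2*1 - k)/s) + 1
            size = (size - 1) * s + k - 2
        return size

    def _feature_size(self, size: int) -> int:
        for s in self.cfg.strides:
            size = (size + 2 - self.cfg.conv_kernel) // s + 1
        return size

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N,1,H,W) input, got {x.shape}")
        h, w = x.shape[-2:]
        need = max(self.cfg.spp_levels)
        if self._feature_size(h) < need or self._feature_size(w) < need:
            raise ValueError(
                f"input {h}x{w} too small for the SPP pyramid; "
                f"minimum side is {self.min_input_size()}"
            )
        out = x
        slope = self.cfg.leaky_slope
        for conv, norm in zip(self.convs, self.norms):
            out = conv(out)
            if norm is not None:
                out = norm(out)
            out = leaky_relu(out, slope)
        out = self.spp(out)
        out = leaky_relu(self.dense1(out), slope)
        return self.dense2(out)


@dataclass
class ModelBundle:
    """The four networks plus their configs and per-epoch training history."""

    G: Generator  # LR -> HR
    F: Generator  # HR -> LR
    D_HR: Discriminator
    D_LR: Discriminator
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    weights: LossWeights
    seed: int
    history: list[dict] = field(default_factory=list)


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator(cfg, np.random.default_rng(seed))


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(cfg, np.random.default_rng(seed))


def build_model(
    gen_cfg: GeneratorConfig | None = None,
    disc_cfg: DiscriminatorConfig | None = None,
    weights: LossWeights | None = None,
    seed: int = 0,
) -> ModelBundle:
    gen_cfg = gen_cfg or GeneratorConfig()
    disc_cfg = disc_cfg or DiscriminatorConfig()
    weights = weights or LossWeights()
    weights.validate()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    return ModelBundle(
        G=build_generator(gen_cfg, int(seeds[0])),
        F=build_generator(gen_cfg, int(seeds[1])),
        D_HR=build_discriminator(disc_cfg, int(seeds[2])),
        D_LR=build_discriminator(disc_cfg, int(seeds[3])),
        gen_cfg=gen_cfg,
        disc_cfg=disc_cfg,
        weights=weights,
        seed=seed,
    )


def init_weights(filter_size: int, n_filters: int, shape: tuple[int, ...],
                 seed: int = 0, rule: str = "sqrt_2_over_m") -> np.ndarray:
    """Draw a weight tensor from the zero-mean Gaussian init rule."""
    sd = init_sd(filter_size, n_filters, rule)
    return np.random.default_rng(seed).normal(0.0, sd, shape).astype(np.float32)


# ---------------------------------------------------------------------------
# loss terms (least-squares adversarial form)
# ---------------------------------------------------------------------------

def adversarial_loss(scores_real: Tensor, scores_fake: Tensor) -> dict[str, Tensor]:
    """Least-squares GAN terms from discriminator scores.

    ``discriminator``: mean (D(real) - 1)^2 + mean D(fake)^2, driving D
    toward 1 on real and 0 on fake; ``generator``: mean (D(fake) - 1)^2.
    """
    disc = ((scores_real - 1.0) ** 2).mean() + (scores_fake**2).mean()
    gen = ((scores_fake - 1.0) ** 2).mean()
    return {"discriminator": disc, "generator": gen}


def _l1(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).abs().mean()


def cycle_loss(g_of_f_hr: Tensor, hr: Tensor, f_of_g_lr: Tensor, lr: Tensor) -> Tensor:
    """Sum of the two l1 round-trip errors."""
    return _l1(f_of_g_lr, lr) + _l1(g_of_f_hr, hr)


def identity_loss(g_hr: Tensor, hr: Tensor, f_lr: Tensor, lr: Tensor) -> Tensor:
    """l1 distance of G(hr) to hr plus F(lr) to lr."""
    return _l1(g_hr, hr) + _l1(f_lr, lr)


def jst_loss(image: Tensor) -> Tensor:
    """Anisotropic total variation: mean |row diff| + mean |column diff|."""
    dv = image.slice2d(slice(1, None), slice(None)) - image.slice2d(
        slice(None, -1), slice(None)
    )
    dh = image.slice2d(slice(None), slice(1, None)) - image.slice2d(
        slice(None), slice(None, -1)
    )
    return dv.abs().mean() + dh.abs().mean()


def total_loss(
    bundle: ModelBundle,
    lr: Tensor,
    hr: Tensor,
    rng: np.random.Generator | None = None,
    training: bool = False,
    adversarial_weight: float = 1.0,
) -> tuple[Tensor, dict[str, float]]:
    """Generator-side composite objective with a per-term breakdown.

    total = w_adv * (L_adv(G) + L_adv(F)) + l1*cycle + l2*identity + l3*TV.
    The reported total equals the weighted sum of the reported terms
    exactly (same floating-point evaluation order).
    """
    w = bundle.weights
    rng = rng or np.random.default_rng(0)
    g_lr = bundle.G(lr, rng, training)
    f_hr = bundle.F(hr, rng, training)
    adv_g = adversarial_loss(bundle.D_HR(hr), bundle.D_HR(g_lr))["generator"]
    adv_f = adversarial_loss(bundle.D_LR(lr), bundle.D_LR(f_hr))["generator"]
    cyc = cycle_loss(bundle.G(f_hr, rng, training), hr, bundle.F(g_lr, rng, training), lr)
    idt = identity_loss(bundle.G(hr, rng, training), hr, bundle.F(lr, rng, training), lr)
    tv = jst_loss(g_lr)
    total = (
        adversarial_weight * (adv_g + adv_f)
        + w.lambda_cycle * cyc
        + w.lambda_identity * idt
        + w.lambda_jst * tv
    )
    breakdown = {
        "adv_G": float(adv_g.data),
        "adv_F": float(adv_f.data),
        "cycle": float(cyc.data),
        "identity": float(idt.data),
        "jst": float(tv.data),
        "total": float(total.data),
    }
    return total, breakdown


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_batches(pairs: list[PatchPair], batch_size: int,
                rng: np.random.Generator) -> list[list[PatchPair]]:
    """Shuffle, then group into batches of identical patch shape."""
    order = rng.permutation(len(pairs))
    by_shape: dict[tuple[int, int], list[PatchPair]] = {}
    for idx in order:
        by_shape.setdefault(pairs[idx].hr.shape, []).append(pairs[idx])
    batches = []
    for group in by_shape.values():
        for i in range(0, len(group), batch_size):
            batches.append(group[i : i + batch_size])
    return batches


def _stack(pairs: list[PatchPair]) -> tuple[Tensor, Tensor]:
    lr = np.stack([p.lr for p in pairs])[:, None].astype(np.float32)
    hr = np.stack([p.hr for p in pairs])[:, None].astype(np.float32)
    return Tensor(lr), Tensor(hr)


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss term {name!r}: {value}")


def train(pairs: list[PatchPair], bundle: ModelBundle, tcfg: TrainConfig,
          epoch_callback=None) -> ModelBundle:
    """Optimise the bundle on patch pairs; appends one history row per epoch.

    Per batch: one discriminator update (both discriminators, learning
    rate gamma_D) followed by one generator update (both generators,
    gamma_G = gamma_D/2 unless overridden).  History rows carry the mean
    of every objective term over the epoch's batches.  ``epoch_callback``
    (optional) is invoked as ``callback(epoch_index, bundle)`` after each
    epoch — e.g. for validation-based model selection.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    tcfg.validate()
    rng = np.random.default_rng(tcfg.seed)
    adam_kwargs = dict(beta1=tcfg.beta1, beta2=tcfg.beta2)
    opt_d = Adam(bundle.D_HR.parameters() + bundle.D_LR.parameters(),
                 lr=tcfg.lr_d, **adam_kwargs)
    opt_g = Adam(bundle.G.parameters() + bundle.F.parameters(),
                 lr=tcfg.gen_lr, **adam_kwargs)

    for epoch in range(tcfg.epochs):
        if tcfg.lr_decay == "linear":
            # anneal toward zero across the run to damp late-phase
            # adversarial oscillation (standard cycle-GAN practice)
            factor = 1.0 - epoch / tcfg.epochs
            opt_d.lr = tcfg.lr_d * factor
            opt_g.lr = tcfg.gen_lr * factor
        terms_acc: dict[str, list[float]] = {}
        for batch in _as_batches(pairs, tcfg.batch_size, rng):
            lr_t, hr_t = _stack(batch)

            # -- discriminator update (generators frozen) -----------------
            if tcfg.adversarial_weight > 0:
                fake_hr = Tensor(bundle.G(lr_t, rng, training=True).data)
                fake_lr = Tensor(bundle.F(hr_t, rng, training=True).data)
                d_hr = adversarial_loss(bundle.D_HR(hr_t), bundle.D_HR(fake_hr))
                d_lr = adversarial_loss(bundle.D_LR(lr_t), bundle.D_LR(fake_lr))
                d_total = d_hr["discriminator"] + d_lr["discriminator"]
                _check_finite("discriminator", float(d_total.data))
                opt_d.zero_grad()
                d_total.backward()
                opt_d.step()
                d_terms = {
                    "disc_HR": float(d_hr["discriminator"].data),
                    "disc_LR": float(d_lr["discriminator"].data),
                }
            else:
                d_terms = {"disc_HR": 0.0, "disc_LR": 0.0}

            # -- generator update -----------------------------------------
            g_total, breakdown = total_loss(
                bundle, lr_t, hr_t, rng, training=True,
                adversarial_weight=tcfg.adversarial_weight,
            )
            for name, value in breakdown.items():
                _check_finite(name, value)
            opt_g.zero_grad()
            bundle.D_HR.zero_grad()
            bundle.D_LR.zero_grad()
            g_total.backward()
            opt_g.step()

            for name, value in {**breakdown, **d_terms}.items():
                terms_acc.setdefault(name, []).append(value)

        bundle.history.append({k: float(np.mean(v)) for k, v in terms_acc.items()})
        if epoch_callback is not None:
            epoch_callback(epoch, bundle)
    return bundle


def super_resolve(bundle: ModelBundle, lr_image: np.ndarray, passes: int = 1) -> np.ndarray:
    """Apply G to a single [0,1] image ``passes`` times (dropout disabled).

    ``passes=2`` composes the 2x model with itself (the sequential
    two-instance composition used for 4x super-resolution).
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    img = np.asarray(lr_image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a single 2D image")
    out = img
    for _ in range(passes):
        t = Tensor(out[None, None])
        out = bundle.G(t, training=False).data[0, 0]
    return out


# ---------------------------------------------------------------------------
# checkpointing: single-file zip archive (JSON header + one .npy per weight)
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: ModelBundle, path: str | Path) -> None:
    header = {
        "gen_cfg": _cfg_dict(bundle.gen_cfg),
        "disc_cfg": _cfg_dict(bundle.disc_cfg),
        "weights": _cfg_dict(bundle.weights),
        "seed": bundle.seed,
        "epochs_trained": len(bundle.history),
        "history": bundle.history,
    }
    arrays: dict[str, np.ndarray] = {}
    for net_name in ("G", "F", "D_HR", "D_LR"):
        for pname, arr in getattr(bundle, net_name).state().items():
            arrays[f"{net_name}/{pname}"] = arr
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=2))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_checkpoint(path: str | Path) -> ModelBundle:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        arrays: dict[str, np.ndarray] = {}
        for info in zf.namelist():
            if info.startswith("weights/"):
                arrays[info[len("weights/") : -len(".npy")]] = np.load(
                    io.BytesIO(zf.read(info))
                )
    gen_cfg = GeneratorConfig(**_tupled(header["gen_cfg"]))
    disc_cfg = DiscriminatorConfig(**_tupled(header["disc_cfg"]))
    weights = LossWeights(**header["weights"])
    bundle = build_model(gen_cfg, disc_cfg, weights, seed=header["seed"])
    bundle.history = header["history"]
    for net_name in ("G", "F", "D_HR", "D_LR"):
        state = {
            k[len(net_name) + 1 :]: v
            for k, v in arrays.items()
            if k.startswith(net_name + "/")
        }
        getattr(bundle, net_name).load_state(state)
    return bundle


def _cfg_dict(cfg) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()}


def _tupled(d: dict) -> dict:
    return {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}


# Reduced-width configuration for CPU smoke benchmarks: same architecture
# family (2x same-grid generator, SPP discriminator), fewer/narrower blocks
# and a practical Adam step size so that a handful of epochs is meaningful.
SMOKE_GENERATOR = GeneratorConfig(
    n_feature_blocks=4,
    filters_per_block=(16, 12, 10, 8),
    dropout_rate=0.1,
    recon_filters=(8, 4),
)
SMOKE_DISCRIMINATOR = DiscriminatorConfig(filters=(8, 16, 16, 16))
SMOKE_TRAIN = TrainConfig(lr_d=4e-3, epochs=10, batch_size=16)
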