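"""The segmentation network: attention-gated encoder-decoder with two heads.

A symmetric U-shaped graph: the encoder alternates feature-extraction blocks
with 2x2 max pooling (the original image, resized to each level, feeds every
block's shallow branch), an optional ASPP sits at the bottleneck, and the
decoder alternates bilinear 2x upsampling with skip-concatenation blocks. Two
independent 1x1 heads emit a sigmoid object-probability channel and
``n_rays`` ReLU radial-distance channels, both at input resolution.

Encoder block variants (the ablation axis):

* ``TCB``      - two 3x3 conv-ReLU layers;
* ``TCB+RC``   - TCB plus a residual shortcut (1x1 projection on channel
  mismatch, identity otherwise);
* ``TCB+FFA``  - TCB gated by the feature-fusion attention unit driven by a
  shallow branch on the resized original image;
* ``RAE``      - attention gating and the residual shortcut together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from spcnet.nn import (
    Conv2d,
    Module,
    ParamStore,
    Tensor,
    concat,
    maxpool2x2,
    mul,
    relu,
    resize_bilinear,
    sigmoid,
    upsample_bilinear,
)

__all__ = ["NetworkConfig", "SPCNet", "ENCODER_VARIANTS"]

ENCODER_VARIANTS = ("TCB", "TCB+RC", "TCB+FFA", "RAE")


@dataclass
class NetworkConfig:
    n_rays: int = 32
    base_channels: int = 32
    n_levels: int = 3
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    encoder_variant: str = "RAE"
    use_aspp: bool = True
    dist_bias_init: float = 3.0  # keeps the ReLU distance head off its dead zone at init
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.encoder_variant not in ENCODER_VARIANTS:
            raise ValueError(
                f"encoder_variant must be one of {ENCODER_VARIANTS}, got {self.encoder_variant!r}"
            )
        self.aspp_rates = tuple(int(r) for r in self.aspp_rates)

    @property
    def stride(self) -> int:
        return 2 ** self.n_levels


class FFA(Module):
    """Feature-fusion attention: a single-channel sigmoid gate on deep features.

    ``Wa = sigmoid(phi(relu(We*Fe + Wo*Fo + bo)) + b_phi)``, applied as
    ``Fa = Wa . Fe`` with spatial broadcasting over channels.
    """

    def __init__(self, store, name, ch_e, ch_o, ch_att, rng, dtype):
        super().__init__(store, name)
        self.we = Conv2d(store, f"{name}.we", ch_e, ch_att, kernel=1, rng=rng, dtype=dtype)
        self.wo = Conv2d(store, f"{name}.wo", ch_o, ch_att, kernel=1, rng=rng, dtype=dtype)
        self.phi = Conv2d(store, f"{name}.phi", ch_att, 1, kernel=1, rng=rng, dtype=dtype)
        # we carries no separate bias in the formula; fold it away
        self.we.bias.data[:] = 0.0

    def __call__(self, fe: Tensor, fo: Tensor) -> Tensor:
        if fe.data.shape[2:] != fo.data.shape[2:]:
            raise ValueError(
                f"FFA spatial mismatch: Fe {fe.data.shape[2:]} vs Fo {fo.data.shape[2:]}"
            )
        psi = self.phi(relu(self.we(fe) + self.wo(fo)))
        wa = sigmoid(psi)  # (N, 1, H, W), open interval (0, 1)
        return mul(wa, fe)

    def attention_map(self, fe: Tensor, fo: Tensor) -> Tensor:
        return sigmoid(self.phi(relu(self.we(fe) + self.wo(fo))))


class EncoderBlock(Module):
    """One encoder stage in any of the four ablation variants."""

    def __init__(self, store, name, in_ch, out_ch, variant, rng, dtype):
        super().__init__(store, name)
        self.variant = variant
        self.c1 = Conv2d(store, f"{name}.c1", in_ch, out_ch, rng=rng, dtype=dtype)
        self.c2 = Conv2d(store, f"{name}.c2", out_ch, out_ch, rng=rng, dtype=dtype)
        if variant in ("TCB+FFA", "RAE"):
            self.o1 = Conv2d(store, f"{name}.o1", 1, out_ch, rng=rng, dtype=dtype)
            self.o2 = Conv2d(store, f"{name}.o2", out_ch, out_ch, rng=rng, dtype=dtype)
            self.ffa = FFA(store, f"{name}.ffa", out_ch, out_ch, max(out_ch // 2, 4), rng, dtype)
        if variant in ("TCB+RC", "RAE") and in_ch != out_ch:
            self.proj = Conv2d(store, f"{name}.proj", in_ch, out_ch, kernel=1, rng=rng, dtype=dtype)
        else:
            self.proj = None

    def __call__(self, x: Tensor, img: Tensor | None) -> Tensor:
        fe = self.c2(self.c1(x, activate=True), activate=True)
        if self.variant == "TCB":
            return fe
        if self.variant == "TCB+RC":
            return fe + (self.proj(x) if self.proj is not None else x)
        if img is None:
            raise ValueError(f"{self.variant} encoder needs the resized original image")
        if x.data.shape[2:] != img.data.shape[2:]:
            raise ValueError(
                f"encoder block spatial mismatch: x {x.data.shape[2:]} vs img {img.data.shape[2:]}"
            )
        fo = self.o2(self.o1(img, activate=True), activate=True)
        fa = self.ffa(fe, fo)
        if self.variant == "TCB+FFA":
            return fa
        return fa + (self.proj(x) if self.proj is not None else x)


class DecoderBlock(Module):
    """Feature recognition stage: skip-concat then two 3x3 conv-ReLU."""

    def __init__(self, store, name, in_ch, out_ch, rng, dtype):
        super().__init__(store, name)
        self.c1 = Conv2d(store, f"{name}.c1", in_ch, out_ch, rng=rng, dtype=dtype)
        self.c2 = Conv2d(store, f"{name}.c2", out_ch, out_ch, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        y = concat([x, skip], axis=1)
        return self.c2(self.c1(y, activate=True), activate=True)


class ASPP(Module):
    """Atrous spatial pyramid pooling: parallel dilated 3x3 branches + 1x1 fuse."""

    def __init__(self, store, name, ch, rates, rng, dtype):
        super().__init__(store, name)
        branch_ch = max(ch // len(rates), 1)
        self.branches = []
        for i, rate in enumerate(rates):
            if rate == 1:
                conv = Conv2d(store, f"{name}.b{i}", ch, branch_ch, kernel=1, rng=rng, dtype=dtype)
            else:
                conv = Conv2d(store, f"{name}.b{i}", ch, branch_ch, kernel=3, dilation=rate,
                              rng=rng, dtype=dtype)
            self.branches.append(conv)
        self.fuse = Conv2d(store, f"{name}.fuse", branch_ch * len(rates), ch, kernel=1,
                           rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        feats = [b(x, activate=True) for b in self.branches]
        return self.fuse(concat(feats, axis=1), activate=True)


class SPCNet:
    """Two-headed star-convex polygon segmentation network."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        store = ParamStore()
        self.store = store

        chans = [cfg.base_channels * 2 ** i for i in range(cfg.n_levels + 1)]
        self.encoders = []
        in_ch = 1
        for i in range(cfg.n_levels):
            self.encoders.append(
                EncoderBlock(store, f"enc{i}", in_ch, chans[i], cfg.encoder_variant, rng, dtype)
            )
            in_ch = chans[i]
        self.bottleneck = EncoderBlock(
            store, "bottleneck", in_ch, chans[-1], cfg.encoder_variant, rng, dtype
        )
        self.aspp = ASPP(store, "aspp", chans[-1], cfg.aspp_rates, rng, dtype) if cfg.use_aspp else None
        self.decoders = []
        up_ch = chans[-1]
        for i in reversed(range(cfg.n_levels)):
            self.decoders.append(DecoderBlock(store, f"dec{i}", up_ch + chans[i], chans[i], rng, dtype))
            up_ch = chans[i]
        self.prob_head = Conv2d(store, "prob_head", up_ch, 1, kernel=1, rng=rng, dtype=dtype)
        self.dist_head = Conv2d(store, "dist_head", up_ch, cfg.n_rays, kernel=1, rng=rng, dtype=dtype)
        self.dist_head.bias.data[:] = dtype(cfg.dist_bias_init)

    # ------------------------------------------------------------------ #

    @property
    def n_parameters(self) -> int:
        return self.store.n_parameters()

    def forward(self, x: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        """Run the graph on an (N, 1, H, W) batch; H, W must be divisible by
        2**n_levels (use :meth:`predict` for arbitrary sizes)."""
        cfg = self.config
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=cfg.dtype))
        n, c, h, w = x.data.shape
        if h == 0 or w == 0:
            raise ValueError("zero-sized input")
        if c != 1:
            raise ValueError(f"expected single-channel input, got {c} channels")
        if h % cfg.stride or w % cfg.stride:
            raise ValueError(f"spatial dims must be divisible by {cfg.stride}; got {h}x{w}")

        needs_pyramid = cfg.encoder_variant in ("TCB+FFA", "RAE")
        img = x.data

        skips = []
        t = x
        for i, enc in enumerate(self.encoders):
            shallow = None
            if needs_pyramid:
                lvl_shape = (h >> i, w >> i)
                shallow = Tensor(img if lvl_shape == img.shape[2:] else resize_bilinear(img, lvl_shape))
            t = enc(t, shallow)
            skips.append(t)
            t = maxpool2x2(t)
        shallow = None
        if needs_pyramid:
            t_shape = t.data.shape[2:]
            shallow = Tensor(resize_bilinear(img, t_shape))
        t = self.bottleneck(t, shallow)
        if self.aspp is not None:
            t = self.aspp(t)
        for dec, skip in zip(self.decoders, reversed(skips)):
            t = upsample_bilinear(t, 2)
            t = dec(t, skip)
        prob = sigmoid(self.prob_head(t))
        dist = relu(self.dist_head(t))
        return prob, dist

    def predict(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Forward a single (H, W) grayscale image of arbitrary size.

        Intensities are scaled to [0, 1]; non-divisible sizes are
        reflect-padded and the outputs cropped back. Returns
        ``(prob (H, W), dist (H, W, n_rays))`` numpy arrays.
        """
        image = np.asarray(image)
        if image.ndim != 2 or image.size == 0:
            raise ValueError("predict expects a non-empty 2-D grayscale image")
        x = image.astype(self.config.dtype)
        if x.max() > 1.5:  # integer-intensity input
            x = x / 255.0
        h, w = x.shape
        s = self.config.stride
        ph, pw = (-h) % s, (-w) % s
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
        prob, dist = self.forward(x[None, None])
        prob_np = prob.data[0, 0, :h, :w]
        dist_np = dist.data[0, :, :h, :w].transpose(1, 2, 0)
        return prob_np, dist_np

    # ------------------------------------------------------------------ #

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.store.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.store.load_state_dict(state)

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.state_dict())

    @classmethod
    def load(cls, path) -> "SPCNet":
        with np.load(path, allow_pickle=False) as npz:
            cfg_raw = json.loads(str(npz["__config__"]))
            cfg_raw["aspp_rates"] = tuple(cfg_raw["aspp_rates"])
            model = cls(NetworkConfig(**cfg_raw))
            model.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
        return model
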