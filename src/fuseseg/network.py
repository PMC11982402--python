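"""Anatomy-guided intermediate-fusion segmentation network.

The model takes co-registered PET and CT grids and produces a per-voxel tumor
probability map. Its three distinctive pieces:

* **Zero layers** — one per modality at the input: a convolution, ReLU, and a
  *learnable* normalization ``y = gamma * (x - mu) / sqrt(var + eps) + beta``
  whose scale (gamma), shift (beta) and stabilizer (eps) are all trained,
  absorbing residual inter-scanner intensity variation that fixed
  preprocessing cannot.
* **Squeeze-and-excite encoders** — parallel per-modality encoder stacks; each
  stage computes ``Enc = ReLU(Conv3(x))``, derives one multiplicative weight
  per channel via global average pooling and a two-layer bottleneck MLP with
  sigmoid output, modulates the features channel-wise, then max-pools
  (stride 2) and normalizes.
* **Anatomy-guided fusion decoder** — at every stage the excited PET and CT
  features are each average- then max-pooled (kernel 2, stride 1, shape
  preserving), reduced by a 1x1 convolution, summed and activated
  (``f_fused``); guidance multiplies ``f_fused`` element-wise by the excited
  CT features (or PET features, for the ablation); a 1x1 convolution, sigmoid
  and normalization give the stage's decoder output, which an upsampling path
  combines into the full-resolution mask.

Everything runs on the numpy autodiff engine in :mod:`fuseseg.autograd`;
arrays are laid out ``(channels, *spatial)`` with no batch axis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .exceptions import ConfigurationError, FusionError

__all__ = [
    "ModelConfig",
    "LearnableNorm",
    "ZeroLayer",
    "SqueezeExcite",
    "EncoderStage",
    "FusionBlock",
    "DecoderHead",
    "SegmentationModel",
    "BaselineUNet",
    "build_model",
    "build_baseline_unet",
    "count_parameters",
    "zero_layer_forward",
    "squeeze_excite",
    "encoder_stage_forward",
    "fuse",
    "anatomy_guide",
    "decoder_head",
    "save_weights",
    "load_weights",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of the fusion segmenter.

    ``encoder_filters`` follows the published schedule ``[128, 64, 32, 16]``
    (decreasing with depth); set ``reverse_filters`` for the conventional
    increasing ordering. ``se_reduction`` r gives SE bottleneck width
    ``max(1, C // r)``. ``fusion_activation`` selects the nonlinearity after
    the additive fusion (relu per the method's prose; sigmoid available).
    """

    dims: int = 3
    encoder_filters: tuple[int, ...] = (128, 64, 32, 16)
    zero_layer_filters: int = 16
    zero_layer_kernel: int = 3
    se_reduction: int = 4
    fusion_activation: str = "relu"
    fusion_post_conv: bool = True
    norm_eps_init: float = 1e-5
    use_zero_layer: bool = True
    use_se: bool = True
    guidance: str = "ct"
    reverse_filters: bool = False
    decoder_kernel: int = 1  # 1x1 convs keep the decoder lightweight

    def __post_init__(self):
        self.encoder_filters = tuple(int(f) for f in self.encoder_filters)
        if self.dims not in (2, 3):
            raise ConfigurationError(f"dims must be 2 or 3, got {self.dims}")
        if any(f < 1 for f in self.encoder_filters) or self.zero_layer_filters < 1:
            raise ConfigurationError("all filter counts must be >= 1")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")
        if self.fusion_activation not in ("relu", "sigmoid"):
            raise ConfigurationError(f"unknown fusion activation {self.fusion_activation!r}")
        if self.guidance not in ("ct", "pet"):
            raise ConfigurationError(f"guidance must be 'ct' or 'pet', got {self.guidance!r}")
        if self.norm_eps_init <= 0:
            raise ConfigurationError("norm_eps_init must be positive")

    @property
    def stage_filters(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_filters)) if self.reverse_filters else self.encoder_filters

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# module machinery
# ---------------------------------------------------------------------------

class Module:
    """Tiny container tracking parameters and submodules by name."""

    def __init__(self):
        self._params: list[tuple[str, Tensor]] = []
        self._children: list[tuple[str, "Module"]] = []

    def _param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(array, dtype=np.float32), requires_grad=True, name=name)
        self._params.append((name, t))
        return t

    def _child(self, name: str, mod: "Module") -> "Module":
        self._children.append((name, mod))
        return mod

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params:
            yield (f"{prefix}{name}", p)
        for cname, child in self._children:
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(1, fan_in))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv(Module):
    """Stride-1 'same' n-D convolution with bias."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, dims: int):
        super().__init__()
        kshape = (kernel,) * dims
        fan_in = in_ch * int(np.prod(kshape))
        self.w = self._param("w", _he_uniform(rng, (out_ch, in_ch) + kshape, fan_in))
        self.b = self._param("b", np.zeros(out_ch, dtype=np.float32))
        self.in_ch, self.out_ch = in_ch, out_ch

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] != self.in_ch:
            raise ConfigurationError(
                f"conv expects {self.in_ch} input channels, got {x.shape[0]}")
        return ag.conv_nd(x, self.w, self.b)


class LearnableNorm(Module):
    """Instance-style normalization with learnable gamma, beta and eps.

    Statistics are per channel over spatial positions. Positivity of eps is
    enforced by storing a raw parameter and mapping it through softplus, so
    eps stays > 0 under any gradient update.
    """

    def __init__(self, channels: int, eps_init: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.gamma = self._param("gamma", np.ones(channels, dtype=np.float32))
        self.beta = self._param("beta", np.zeros(channels, dtype=np.float32))
        # softplus(raw) == eps_init
        raw = np.log(np.expm1(np.float64(eps_init)))
        self.eps_raw = self._param("eps_raw", np.asarray(raw, dtype=np.float32))

    @property
    def eps(self) -> float:
        return float(np.logaddexp(0.0, self.eps_raw.data))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] != self.channels:
            raise ConfigurationError(
                f"norm expects {self.channels} channels, got {x.shape[0]}")
        eps = ag.softplus(self.eps_raw)
        return ag.instance_norm(x, self.gamma, self.beta, eps)


class ZeroLayer(Module):
    """Input block: Conv_k -> ReLU -> learnable normalization."""

    def __init__(self, rng, dims: int, filters: int, kernel: int, eps_init: float):
        super().__init__()
        self.conv = self._child("conv", Conv(rng, 1, filters, kernel, dims))
        self.norm = self._child("norm", LearnableNorm(filters, eps_init))

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(ag.relu(self.conv(x)))


class SqueezeExcite(Module):
    """Channel attention: sigmoid(FC2(ReLU(FC1(GAP(features)))))."""

    def __init__(self, rng, channels: int, reduction: int):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.channels, self.hidden = channels, hidden
        self.w1 = self._param("w1", _he_uniform(rng, (hidden, channels), channels))
        self.b1 = self._param("b1", np.zeros(hidden, dtype=np.float32))
        self.w2 = self._param("w2", _he_uniform(rng, (channels, hidden), hidden))
        self.b2 = self._param("b2", np.zeros(channels, dtype=np.float32))

    def __call__(self, enc: Tensor) -> Tensor:
        if enc.shape[0] != self.channels:
            raise ConfigurationError(
                f"SE block expects {self.channels} channels, got {enc.shape[0]}")
        g = enc.mean(axis=tuple(range(1, enc.ndim)))  # (C,)
        h = ag.relu(ag.matmul(self.w1, g) + self.b1)
        return ag.sigmoid(ag.matmul(self.w2, h) + self.b2)


class EncoderStage(Module):
    """One encoder stage: conv+ReLU, SE modulation, maxpool (stride 2), norm.

    Returns both the downsampled stage output and the pre-pool excited
    features, which the fusion decoder consumes at this resolution.
    """

    def __init__(self, rng, dims: int, in_ch: int, out_ch: int, reduction: int,
                 eps_init: float, use_se: bool = True):
        super().__init__()
        self.dims = dims
        self.use_se = use_se
        self.conv = self._child("conv", Conv(rng, in_ch, out_ch, 3, dims))
        if use_se:
            self.se = self._child("se", SqueezeExcite(rng, out_ch, reduction))
        self.norm = self._child("norm", LearnableNorm(out_ch, eps_init))
        self.pad_events: list[tuple[int, ...]] = []

    def __call__(self, x: Tensor, excitation_override: np.ndarray | None = None):
        enc = ag.relu(self.conv(x))
        if excitation_override is not None:
            exc_r = np.asarray(excitation_override, dtype=enc.data.dtype).reshape(
                (enc.shape[0],) + (1,) * self.dims)
            excited = enc * Tensor(exc_r)
        elif self.use_se:
            exc = self.se(enc)
            excited = enc * exc.reshape((enc.shape[0],) + (1,) * self.dims)
        else:
            excited = enc
        if any(s % 2 for s in excited.shape[1:]):
            self.pad_events.append(tuple(excited.shape[1:]))
        pooled = ag.maxpool_down(excited)
        return self.norm(pooled), excited


class FusionBlock(Module):
    """Pool/reduce each modality, add, activate; optional 1x1 mixing conv."""

    def __init__(self, rng, dims: int, channels: int, activation: str, post_conv: bool):
        super().__init__()
        self.activation = activation
        self.conv_pet = self._child("conv_pet", Conv(rng, channels, channels, 1, dims))
        self.conv_ct = self._child("conv_ct", Conv(rng, channels, channels, 1, dims))
        self.post_conv = self._child("post_conv", Conv(rng, channels, channels, 1, dims)) if post_conv else None

    def _pooled_features(self, m: Tensor) -> Tensor:
        return ag.maxpool_same(ag.avgpool_same(m))

    def __call__(self, pet_exc: Tensor, ct_exc: Tensor) -> Tensor:
        if pet_exc.shape != ct_exc.shape:
            raise FusionError(
                f"fusion inputs differ in shape: {pet_exc.shape} vs {ct_exc.shape}")
        pet_pf = self.conv_pet(self._pooled_features(pet_exc))
        ct_pf = self.conv_ct(self._pooled_features(ct_exc))
        s = pet_pf + ct_pf
        f = ag.relu(s) if self.activation == "relu" else ag.sigmoid(s)
        if self.post_conv is not None:
            f = self.post_conv(f)
        return f


class DecoderHead(Module):
    """Stage decoder output: Norm(sigmoid(Conv_1x1(guidance)))."""

    def __init__(self, rng, dims: int, channels: int, eps_init: float):
        super().__init__()
        self.conv = self._child("conv", Conv(rng, channels, channels, 1, dims))
        self.norm = self._child("norm", LearnableNorm(channels, eps_init))

    def __call__(self, guidance: Tensor) -> Tensor:
        return self.norm(ag.sigmoid(self.conv(guidance)))


def _guide(guide_exc: Tensor, f_fused: Tensor) -> Tensor:
    if guide_exc.shape != f_fused.shape:
        raise FusionError(
            f"guidance inputs differ in shape: {guide_exc.shape} vs {f_fused.shape}")
    return guide_exc * f_fused


# ---------------------------------------------------------------------------
# full models
# ---------------------------------------------------------------------------

class SegmentationModel(Module):
    """The full fusion segmenter: (PET, CT) -> per-voxel probability grid."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        dims = config.dims
        filters = config.stage_filters
        eps0 = config.norm_eps_init

        if config.use_zero_layer:
            self.zero_pet = self._child("zero_pet", ZeroLayer(
                rng, dims, config.zero_layer_filters, config.zero_layer_kernel, eps0))
            self.zero_ct = self._child("zero_ct", ZeroLayer(
                rng, dims, config.zero_layer_filters, config.zero_layer_kernel, eps0))
            in_ch = config.zero_layer_filters
        else:
            self.zero_pet = self.zero_ct = None
            in_ch = 1

        self.enc_pet: list[EncoderStage] = []
        self.enc_ct: list[EncoderStage] = []
        self.fusions: list[FusionBlock] = []
        self.heads: list[DecoderHead] = []
        prev = in_ch
        for i, f in enumerate(filters):
            self.enc_pet.append(self._child(f"enc_pet{i}", EncoderStage(
                rng, dims, prev, f, config.se_reduction, eps0, config.use_se)))
            self.enc_ct.append(self._child(f"enc_ct{i}", EncoderStage(
                rng, dims, prev, f, config.se_reduction, eps0, config.use_se)))
            self.fusions.append(self._child(f"fusion{i}", FusionBlock(
                rng, dims, f, config.fusion_activation, config.fusion_post_conv)))
            self.heads.append(self._child(f"head{i}", DecoderHead(rng, dims, f, eps0)))
            prev = f

        # upsampling path from the deepest pooled output back to full
        # resolution, combining each stage's decoder output element-wise
        self.up_convs: list[Conv] = []
        n = len(filters)
        for s in reversed(range(n)):
            cin = filters[s + 1] if s < n - 1 else filters[-1]
            self.up_convs.append(self._child(
                f"up{s}", Conv(rng, cin, filters[s], config.decoder_kernel, dims)))
        self.final = self._child("final", Conv(rng, filters[0], 1, 1, dims))

    # -- forward ------------------------------------------------------------
    def _check_input(self, pet: np.ndarray, ct: np.ndarray) -> None:
        dims = self.config.dims
        if pet.ndim != dims or ct.ndim != dims:
            raise ConfigurationError(
                f"model is {dims}-D but inputs have ranks {pet.ndim}, {ct.ndim}")
        if pet.shape != ct.shape:
            raise ConfigurationError(f"PET/CT shapes differ: {pet.shape} vs {ct.shape}")
        div = 2 ** len(self.config.stage_filters)
        if any(s % div for s in pet.shape):
            raise ConfigurationError(
                f"spatial shape {pet.shape} not divisible by {div}; pad or crop "
                f"to a multiple of {div}")

    def forward(self, pet: np.ndarray, ct: np.ndarray) -> Tensor:
        self._check_input(pet, ct)
        dims = self.config.dims
        x_pet = Tensor(np.asarray(pet, dtype=np.float32)[None])
        x_ct = Tensor(np.asarray(ct, dtype=np.float32)[None])
        if self.zero_pet is not None:
            x_pet = self.zero_pet(x_pet)
            x_ct = self.zero_ct(x_ct)
        excited_pet: list[Tensor] = []
        excited_ct: list[Tensor] = []
        for st_p, st_c in zip(self.enc_pet, self.enc_ct):
            x_pet, e_p = st_p(x_pet)
            x_ct, e_c = st_c(x_ct)
            excited_pet.append(e_p)
            excited_ct.append(e_c)

        dec_outs: list[Tensor] = []
        for i, (fus, head) in enumerate(zip(self.fusions, self.heads)):
            f_fused = fus(excited_pet[i], excited_ct[i])
            guide = excited_ct[i] if self.config.guidance == "ct" else excited_pet[i]
            dec_outs.append(head(_guide(guide, f_fused)))

        n = len(self.config.stage_filters)
        d = x_ct + x_pet  # deepest pooled outputs of both encoders, summed
        for j, s in enumerate(reversed(range(n))):
            target = dec_outs[s].shape[1:]
            d = ag.upsample_nearest(d, target_shape=target)
            d = ag.relu(self.up_convs[j](d))
            d = d + dec_outs[s]
        logits = self.final(d)
        probs = ag.sigmoid(logits)
        return probs.reshape(probs.shape[1:])

    __call__ = forward

    def predict_proba(self, pet: np.ndarray, ct: np.ndarray) -> np.ndarray:
        return self.forward(pet, ct).data


class BaselineUNet(Module):
    """Encoder-decoder UNet with doubling filters and skip connections,
    instance normalization after every convolution (standard modern practice;
    it also keeps the network trainable at the protocol's high initial lr).

    Serves two roles: the early-fusion comparator (PET and CT stacked as
    input channels) and, with ``in_channels=1``, the single-modality
    CT-only / PET-only variants. Parameter accounting for the
    fewer-parameters comparison uses this model at matched stage count.
    """

    def __init__(self, dims: int = 3, in_channels: int = 2, base_filters: int = 16,
                 n_stages: int = 4, seed: int = 0):
        super().__init__()
        self.dims = dims
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        self.enc_convs: list[Conv] = []
        self.enc_norms: list[LearnableNorm] = []
        filters = [base_filters * 2 ** i for i in range(n_stages)]
        self.filters = filters
        prev = in_channels
        for i, f in enumerate(filters):
            self.enc_convs.append(self._child(f"enc{i}", Conv(rng, prev, f, 3, dims)))
            self.enc_norms.append(self._child(f"enc{i}_norm", LearnableNorm(f)))
            prev = f
        self.bottleneck = self._child("bottleneck", Conv(rng, prev, prev * 2, 3, dims))
        self.bottleneck_norm = self._child("bottleneck_norm", LearnableNorm(prev * 2))
        self.dec_convs: list[Conv] = []
        self.dec_norms: list[LearnableNorm] = []
        prev = filters[-1] * 2
        for i, f in enumerate(reversed(filters)):
            self.dec_convs.append(self._child(f"dec{i}", Conv(rng, prev + f, f, 3, dims)))
            self.dec_norms.append(self._child(f"dec{i}_norm", LearnableNorm(f)))
            prev = f
        self.final = self._child("final", Conv(rng, filters[0], 1, 1, dims))

    def forward_channels(self, x: np.ndarray) -> Tensor:
        if x.ndim != self.dims + 1 or x.shape[0] != self.in_channels:
            raise ConfigurationError(
                f"expected ({self.in_channels}, *spatial) rank-{self.dims + 1} input, got {x.shape}")
        div = 2 ** len(self.enc_convs)
        if any(s % div for s in x.shape[1:]):
            raise ConfigurationError(
                f"spatial shape {x.shape[1:]} not divisible by {div}")
        t = Tensor(np.asarray(x, dtype=np.float32))
        skips: list[Tensor] = []
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            t = norm(ag.relu(conv(t)))
            skips.append(t)
            t = ag.maxpool_down(t)
        t = self.bottleneck_norm(ag.relu(self.bottleneck(t)))
        for conv, norm, skip in zip(self.dec_convs, self.dec_norms, reversed(skips)):
            t = ag.upsample_nearest(t, target_shape=skip.shape[1:])
            t = norm(ag.relu(conv(ag.concat([t, skip], axis=0))))
        probs = ag.sigmoid(self.final(t))
        return probs.reshape(probs.shape[1:])

    def forward(self, pet: np.ndarray, ct: np.ndarray) -> Tensor:
        if self.in_channels == 2:
            x = np.stack([pet, ct]).astype(np.float32)
        elif getattr(self, "modality", "ct") == "pet":
            x = np.asarray(pet, dtype=np.float32)[None]
        else:
            x = np.asarray(ct, dtype=np.float32)[None]
        return self.forward_channels(x)

    __call__ = forward

    def predict_proba(self, pet: np.ndarray, ct: np.ndarray) -> np.ndarray:
        return self.forward(pet, ct).data


# ---------------------------------------------------------------------------
# builders, accounting, serialization
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, seed: int = 0,
                input_shape: tuple[int, ...] | None = None) -> SegmentationModel:
    """Construct the fusion segmenter; validates ``input_shape`` if given."""
    model = SegmentationModel(config, seed=seed)
    if input_shape is not None:
        div = 2 ** len(config.stage_filters)
        if len(input_shape) != config.dims:
            raise ConfigurationError(
                f"input_shape rank {len(input_shape)} != dims {config.dims}")
        if any(s % div for s in input_shape):
            raise ConfigurationError(
                f"input shape {input_shape} not divisible by 2^{len(config.stage_filters)}")
    return model


def build_baseline_unet(dims: int = 3, in_channels: int = 2, base_filters: int = 16,
                        n_stages: int = 4, seed: int = 0,
                        modality: str = "ct") -> BaselineUNet:
    """Early-fusion UNet comparator; ``in_channels=1`` with ``modality`` picks
    the CT-only or PET-only variant."""
    model = BaselineUNet(dims=dims, in_channels=in_channels,
                         base_filters=base_filters, n_stages=n_stages, seed=seed)
    model.modality = modality
    return model


def count_parameters(model: Module) -> tuple[int, dict[str, int]]:
    """Exact trainable-scalar count with a per-block breakdown."""
    total = 0
    breakdown: dict[str, int] = {}
    for name, p in model.named_parameters():
        total += int(p.size)
        block = name.split(".")[0]
        breakdown[block] = breakdown.get(block, 0) + int(p.size)
    return total, breakdown


def save_weights(model: Module, path) -> None:
    arrays = {name: p.data for name, p in model.named_parameters()}
    meta = {}
    if isinstance(model, SegmentationModel):
        meta["config"] = json.dumps(asdict(model.config), default=list)
        meta["digest"] = model.config.digest()
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_weights(model: Module, path) -> None:
    with np.load(path, allow_pickle=False) as f:
        for name, p in model.named_parameters():
            arr = f[name]
            if arr.shape != p.data.shape:
                raise ConfigurationError(
                    f"checkpoint parameter {name} has shape {arr.shape}, model expects {p.data.shape}")
            p.data = arr.astype(np.float32)


# ---------------------------------------------------------------------------
# functional views of the individual operations (array in, array out)
# ---------------------------------------------------------------------------

def zero_layer_forward(vol: np.ndarray, zero_layer: ZeroLayer) -> np.ndarray:
    """Run one modality's zero layer on a single-channel grid."""
    x = np.asarray(vol, dtype=np.float32)
    if x.ndim == zero_layer.conv.w.data.ndim - 2:  # no channel axis supplied
        x = x[None]
    return zero_layer(Tensor(x)).data


def squeeze_excite(enc: np.ndarray, se: SqueezeExcite) -> np.ndarray:
    """Per-channel excitation weights in (0, 1) for a feature map."""
    return se(Tensor(np.asarray(enc, dtype=np.float32))).data


def encoder_stage_forward(x: np.ndarray, stage: EncoderStage,
                          excitation_override: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One encoder stage; returns (downsampled output, pre-pool excited)."""
    out, excited = stage(Tensor(np.asarray(x, dtype=np.float32)),
                         excitation_override=excitation_override)
    return out.data, excited.data


def fuse(pet_exc: np.ndarray, ct_exc: np.ndarray, fusion: FusionBlock) -> np.ndarray:
    """Intermediate fusion of excited PET and CT features (f_fused)."""
    return fusion(Tensor(np.asarray(pet_exc, dtype=np.float32)),
                  Tensor(np.asarray(ct_exc, dtype=np.float32))).data


def anatomy_guide(ct_exc: np.ndarray, f_fused: np.ndarray) -> np.ndarray:
    """Element-wise anatomical guidance: excited CT features * fused features."""
    a = np.asarray(ct_exc, dtype=np.float32)
    b = np.asarray(f_fused, dtype=np.float32)
    return _guide(Tensor(a), Tensor(b)).data


def decoder_head(ct_guidance: np.ndarray, head: DecoderHead) -> np.ndarray:
    """Stage decoder output from guided features."""
    return head(Tensor(np.asarray(ct_guidance, dtype=np.float32))).data
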