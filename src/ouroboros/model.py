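"""Conditional generator and dual-head discriminator/predictor.

The generator maps a noise vector z ~ N(0, I) and a transformed expression
vector p to an RGB patch in [-1, 1]: the concatenated (z, p) seeds a 4x4
feature grid that is doubled by residual up-sampling blocks until the
configured patch size is reached (so ``4 * 2**s == patch_size_px``), with p
re-injected at every stage through conditional channel normalisation and one
self-attention block at quarter resolution. The discriminator mirrors the
design with residual down-sampling blocks and ends in two heads on a shared
trunk: an unbounded realism logit and an n_markers expression prediction.

Architectures are fully size-configurable through :class:`ArchDescriptor`;
the same code instantiates 32-px test models and 256-px full-scale models.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn as nn
from .config import ConfigError


# ---------------------------------------------------------------------------
# architecture descriptor
# ---------------------------------------------------------------------------

def n_stages(patch_size_px: int) -> int:
    """Number of 2x resampling stages between a 4x4 grid and the patch size."""
    s = int(round(math.log2(patch_size_px / 4)))
    if 4 * 2 ** s != patch_size_px:
        raise ConfigError(
            f"patch_size_px must be 4 * 2**s for integer s, got {patch_size_px}")
    return s


def default_channels(patch_size_px: int, base_width: int = 64,
                     min_width: int = 8) -> tuple[int, ...]:
    """Channel widths from the 4x4 seed grid out to full resolution (halving)."""
    s = n_stages(patch_size_px)
    return tuple(max(base_width // 2 ** i, min_width) for i in range(s + 1))


@dataclass
class ArchDescriptor:
    """Size/width description shared by generator and discriminator."""

    patch_size_px: int = 64
    n_markers: int = 38
    noise_dim: int = 32
    base_width: int = 64
    min_width: int = 8
    attention: bool = True

    @property
    def stages(self) -> int:
        return n_stages(self.patch_size_px)

    @property
    def channels(self) -> tuple[int, ...]:
        return default_channels(self.patch_size_px, self.base_width, self.min_width)

    @property
    def attention_stage(self) -> int:
        """Index of the resampling block whose output resolution is patch/4.

        In the generator, block i outputs a 4 * 2**(i+1) px map; in the
        discriminator, block i outputs a patch / 2**(i+1) px map. Both reach
        quarter resolution at the same index.
        """
        return max(self.stages - 3, 0)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _Module:
    """Tiny module base: named parameter collection."""

    def parameters(self) -> list[nn.Parameter]:
        # __dict__ insertion order makes the traversal deterministic
        out = []
        for v in self.__dict__.values():
            if isinstance(v, nn.Parameter):
                out.append(v)
            elif isinstance(v, _Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, _Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self, prefix="") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, nn.Parameter):
                out[f"{prefix}{k}"] = v.data
            elif isinstance(v, _Module):
                out.update(v.state_arrays(f"{prefix}{k}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, _Module):
                        out.update(item.state_arrays(f"{prefix}{k}.{i}."))
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, nn.Parameter):
                v.data = np.asarray(arrays[f"{prefix}{k}"], dtype=np.float32)
            elif isinstance(v, _Module):
                v.load_state_arrays(arrays, f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, _Module):
                        item.load_state_arrays(arrays, f"{prefix}{k}.{i}.")


class Linear(_Module):
    def __init__(self, n_in, n_out, rng, gain=1.0, zero=False):
        if zero:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, gain * math.sqrt(2.0 / (n_in + n_out)),
                           size=(n_in, n_out))
        self.w = nn.Parameter(w)
        self.b = nn.Parameter(np.zeros(n_out))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.add(nn.matmul(x, self.w), self.b)


class Conv3x3(_Module):
    def __init__(self, c_in, c_out, rng, gain=1.0):
        w = rng.normal(0.0, gain * math.sqrt(2.0 / (9 * c_in)),
                       size=(3, 3, c_in, c_out))
        self.w = nn.Parameter(w)
        self.b = nn.Parameter(np.zeros(c_out))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.conv3x3(x, self.w, self.b)


class ChannelLinear(_Module):
    """1x1 convolution (pure channel mixing) used on residual skips."""

    def __init__(self, c_in, c_out, rng):
        self.w = nn.Parameter(rng.normal(0.0, math.sqrt(1.0 / c_in),
                                         size=(c_in, c_out)))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, h, w, c = x.shape
        flat = nn.reshape(x, (n * h * w, c))
        return nn.reshape(nn.matmul(flat, self.w), (n, h, w, self.w.shape[1]))


class CondNorm(_Module):
    """Conditional channel normalisation: per-channel scale/shift from p."""

    def __init__(self, channels, cond_dim, rng):
        self.gamma = Linear(cond_dim, channels, rng, zero=True)
        self.beta = Linear(cond_dim, channels, rng, zero=True)

    def __call__(self, x: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        xn = nn.channel_norm(x)
        n = x.shape[0]
        g = nn.reshape(self.gamma(cond), (n, 1, 1, x.shape[3]))
        b = nn.reshape(self.beta(cond), (n, 1, 1, x.shape[3]))
        one = nn.Tensor(np.ones((), dtype=np.float32))
        return nn.add(nn.mul(xn, nn.add(one, g)), b)


class SelfAttention(_Module):
    """Non-local self-attention over spatial positions (scaled dot-product)."""

    def __init__(self, channels, rng):
        dk = max(channels // 8, 4)
        dv = max(channels // 2, 4)
        self.q = nn.Parameter(rng.normal(0, math.sqrt(1.0 / channels), (channels, dk)))
        self.k = nn.Parameter(rng.normal(0, math.sqrt(1.0 / channels), (channels, dk)))
        self.v = nn.Parameter(rng.normal(0, math.sqrt(1.0 / channels), (channels, dv)))
        self.o = nn.Parameter(rng.normal(0, math.sqrt(1.0 / dv), (dv, channels)))
        self.gate = nn.Parameter(np.zeros(1))
        self._dk = dk

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, h, w, c = x.shape
        t = nn.reshape(x, (n, h * w, c))
        q = _proj(t, self.q)
        k = _proj(t, self.k)
        v = _proj(t, self.v)
        att = nn.softmax_lastdim(nn.scale(nn.bmm(q, nn.swap_last2(k)),
                                          1.0 / math.sqrt(self._dk)))
        out = _proj(nn.bmm(att, v), self.o)
        out = nn.mul(out, self.gate)
        return nn.add(x, nn.reshape(out, (n, h, w, c)))


def _proj(t: nn.Tensor, w: nn.Parameter) -> nn.Tensor:
    """(N, T, C) @ (C, D) -> (N, T, D) via flattening."""
    n, tt, c = t.shape
    return nn.reshape(nn.matmul(nn.reshape(t, (n * tt, c)), w),
                      (n, tt, w.shape[1]))


class ResBlockUp(_Module):
    """norm-relu-upsample-conv-norm-relu-conv with a learned upsampled skip."""

    def __init__(self, c_in, c_out, cond_dim, rng):
        self.n1 = CondNorm(c_in, cond_dim, rng)
        self.c1 = Conv3x3(c_in, c_out, rng)
        self.n2 = CondNorm(c_out, cond_dim, rng)
        self.c2 = Conv3x3(c_out, c_out, rng)
        self.skip = ChannelLinear(c_in, c_out, rng)

    def __call__(self, x: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.n1(x, cond))
        h = self.c1(nn.upsample2x(h))
        h = nn.relu(self.n2(h, cond))
        h = self.c2(h)
        return nn.add(h, self.skip(nn.upsample2x(x)))


class ResBlockDown(_Module):
    """relu-conv-relu-conv-pool with a pooled learned skip."""

    def __init__(self, c_in, c_out, rng):
        self.c1 = Conv3x3(c_in, c_out, rng)
        self.c2 = Conv3x3(c_out, c_out, rng)
        self.skip = ChannelLinear(c_in, c_out, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.c1(nn.leaky_relu(x))
        h = self.c2(nn.leaky_relu(h))
        h = nn.avgpool2x(h)
        return nn.add(h, self.skip(nn.avgpool2x(x)))


# ---------------------------------------------------------------------------
# generator / discriminator parameter collections
# ---------------------------------------------------------------------------

class GeneratorParams(_Module):
    """Trainable generator parameters theta_G plus its architecture."""

    def __init__(self, arch: ArchDescriptor, rng: np.random.Generator):
        self.arch = arch
        ch = arch.channels
        self.fc = Linear(arch.noise_dim + arch.n_markers, 4 * 4 * ch[0], rng)
        self.blocks = [ResBlockUp(ch[i], ch[i + 1], arch.n_markers, rng)
                       for i in range(arch.stages)]
        self.attn = SelfAttention(ch[arch.attention_stage + 1], rng) if arch.attention else None
        self.out_norm = CondNorm(ch[-1], arch.n_markers, rng)
        self.out_conv = Conv3x3(ch[-1], 3, rng, gain=0.5)

    def forward(self, p: nn.Tensor, z: nn.Tensor) -> nn.Tensor:
        n = p.shape[0]
        h = self.fc(nn.concat(z, p))
        h = nn.reshape(h, (n, 4, 4, self.arch.channels[0]))
        for i, blk in enumerate(self.blocks):
            h = blk(h, p)
            if self.attn is not None and i == self.arch.attention_stage:
                h = self.attn(h)
        h = nn.relu(self.out_norm(h, p))
        return nn.tanh(self.out_conv(h))

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class DiscriminatorParams(_Module):
    """Trainable discriminator parameters theta_D (shared trunk, two heads)."""

    def __init__(self, arch: ArchDescriptor, rng: np.random.Generator):
        self.arch = arch
        ch = arch.channels[::-1]  # mirror: thin at full res, wide at 4x4
        self.stem = Conv3x3(3, ch[0], rng)
        self.blocks = [ResBlockDown(ch[i], ch[i + 1], rng)
                       for i in range(arch.stages)]
        # attention after the block whose output is patch/4
        self.attn = (SelfAttention(ch[arch.attention_stage + 1], rng)
                     if arch.attention else None)
        self.head_real = Linear(ch[-1], 1, rng)
        self.head_pred = Linear(ch[-1], arch.n_markers, rng)

    def forward(self, images: nn.Tensor):
        """images: (N, P, P, 3) in [-1, 1] -> (realism logits (N,1), p_hat (N,m))."""
        if images.shape[1] != self.arch.patch_size_px:
            raise ValueError(
                f"discriminator expects {self.arch.patch_size_px}px images, "
                f"got {images.shape[1]}px")
        h = self.stem(images)
        for i, blk in enumerate(self.blocks):
            h = blk(h)
            if self.attn is not None and i == self.arch.attention_stage:
                h = self.attn(h)
        feat = nn.global_avg_pool(nn.leaky_relu(h))
        return self.head_real(feat), self.head_pred(feat)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def init_generator(arch: ArchDescriptor, seed: int) -> GeneratorParams:
    """Deterministically initialize generator parameters from a seed."""
    g = GeneratorParams(arch, np.random.default_rng(np.random.SeedSequence([seed, 0x6E])))
    return g


def init_discriminator(arch: ArchDescriptor, seed: int) -> DiscriminatorParams:
    """Deterministically initialize discriminator parameters from a seed."""
    return DiscriminatorParams(arch, np.random.default_rng(np.random.SeedSequence([seed, 0xD1])))


# ---------------------------------------------------------------------------
# functional interface
# ---------------------------------------------------------------------------

def _check_2d(name, x, width):
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != width:
        raise ValueError(f"{name} must have {width} entries per row, "
                         f"got shape {x.shape}")
    return x


def generate(params: GeneratorParams, p, z) -> np.ndarray:
    """Generate patches from expression vectors and noise.

    ``p``: (n, n_markers) transformed expression; ``z``: (n, noise_dim)
    standard-normal noise drawn by the caller. Returns float32 images in
    [-1, 1] with shape (n, P, P, 3); a single vector in gives a single image
    out.
    """
    arr_p = _check_2d("expression vector p", p, params.arch.n_markers)
    arr_z = _check_2d("noise vector z", z, params.arch.noise_dim)
    if arr_p.shape[0] != arr_z.shape[0]:
        raise ValueError("p and z must have the same number of rows")
    out = params.forward(nn.Tensor(arr_p), nn.Tensor(arr_z)).data
    if np.asarray(p).ndim == 1:
        return out[0]
    return out


def discriminate(params: DiscriminatorParams, images) -> tuple[np.ndarray, np.ndarray]:
    """Score realism and predict expression for images in [-1, 1].

    Returns ``(realism logits (n,), p_hat (n, n_markers))``; single image in
    gives scalars/vector out.
    """
    arr = np.asarray(images, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    logit, pred = params.forward(nn.Tensor(arr))
    if single:
        return float(logit.data[0, 0]), pred.data[0]
    return logit.data[:, 0], pred.data


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, generator: GeneratorParams,
                    discriminator: DiscriminatorParams | None = None) -> None:
    """Save parameters + architecture descriptor in one ``.npz`` container."""
    import hashlib
    import logging

    arrays = {f"G.{k}": v for k, v in generator.state_arrays().items()}
    if discriminator is not None:
        arrays.update({f"D.{k}": v for k, v in discriminator.state_arrays().items()})
    arrays["__arch__"] = np.frombuffer(
        json.dumps(generator.arch.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    with open(path, "rb") as fh:
        digest = hashlib.sha256(fh.read()).hexdigest()
    logging.getLogger(__name__).info("checkpoint %s sha256=%s", path, digest)


def load_checkpoint(path):
    """Load ``(generator, discriminator_or_None)`` from a checkpoint file."""
    with np.load(path) as data:
        arch = ArchDescriptor(**json.loads(bytes(data["__arch__"]).decode()))
        g = init_generator(arch, seed=0)
        g.load_state_arrays({k[2:]: data[k] for k in data.files if k.startswith("G.")})
        d = None
        if any(k.startswith("D.") for k in data.files):
            d = init_discriminator(arch, seed=0)
            d.load_state_arrays({k[2:]: data[k] for k in data.files if k.startswith("D.")})
    return g, d
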