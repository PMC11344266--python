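"""Conditional adversarial networks and losses for slice imputation.

One deterministic generator ``G`` maps a ``2·(2n+1)``-channel 2.5D
conditioning stack (DWI neighborhood + structural neighborhood) to the
single target DWI slice; a patch-level convolutional discriminator ``D``
scores (conditioning, candidate-slice) pairs.  The objective is the
classic conditional-GAN minimax value

    L_GAN(G, D) = E[log D(y)] + E[log(1 − D(G(x)))]

combined with an L1 reconstruction term weighted by ``λ`` (default 100):
``G* = arg min_G max_D  L_GAN(G, D) + λ·L_L1(G)``.

Intensities are handled in [0, 1] at the module boundary and mapped
affinely to the generator's internal tanh range [−1, 1].

The full-scale architecture is a residual-block encoder–decoder with 9
residual blocks; for small desk-scale grids the depth and width scale
down (see :func:`default_generator_spec`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .errors import ConfigurationError

SHELL_GROUPS = ("b0", "bweighted")
VIEWS = ("sagittal", "coronal")
BUNDLE_KEYS = tuple((g, v) for g in SHELL_GROUPS for v in VIEWS)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d:
    def __init__(self, c_in, c_out, k=3, stride=1, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(rng.normal(0.0, 0.02, (c_out, c_in, k, k))
                        .astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class ResBlock:
    def __init__(self, c, rng):
        self.c1 = Conv2d(c, c, rng=rng)
        self.c2 = Conv2d(c, c, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.c2(ag.relu(self.c1(x)))

    def params(self):
        return self.c1.params() + self.c2.params()


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture hyperparameters for one generator."""

    n: int = 7                    # neighbor half-width of the 2.5D stack
    width: int = 64               # base channel count
    n_blocks: int = 9             # residual blocks (at the bottleneck)
    n_down: int = 2               # stride-2 encoder/decoder stages
    out_channels: int = 1

    @property
    def in_channels(self) -> int:
        return 2 * (2 * self.n + 1)


def default_generator_spec(n: int, slice_size: int) -> GeneratorSpec:
    """Full-scale depth (9 blocks, width 64, two stride-2 stages) for
    ≥128² slices, a narrow shallow variant below that."""
    if slice_size >= 128:
        return GeneratorSpec(n=n, width=64, n_blocks=9, n_down=2)
    return GeneratorSpec(n=n, width=16, n_blocks=1, n_down=1)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch-level convolutional discriminator on (conditioning, slice)."""

    cond_channels: int
    width: int = 16
    n_layers: int = 2

    @property
    def in_channels(self) -> int:
        return self.cond_channels + 1


class ResnetGenerator:
    """Deterministic residual encoder–decoder; tanh output in [−1, 1].

    Stride-2 convolutions downsample ``n_down`` times, the residual
    blocks run at the bottleneck resolution, and nearest-neighbor
    upsampling + convolution restores the input resolution.
    """

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        self.inc = Conv2d(spec.in_channels, spec.width, rng=rng)
        self.down, self.up = [], []
        c = spec.width
        for _ in range(spec.n_down):
            self.down.append(Conv2d(c, c * 2, stride=2, rng=rng))
            c *= 2
        self.blocks = [ResBlock(c, rng) for _ in range(spec.n_blocks)]
        for _ in range(spec.n_down):
            self.up.append(Conv2d(c, c // 2, rng=rng))
            c //= 2
        self.out = Conv2d(c, spec.out_channels, rng=rng)

    @property
    def in_channels(self) -> int:
        return self.spec.in_channels

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.relu(self.inc(x))
        for conv in self.down:
            h = ag.relu(conv(h))
        for blk in self.blocks:
            h = blk(h)
        for conv in self.up:
            h = ag.upsample2x(ag.relu(conv(h)))
        return ag.tanh(self.out(h))

    def params(self):
        ps = self.inc.params()
        for conv in self.down:
            ps += conv.params()
        for blk in self.blocks:
            ps += blk.params()
        for conv in self.up:
            ps += conv.params()
        return ps + self.out.params()

    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.params()):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ConfigurationError("checkpoint/architecture mismatch")
            p.data = arr.astype(np.float32).copy()


class PatchDiscriminator:
    """Strided conv stack returning a map of real/fake logits."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        c = spec.in_channels
        self.layers = []
        w = spec.width
        for _ in range(spec.n_layers):
            self.layers.append(Conv2d(c, w, stride=2, rng=rng))
            c, w = w, w * 2
        self.final = Conv2d(c, 1, stride=1, rng=rng)

    def __call__(self, cond: Tensor, candidate: Tensor) -> Tensor:
        h = ag.concat([cond, candidate], axis=1)
        for layer in self.layers:
            h = ag.leaky_relu(layer(h), 0.2)
        return self.final(h)      # logits

    def params(self):
        ps = []
        for layer in self.layers:
            ps += layer.params()
        return ps + self.final.params()


def build_generator(spec: GeneratorSpec, seed: int = 0) -> ResnetGenerator:
    return ResnetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def adversarial_loss(d_real_scores, d_fake_scores) -> float:
    """Minimax GAN value ``E[log D(real)] + E[log(1 − D(fake))]``.

    Scores are discriminator probabilities in (0, 1).  The discriminator
    ascends this quantity, the generator descends its second term.
    """
    real = np.asarray(d_real_scores, dtype=np.float64)
    fake = np.asarray(d_fake_scores, dtype=np.float64)
    if not (np.all(np.isfinite(real)) and np.all(np.isfinite(fake))):
        raise ValueError("non-finite discriminator scores")
    if np.any((real <= 0) | (real >= 1)) or np.any((fake <= 0) | (fake >= 1)):
        raise ValueError("discriminator scores must lie strictly in (0, 1)")
    return float(np.mean(np.log(real)) + np.mean(np.log1p(-fake)))


def adversarial_loss_from_logits(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    """Numerically stable logit-space form of the minimax value.

    With ``D = sigmoid(logit)``: ``log D = −softplus(−logit)`` and
    ``log(1 − D) = −softplus(logit)``; agrees with
    :func:`adversarial_loss` on the corresponding probabilities.
    """
    return -ag.mean(ag.softplus(-real_logits)) - ag.mean(ag.softplus(fake_logits))


def generator_adversarial_term(fake_logits: Tensor) -> Tensor:
    """The generator-visible part ``E[log(1 − D(G(·)))]`` (minimized by G)."""
    return -ag.mean(ag.softplus(fake_logits))


def l1_loss(target_slice, generated_slice):
    """Mean absolute voxel difference; differentiable when given Tensors."""
    if isinstance(target_slice, Tensor) or isinstance(generated_slice, Tensor):
        t = target_slice if isinstance(target_slice, Tensor) else Tensor(target_slice)
        g = generated_slice if isinstance(generated_slice, Tensor) else Tensor(generated_slice)
        if t.shape != g.shape:
            raise ValueError(f"shape mismatch: {t.shape} vs {g.shape}")
        return ag.mean(ag.absolute(t - g))
    t = np.asarray(target_slice)
    g = np.asarray(generated_slice)
    if t.shape != g.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {g.shape}")
    return float(np.mean(np.abs(t - g)))


def total_generator_objective(adv_term, l1_term, lam: float):
    """Combined objective ``adv + λ·L1`` (λ ≥ 0)."""
    if lam < 0:
        raise ValueError("λ must be non-negative")
    if isinstance(adv_term, Tensor) or isinstance(l1_term, Tensor):
        adv = adv_term if isinstance(adv_term, Tensor) else Tensor(np.asarray(adv_term))
        l1 = l1_term if isinstance(l1_term, Tensor) else Tensor(np.asarray(l1_term))
        return adv + lam * l1
    return float(adv_term) + lam * float(l1_term)


# ---------------------------------------------------------------------------
# Inference-time forward pass
# ---------------------------------------------------------------------------

def to_internal(x: np.ndarray) -> np.ndarray:
    """[0, 1] normalized intensities -> generator-internal [−1, 1]."""
    return (2.0 * np.asarray(x, dtype=np.float32) - 1.0)


def from_internal(y: np.ndarray) -> np.ndarray:
    return (np.asarray(y, dtype=np.float32) + 1.0) / 2.0


def forward_generate(generator, input_stack: np.ndarray) -> np.ndarray:
    """Generate the target slice(s) for a [0, 1]-normalized input stack.

    Accepts ``(C, H, W)`` or ``(B, C, H, W)``; returns ``(H, W)`` or
    ``(B, H, W)`` in [0, 1].  Deterministic for fixed weights.
    """
    x = np.asarray(input_stack, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.ndim != 4 or x.shape[1] != generator.in_channels:
        raise ValueError(
            f"input stack must have {generator.in_channels} channels, "
            f"got shape {x.shape}")
    with ag.no_grad():
        y = generator(Tensor(to_internal(x))).data
    out = from_internal(y[:, 0])
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Model bundle (four generators: shell group × view)
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """The four trained generators keyed by (shell_group, view)."""

    generators: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, shell_group: str, view: str, generator, meta: dict | None = None):
        self.generators[(shell_group, view)] = generator
        if meta:
            self.metadata[f"{shell_group}_{view}"] = meta

    def get(self, shell_group: str, view: str):
        try:
            return self.generators[(shell_group, view)]
        except KeyError:
            raise ConfigurationError(
                f"no generator for shell group {shell_group!r}, view {view!r}")

    def require_complete(self):
        missing = [k for k in BUNDLE_KEYS if k not in self.generators]
        if missing:
            raise ConfigurationError(f"model bundle incomplete; missing {missing}")

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"keys": [], "metadata": self.metadata}
        for (group, view), gen in self.generators.items():
            name = f"{group}_{view}"
            np.savez(directory / f"{name}.npz", **gen.state_dict())
            manifest["keys"].append(
                {"shell_group": group, "view": view, "file": f"{name}.npz",
                 "spec": asdict(gen.spec)})
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise ConfigurationError(f"no manifest.json in {directory}")
        manifest = json.loads(manifest_path.read_text())
        bundle = cls(metadata=manifest.get("metadata", {}))
        for entry in manifest["keys"]:
            spec = GeneratorSpec(**entry["spec"])
            gen = build_generator(spec, seed=0)
            with np.load(directory / entry["file"]) as state:
                gen.load_state_dict(dict(state))
            bundle.generators[(entry["shell_group"], entry["view"])] = gen
        return bundle
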