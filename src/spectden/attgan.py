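"""Attention-guided conditional GAN for projection-domain SPECT denoising.

The generator is a 3D U-Net conditioned on the fast (short acquisition time)
projection stack; attention gates on the skip connections let distant voxels
modulate the local features that are forwarded to the decoder.  The
discriminator is a strided 3D CNN judging (fast, candidate) pairs.  The
objective is

    L = argmin_G max_D ( L_ADV(G, D) + lambda * L1(G) ),    lambda = 100,

with a non-saturating cross-entropy adversarial term.  Disabling the gates
yields the plain conditional-GAN generator; dropping the adversarial term
yields L1-only U-Net training — the two baselines nest structurally inside
the full model.

Attention-gate convention
-------------------------
The pairwise feature-dependency map alpha[i, j] = f(x_i)^T g(x_j) is dense in
the number of spatial positions N and is intractable at full resolution, so
the production gate uses a memory-linear restriction with position-matched
scores.  The inner product is kept resolved per channel and the softmax
normalizes over the channel axis:

    g = W_g x_enc,  f = W_f x_dec        (1x1x1 convolutions)
    u_i = ReLU(f_i * g_i)                (channel-resolved product at i;
                                          its channel sum is the diagonal
                                          alpha[i, i] of the dense map)
    e_i = psi(u_i)                       (1x1x1 convolution, C -> C)
    r_i = softmax over channels of e_i
    Att_i = C * r_i * x_enc_i

``r`` sums to one along its normalization axis (the channel axis) at every
position of every gate; the factor C makes the uniform case r = 1/C reduce
to the plain skip Att = x exactly, and bounds the per-channel gain by C.  In
the degenerate case W_f = 0 the scores are constant, r is uniform, and
Att = x — the closed form asserted by the unit tests.  A brute-force dense
alpha (for small feature maps) is the oracle: the channel sum of the
production inner products equals its diagonal, and at W_f = 0 both
formulations collapse to uniform weights.

An earlier spatial-axis softmax variant was abandoned: normalizing over
positions either amplifies single voxels by factors up to N (elementwise
use) or collapses the skip to a global context vector (pooled use), and
both measurably broke denoising at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Adam, BatchNorm, Conv1x1, Conv3d, Dropout, Module
from .projector import ProjectionStack

__all__ = [
    "GeneratorSpec", "TrainConfig", "GanLosses", "AttentionGate",
    "UNetGenerator", "PatchDiscriminator", "IdentityGenerator",
    "build_generator", "build_discriminator", "dense_attention_map",
    "train", "TrainResult", "Denoiser", "save_checkpoint", "load_checkpoint",
]

#: filter counts searched in the emulated hyper-parameter grid
FILTER_GRID = (8, 16, 24, 32, 40)


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the U-Net generator.

    ``n_levels`` counts encoder (= decoder) resolution levels; each level is
    one [conv(3x3x3) - BN - ReLU - dropout(0.5)] block, with max-pooling
    between encoder levels and nearest-neighbour upsampling between decoder
    levels.  ``base_filters`` is the filter count used in every layer.
    """

    n_levels: int = 3
    base_filters: int = 32
    dropout_rate: float = 0.5
    attention_enabled: bool = True
    in_channels: int = 1

    def __post_init__(self):
        if not (2 <= self.n_levels <= 5):
            raise ValueError("n_levels must be in 2..5")
        if self.base_filters < 1:
            raise ValueError("base_filters must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  The emulated protocol ran Adam at 1e-4 for
    400 epochs; the desk-scale default is 50 epochs at batch size 1."""

    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 1
    lambda_l1: float = 100.0
    adversarial: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class GanLosses:
    """One logged step/epoch of the composite objective."""

    l1: float
    l_adv: float
    l_d: float
    lam: float = 100.0

    @property
    def generator_objective(self) -> float:
        return self.l_adv + self.lam * self.l1


# ---------------------------------------------------------------------------
# modules

class ConvBlock(Module):
    """conv(3x3x3) -> batch norm -> ReLU -> dropout."""

    def __init__(self, c_in, c_out, rng, dropout_rate):
        super().__init__()
        self.conv = self.add_module(Conv3d(c_in, c_out, rng))
        self.bn = self.add_module(BatchNorm(c_out))
        self.drop = self.add_module(Dropout(dropout_rate, rng))

    def __call__(self, x):
        return self.drop(ag.relu(self.bn(self.conv(x))))


class AttentionGate(Module):
    """Soft attention on a skip connection (see module docstring)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.w_g = self.add_module(Conv1x1(channels, channels, rng, bias=False))
        self.w_f = self.add_module(Conv1x1(channels, channels, rng, bias=False))
        self.psi = self.add_module(Conv1x1(channels, channels, rng, bias=True))
        self.last_r: np.ndarray | None = None
        self.last_inner: np.ndarray | None = None

    def __call__(self, enc: Tensor, dec: Tensor) -> Tensor:
        if enc.shape != dec.shape:
            raise ValueError(
                f"attention gate: encoder features {enc.shape} and decoder "
                f"features {dec.shape} must match after resampling")
        g = self.w_g(enc)
        f = self.w_f(dec)
        inner = ag.mul(f, g)             # channel-resolved; sum = dense diagonal
        e = self.psi(ag.relu(inner))
        r = ag.softmax_channel(e)
        att = ag.mul(enc, ag.scale(r, float(self.channels)))
        self.last_inner = inner.data
        self.last_r = r.data
        return att


def dense_attention_map(f_features: np.ndarray, g_features: np.ndarray) -> np.ndarray:
    """Brute-force pairwise dependency map alpha[i, j] = f_i . g_j.

    ``f_features``/``g_features`` are (D, H, W, C) arrays of the projected
    decoder/encoder features.  O(N^2) memory — oracle use only, on feature
    maps of at most ~8^3 positions.  The production gate consumes the
    diagonal alpha[i, i] of this map.
    """
    c = f_features.shape[-1]
    f2 = f_features.reshape(-1, c)
    g2 = g_features.reshape(-1, c)
    return f2 @ g2.T


class UNetGenerator(Module):
    """Mirrored encoder/decoder U-Net with optional attention-gated skips."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        F = spec.base_filters
        self.enc = []
        c_in = spec.in_channels
        for _ in range(spec.n_levels):
            self.enc.append(self.add_module(ConvBlock(c_in, F, rng, spec.dropout_rate)))
            c_in = F
        self.bottleneck = self.add_module(ConvBlock(F, F, rng, spec.dropout_rate))
        self.dec = []
        self.gates = []
        for _ in range(spec.n_levels):
            self.dec.append(self.add_module(ConvBlock(2 * F, F, rng, spec.dropout_rate)))
            if spec.attention_enabled:
                self.gates.append(self.add_module(AttentionGate(F, rng)))
            else:
                self.gates.append(None)
        # small positive bias so the ReLU output head starts alive
        self.head = self.add_module(Conv1x1(F, 1, rng, bias=True, bias_init=0.01))

    def _check_shape(self, shape):
        div = 2 ** self.spec.n_levels
        bad = {f"axis{i}": (-s) % div for i, s in enumerate(shape, 1) if s % div}
        if bad:
            raise ValueError(
                f"input spatial shape {tuple(shape)} not divisible by {div}; "
                f"required zero-padding: {bad}")

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 5:
            raise ValueError("expected batched (B, D, H, W, C) input")
        self._check_shape(x.shape[1:4])
        skips = []
        h = x
        for blk in self.enc:
            h = blk(h)
            skips.append(h)
            h = ag.maxpool2(h)
        h = self.bottleneck(h)
        for lvl in range(self.spec.n_levels - 1, -1, -1):
            h = ag.upsample2(h)
            skip = skips[lvl]
            if self.gates[lvl] is not None:
                skip = self.gates[lvl](skip, h)
            h = self.dec[lvl](ag.concat([h, skip], axis=-1))
        return ag.relu(self.head(h))


class PatchDiscriminator(Module):
    """Strided 3D CNN on channel-concatenated (condition, candidate) pairs.

    Four stride-2 levels (filters 32, 64, 128, 256), LeakyReLU(0.2), batch
    norm from the second level, and a pointwise head producing patch logits.
    """

    FILTERS = (32, 64, 128, 256)

    def __init__(self, rng: np.random.Generator, in_channels: int = 2):
        super().__init__()
        self.convs, self.bns = [], []
        c_in = in_channels
        for lvl, f in enumerate(self.FILTERS):
            self.convs.append(self.add_module(Conv3d(c_in, f, rng, stride=2)))
            self.bns.append(self.add_module(BatchNorm(f)) if lvl > 0 else None)
            c_in = f
        self.head = self.add_module(Conv1x1(c_in, 1, rng))

    def __call__(self, condition: Tensor, candidate: Tensor) -> Tensor:
        if condition.data.ndim != 5 or candidate.data.ndim != 5:
            raise ValueError("discriminator expects batched (B, D, H, W, C) inputs")
        if condition.shape != candidate.shape:
            raise ValueError("condition and candidate shapes must match")
        h = ag.concat([condition, candidate], axis=-1)
        for conv, bn in zip(self.convs, self.bns):
            h = conv(h)
            if bn is not None:
                h = bn(h)
            h = ag.leaky_relu(h, 0.2)
        return self.head(h)  # (B, d, h, w, 1) patch logits

    def mean_logit(self, condition: Tensor, candidate: Tensor) -> float:
        return float(self(condition, candidate).data.mean())


class IdentityGenerator:
    """Test double with the generator interface that returns its input."""

    spec = GeneratorSpec(attention_enabled=False)

    def train(self):
        pass

    def eval(self):
        pass

    def __call__(self, x: Tensor) -> Tensor:
        return x


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, np.random.default_rng([seed, 101]))


def build_discriminator(seed: int = 0, in_channels: int = 2) -> PatchDiscriminator:
    return PatchDiscriminator(np.random.default_rng([seed, 202]), in_channels=in_channels)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainResult:
    generator: UNetGenerator
    history: pd.DataFrame
    best_epoch: int
    best_val_l1: float
    manifest: dict


def _as_input(sample: preprocess.TrainingSample, defect_conditioned: bool) -> np.ndarray:
    arr = sample.input_stack
    if defect_conditioned:
        arr = preprocess.embed_defect_block(arr, sample.defect_label)
    return arr.astype(np.float32)[..., None]


def train(pairs, cfg: TrainConfig, spec: GeneratorSpec,
          val_pairs=(), defect_conditioned: bool = False,
          time_level_s: float | None = None) -> TrainResult:
    """Train a generator (and, if adversarial, a discriminator).

    ``pairs`` are :class:`~spectden.preprocess.TrainingSample` objects; all
    stacks must share one shape.  When ``defect_conditioned`` the binary
    defect block is appended to the generator input and the four extra
    output slices are stripped before any loss is evaluated (the
    discriminator likewise only sees the projection views).

    Returns the generator restored to the best-validation-L1 checkpoint
    (final epoch when no validation pairs are given) plus a per-epoch loss
    history.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng([cfg.rng_seed, 7])
    G = build_generator(spec, seed=cfg.rng_seed)
    D = build_discriminator(seed=cfg.rng_seed) if cfg.adversarial else None
    opt_g = Adam(G.parameters(), lr=cfg.learning_rate)
    opt_d = Adam(D.parameters(), lr=cfg.learning_rate) if D is not None else None

    xs = np.stack([_as_input(s, defect_conditioned) for s in pairs])
    ys = np.stack([s.target_stack.astype(np.float32)[..., None] for s in pairs])
    n_views = ys.shape[1]
    val_x = (np.stack([_as_input(s, defect_conditioned) for s in val_pairs])
             if len(val_pairs) else None)
    val_y = (np.stack([s.target_stack.astype(np.float32)[..., None] for s in val_pairs])
             if len(val_pairs) else None)

    rows = []
    best_val = np.inf
    best_epoch = -1
    best_state = None
    for epoch in range(cfg.epochs):
        G.train()
        if D is not None:
            D.train()
        order = rng.permutation(len(pairs))
        ep_l1 = ep_adv = ep_d = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            x = Tensor(xs[sel])
            y = Tensor(ys[sel])
            cond = ag.narrow_views(x, n_views) if defect_conditioned else x

            fake_full = G(x)
            fake = (ag.narrow_views(fake_full, n_views)
                    if defect_conditioned else fake_full)
            l1 = ag.l1_mean(fake, y)
            if D is not None:
                adv = ag.bce_with_logits_mean(D(cond, fake), 1.0)
                loss_g = ag.add(adv, ag.scale(l1, cfg.lambda_l1))
            else:
                adv = None
                loss_g = l1
            if not np.isfinite(loss_g.item()):
                raise RuntimeError(
                    f"non-finite generator loss at epoch {epoch}: "
                    f"l1={l1.item():.4g} adv={adv.item() if adv else 0:.4g}")
            opt_g.zero_grad()
            loss_g.backward()
            opt_g.step()

            d_val = 0.0
            if D is not None:
                # real and fake pairs in one batched pass (labels 1 / 0)
                cond2 = ag.concat([cond, cond], axis=0)
                cand2 = ag.concat([y, fake.detach()], axis=0)
                nb = y.shape[0]
                labels = np.concatenate(
                    [np.ones(nb, np.float32), np.zeros(nb, np.float32)]
                ).reshape(2 * nb, 1, 1, 1, 1)
                loss_d = ag.scale(
                    ag.bce_with_logits_mean(D(cond2, cand2), labels), 2.0)
                if not np.isfinite(loss_d.item()):
                    raise RuntimeError(f"non-finite discriminator loss at epoch {epoch}")
                opt_d.zero_grad()
                loss_d.backward()
                opt_d.step()
                d_val = loss_d.item()

            ep_l1 += l1.item()
            ep_adv += adv.item() if adv is not None else 0.0
            ep_d += d_val
            n_batches += 1

        row = {"epoch": epoch, "l1": ep_l1 / n_batches,
               "l_adv": ep_adv / n_batches, "l_d": ep_d / n_batches}
        if val_x is not None:
            G.eval()
            out = G(Tensor(val_x))
            out_d = out.data[:, :n_views] if defect_conditioned else out.data
            row["val_l1"] = float(np.abs(out_d - val_y).mean())
            if row["val_l1"] < best_val:
                best_val = row["val_l1"]
                best_epoch = epoch
                best_state = G.state_dict()
        rows.append(row)

    if best_state is not None:
        G.load_state_dict(best_state)
    else:
        best_epoch = cfg.epochs - 1
        best_val = float("nan")
    G.eval()
    manifest = {
        "generator_spec": asdict(spec),
        "train_config": asdict(cfg),
        "defect_conditioned": defect_conditioned,
        "time_level_s": time_level_s,
        "n_views": int(n_views),
    }
    return TrainResult(generator=G, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_l1=best_val,
                       manifest=manifest)


# ---------------------------------------------------------------------------
# inference

@dataclass
class Denoiser:
    """Trained generator plus the preprocessing contract it was trained with."""

    generator: UNetGenerator | IdentityGenerator
    defect_conditioned: bool = False
    time_level_s: float | None = None
    n_levels: int = 3
    meta: dict = field(default_factory=dict)

    def denoise(self, stack: ProjectionStack, defect_label: int | None = None,
                norm_scale: float | None = None) -> ProjectionStack:
        """Estimate the full-time projections from a fast stack.

        ``norm_scale`` is the full-time normalization scale of the subject
        (shared-scale convention); when absent the stack's own maximum is
        used.  Output counts are non-negative and on the de-normalized count
        scale.
        """
        import warnings

        if (self.time_level_s is not None
                and not np.isclose(stack.time_per_view_s, self.time_level_s)):
            warnings.warn(
                f"model trained at {self.time_level_s} s/view applied to a "
                f"{stack.time_per_view_s} s/view stack (dose-specific mismatch)",
                RuntimeWarning)
        arr, scale = preprocess.normalize(stack, scale=norm_scale)
        n_views = arr.shape[0]
        if self.defect_conditioned:
            if defect_label is None:
                raise ValueError("defect-conditioned model requires a defect_label")
            arr = preprocess.embed_defect_block(arr, defect_label)
        arr, orig = preprocess.pad_views(arr, 2 ** self.n_levels)
        self.generator.eval()
        out = self.generator(Tensor(arr.astype(np.float32)[None, ..., None]))
        est = out.data[0, ..., 0].astype(np.float64)
        est = preprocess.unpad_views(est, orig)
        if self.defect_conditioned:
            est = est[:n_views]
        est = np.maximum(est, 0.0)
        counts = preprocess.denormalize(est, scale)
        return ProjectionStack(
            counts=counts, angles_deg=stack.angles_deg,
            time_per_view_s=stack.time_per_view_s, is_noisy=False,
            meta={**stack.meta, "denoised": True,
                  "model_time_level_s": self.time_level_s})


def save_checkpoint(result: TrainResult, path: str | Path) -> Path:
    """Serialize generator weights (npz) plus a JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = result.generator.state_dict()
    np.savez_compressed(path, **state)
    path.with_suffix(".json").write_text(json.dumps(result.manifest, indent=2))
    return path


def load_checkpoint(path: str | Path) -> Denoiser:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = GeneratorSpec(**manifest["generator_spec"])
    G = build_generator(spec, seed=manifest["train_config"]["rng_seed"])
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        G.load_state_dict({k: z[k] for k in z.files})
    G.eval()
    return Denoiser(generator=G,
                    defect_conditioned=manifest["defect_conditioned"],
                    time_level_s=manifest["time_level_s"],
                    n_levels=spec.n_levels,
                    meta=manifest)
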