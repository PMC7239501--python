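"""The five parameterized functions of the adaptation framework.

- encoder F: six convolution layers (batch norm before ReLU), weight-shared
  across both domains, mapping images to a spatial latent code;
- decoders G_S / G_T: six transposed-convolution layers mirroring the
  encoder's stride pattern, tanh output in [-1, 1];
- classifier C: two fully connected layers over the flattened latent;
- discriminators D_S / D_T: DC-GAN-style strided conv stacks with a sigmoid
  scalar output (probability the input is a real image of that domain).

Strides adapt to the image side: layers use stride 2 while the spatial size
exceeds 4 and stride 1 afterwards, so the same six-layer encoder covers
32-256 px inputs with a latent spatial size of 4.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

N_LAYERS = 6
LATENT_SPATIAL = 4


@dataclass(frozen=True)
class NetShapeConfig:
    image_side: int = 32
    channels: int = 1
    base_filters: int = 8
    max_filters: int = 32
    latent_channels: int = 32
    fc_width: int = 64
    n_classes: int = 2

    def __post_init__(self):
        if self.image_side % 4 or self.image_side < 16:
            raise ValueError("image_side must be >= 16 and a multiple of 4")
        if self.base_filters < 8:
            raise ValueError("base_filters must be >= 8")
        if self.n_classes != 2:
            raise ValueError("only binary classification is supported")
        if self.image_side // (2 ** self._n_strided()) != LATENT_SPATIAL:
            raise ValueError(
                f"image_side {self.image_side} cannot reach latent size "
                f"{LATENT_SPATIAL} within {N_LAYERS} stride-2 layers")

    def _n_strided(self) -> int:
        n = int(np.log2(self.image_side // LATENT_SPATIAL))
        if n > N_LAYERS:
            raise ValueError("image_side too large for a six-layer encoder")
        return n

    @property
    def stride_pattern(self) -> tuple:
        """Per-layer strides: 2 while spatial size > 4, then 1."""
        n2 = self._n_strided()
        return (2,) * n2 + (1,) * (N_LAYERS - n2)

    @property
    def filter_schedule(self) -> tuple:
        """Output channels per encoder layer: base doubling per strided layer,
        capped; the last layer emits latent_channels."""
        chans, c = [], self.base_filters
        for i, s in enumerate(self.stride_pattern):
            chans.append(c)
            if s == 2:
                c = min(2 * c, self.max_filters)
        chans[-1] = self.latent_channels
        return tuple(chans)


class Encoder(nn.Module):
    """Shared encoder F: conv -> BN -> ReLU, six times."""

    def __init__(self, cfg: NetShapeConfig, rng):
        super().__init__()
        self.cfg = cfg
        layers = []
        in_ch = cfg.channels
        for out_ch, s in zip(cfg.filter_schedule, cfg.stride_pattern):
            k, p = (4, 1) if s == 2 else (3, 1)
            layers += [nn.Conv2d(in_ch, out_ch, k, s, p, rng=rng),
                       nn.BatchNorm2d(out_ch), nn.ReLU()]
            in_ch = out_ch
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x)


class Decoder(nn.Module):
    """Per-domain decoder G: six transposed convs mirroring the encoder,
    BN+ReLU on hidden layers, tanh output."""

    def __init__(self, cfg: NetShapeConfig, rng):
        super().__init__()
        self.cfg = cfg
        enc_chans = cfg.filter_schedule
        enc_strides = cfg.stride_pattern
        # mirror: walk the encoder backwards
        in_chans = enc_chans[::-1]                       # starting at latent
        out_chans = (enc_chans[-2::-1] + (cfg.channels,))
        strides = enc_strides[::-1]
        layers = []
        for i, (ci, co, s) in enumerate(zip(in_chans, out_chans, strides)):
            k, p = (4, 1) if s == 2 else (3, 1)
            last = i == N_LAYERS - 1
            layers.append(nn.ConvTranspose2d(ci, co, k, s, p, rng=rng))
            if last:
                layers.append(nn.Tanh())
            else:
                layers += [nn.BatchNorm2d(co), nn.ReLU()]
        self.net = nn.Sequential(*layers)

    def forward(self, z):
        return self.net(z)


class Classifier(nn.Module):
    """Two fully connected layers over the flattened latent; emits logits."""

    def __init__(self, cfg: NetShapeConfig, rng):
        super().__init__()
        self.cfg = cfg
        in_f = cfg.latent_channels * LATENT_SPATIAL * LATENT_SPATIAL
        self.flatten = nn.Flatten()
        self.fc1 = nn.Linear(in_f, cfg.fc_width, rng=rng)
        self.act = nn.ReLU()
        self.fc2 = nn.Linear(cfg.fc_width, cfg.n_classes, rng=rng)

    def forward(self, z):
        return self.fc2(self.act(self.fc1(self.flatten(z))))

    def probs(self, z):
        """Class probabilities (softmax over the two logits)."""
        return self.forward(z).softmax()


class Discriminator(nn.Module):
    """DC-GAN-style discriminator: strided convs (leaky ReLU, no BN on the
    first layer) down to spatial 4, then a valid 4x4 conv to one sigmoid unit."""

    def __init__(self, cfg: NetShapeConfig, rng):
        super().__init__()
        self.cfg = cfg
        layers = []
        in_ch, c = cfg.channels, cfg.base_filters
        n2 = cfg._n_strided()
        for i in range(n2):
            layers.append(nn.Conv2d(in_ch, c, 4, 2, 1, rng=rng))
            if i > 0:
                layers.append(nn.BatchNorm2d(c))
            layers.append(nn.LeakyReLU(0.2))
            in_ch, c = c, min(2 * c, cfg.max_filters)
        layers.append(nn.Conv2d(in_ch, 1, LATENT_SPATIAL, 1, 0, rng=rng))
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x).reshape(x.shape[0])


def build_encoder(cfg: NetShapeConfig, rng=None) -> Encoder:
    return Encoder(cfg, rng or np.random.default_rng(0))


def build_decoder(cfg: NetShapeConfig, rng=None) -> Decoder:
    return Decoder(cfg, rng or np.random.default_rng(0))


def build_classifier(cfg: NetShapeConfig, rng=None) -> Classifier:
    return Classifier(cfg, rng or np.random.default_rng(0))


def build_discriminator(cfg: NetShapeConfig, rng=None) -> Discriminator:
    return Discriminator(cfg, rng or np.random.default_rng(0))


@dataclass
class ModelBundle:
    """The six parameter collections; F is shared across domains, the other
    five are disjoint per-module collections. The source-only baseline keeps
    just F and C (the rest None)."""
    F: Encoder
    C: Classifier
    cfg: NetShapeConfig
    G_S: Decoder | None = None
    G_T: Decoder | None = None
    D_S: Discriminator | None = None
    D_T: Discriminator | None = None
    step: int = 0

    def modules(self) -> dict:
        all_mods = {"F": self.F, "G_S": self.G_S, "G_T": self.G_T,
                    "D_S": self.D_S, "D_T": self.D_T, "C": self.C}
        return {k: v for k, v in all_mods.items() if v is not None}

    def eval(self):
        for m in self.modules().values():
            m.eval()
        return self

    def param_snapshot(self) -> dict:
        return {name: {k: p.data.copy() for k, p in m.parameters().items()}
                for name, m in self.modules().items()}


def build_bundle(cfg: NetShapeConfig, seed: int = 0,
                 source_only: bool = False) -> ModelBundle:
    """Initialize a full six-module bundle, or just F + C for the
    source-only baseline. Each module gets an independent init stream."""
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    if source_only:
        return ModelBundle(F=Encoder(cfg, rngs[0]), C=Classifier(cfg, rngs[5]),
                           cfg=cfg)
    return ModelBundle(
        F=Encoder(cfg, rngs[0]),
        C=Classifier(cfg, rngs[5]),
        G_S=Decoder(cfg, rngs[1]),
        G_T=Decoder(cfg, rngs[2]),
        D_S=Discriminator(cfg, rngs[3]),
        D_T=Discriminator(cfg, rngs[4]),
        cfg=cfg,
    )


# ---------------------------------------------------------------------------
# checkpointing: one npz archive with namespaced arrays + a JSON config entry
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: ModelBundle, path: str):
    modules = bundle.modules()
    arrays = {}
    for name, m in modules.items():
        for k, v in m.state_dict().items():
            arrays[f"{name}/{k}"] = v
    meta = json.dumps({"cfg": asdict(bundle.cfg), "step": bundle.step,
                       "modules": sorted(modules)})
    arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> ModelBundle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = NetShapeConfig(**meta["cfg"])
        names = set(meta["modules"])
        bundle = build_bundle(cfg, seed=0,
                              source_only=names == {"F", "C"})
        bundle.step = int(meta["step"])
        for name in list(bundle.modules()):
            if name not in names:
                setattr(bundle, name, None)
        for name in names:
            prefix = f"{name}/"
            state = {k[len(prefix):]: data[k] for k in data.files
                     if k.startswith(prefix)}
            bundle.modules()[name].load_state_dict(state)
    return bundle


def checkpoint_bytes(bundle: ModelBundle) -> bytes:
    """Serialized checkpoint as bytes (used for hashing / purity checks)."""
    buf = io.BytesIO()
    arrays = {}
    for name, m in bundle.modules().items():
        for k, v in m.state_dict().items():
            arrays[f"{name}/{k}"] = v
    np.savez(buf, **arrays)
    return buf.getvalue()
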