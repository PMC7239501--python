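"""Synthetic unpaired two-domain, two-class image benchmark.

Emulates a multicenter CT-style setting at desk scale: the class signal is
geometric (which shape family an image contains), while the domain signal is
a global, label-free appearance transform (contrast curve, blur, background
texture, noise). Source images are labeled; target images carry labels only
in an eval-only field so the unsupervised setting can be enforced and still
evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dataio import DomainDatasetPair

GEOMETRIES = ("disc", "annulus", "blobs_low", "blobs_high")

# transform kind -> {param: (low, high)}
TRANSFORM_SPECS = {
    "gamma": {"gamma": (0.05, 10.0)},
    "blur": {"sigma": (0.0, 5.0)},
    "intensity_scale": {"a": (-1.0, 1.0), "b": (-2.0, 2.0)},
    "background_texture": {"amplitude": (0.0, 1.0), "corr_len": (0.5, 16.0)},
    "additive_noise": {"sd": (0.0, 0.5)},
}
_STOCHASTIC = {"background_texture", "additive_noise"}


@dataclass(frozen=True)
class ClassSpec:
    """One renderable class: a shape family plus per-sample jitter."""
    class_id: int
    geometry: str
    geometry_jitter: float = 0.25

    def __post_init__(self):
        if self.class_id not in (0, 1):
            raise ValueError(f"class_id must be 0 or 1, got {self.class_id}")
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; choose from {GEOMETRIES}")
        if not 0.0 <= self.geometry_jitter <= 0.5:
            raise ValueError("geometry_jitter must be in [0, 0.5]")


@dataclass(frozen=True)
class DomainSpec:
    """Label-free appearance regime: an ordered list of pixel transforms.

    Each transform is a dict with a ``kind`` key plus that kind's parameters,
    e.g. ``{"kind": "gamma", "gamma": 0.6}``. Transforms depend only on pixel
    values, never on the class label.
    """
    domain_id: str
    appearance: tuple = ()

    def __post_init__(self):
        if self.domain_id not in ("source", "target"):
            raise ValueError("domain_id must be 'source' or 'target'")
        object.__setattr__(self, "appearance",
                           tuple(dict(t) for t in self.appearance))
        for t in self.appearance:
            kind = t.get("kind")
            if kind not in TRANSFORM_SPECS:
                raise ValueError(f"unknown transform kind {kind!r}")
            spec = TRANSFORM_SPECS[kind]
            extra = set(t) - {"kind"} - set(spec)
            if extra:
                raise ValueError(f"unknown parameters {extra} for {kind}")
            for p, (lo, hi) in spec.items():
                v = t.get(p)
                if v is None or not np.isfinite(v) or not lo <= v <= hi:
                    raise ValueError(
                        f"{kind}.{p} must be finite in [{lo}, {hi}], got {v}")


@dataclass(frozen=True)
class SyntheticConfig:
    image_size: int = 32
    n_per_domain: int = 2000
    class_balance: float = 0.5
    source_spec: DomainSpec = field(
        default_factory=lambda: DomainSpec("source", ()))
    target_spec: DomainSpec = field(
        default_factory=lambda: DomainSpec("target", ()))
    class_specs: tuple = field(default_factory=lambda: (
        ClassSpec(0, "disc"), ClassSpec(1, "annulus")))
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16 or self.image_size % 4:
            raise ValueError("image_size must be >= 16 and a multiple of 4")
        if self.n_per_domain < 4:
            raise ValueError("n_per_domain must be >= 4")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must be in [0, 1]")
        ids = sorted(c.class_id for c in self.class_specs)
        if ids != [0, 1]:
            raise ValueError("class_specs must carry class_ids {0, 1}")
        if self.class_specs[0].geometry == self.class_specs[1].geometry:
            raise ValueError("the two classes must use distinct geometries")


def default_benchmark_config(seed: int = 0, n_per_domain: int = 2000,
                             image_size: int = 32) -> SyntheticConfig:
    """The desk-scale benchmark: disc vs annulus under two appearance
    regimes. The source domain is crisp and high-contrast (gamma 2.2, like a
    contrast-enhanced acquisition); the target domain is flat and cluttered
    (gamma 0.6 contrast lift, blur sigma 1.0, bright correlated background
    texture, like a plain acquisition)."""
    return SyntheticConfig(
        image_size=image_size,
        n_per_domain=n_per_domain,
        class_balance=0.5,
        source_spec=DomainSpec("source", (
            {"kind": "gamma", "gamma": 2.2},
            {"kind": "additive_noise", "sd": 0.02},
        )),
        target_spec=DomainSpec("target", (
            {"kind": "gamma", "gamma": 0.6},
            {"kind": "blur", "sigma": 1.0},
            {"kind": "background_texture", "amplitude": 0.5, "corr_len": 4.0},
            {"kind": "additive_noise", "sd": 0.02},
        )),
        class_specs=(ClassSpec(0, "disc"), ClassSpec(1, "annulus")),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grid(size: int):
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    return xx - c, yy - c


def _soft_disc(xx, yy, cx, cy, r):
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    return np.clip(r + 0.5 - d, 0.0, 1.0)


def render_class_instance(spec: ClassSpec, rng: np.random.Generator,
                          size: int = 32) -> np.ndarray:
    """Draw one clean instance of the class geometry; values in [0, 1].

    The rng is consumed in a fixed order, so a given bit-generator state
    always yields the same image.
    """
    if spec.geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    j = spec.geometry_jitter
    xx, yy = _grid(size)
    fg = 0.85
    img = np.zeros((size, size), dtype=np.float64)

    if spec.geometry in ("disc", "annulus"):
        r0 = 0.30 * size * (1.0 + j * rng.uniform(-1, 1))
        cx = j * 0.3 * size * rng.uniform(-1, 1)
        cy = j * 0.3 * size * rng.uniform(-1, 1)
        if spec.geometry == "disc":
            img = fg * _soft_disc(xx, yy, cx, cy, r0)
        else:
            ri = r0 * (0.55 + 0.1 * j * rng.uniform(-1, 1))
            outer = _soft_disc(xx, yy, cx, cy, r0)
            inner = _soft_disc(xx, yy, cx, cy, ri)
            img = fg * np.clip(outer - inner, 0.0, 1.0)
    else:
        n_blobs = 2 if spec.geometry == "blobs_low" else 5
        # fixed polygon of anchor positions, jittered per sample
        angles = 2 * np.pi * np.arange(n_blobs) / n_blobs
        rad = 0.25 * size
        sig = 0.08 * size
        for a in angles:
            cx = rad * np.cos(a) + j * 0.2 * size * rng.uniform(-1, 1)
            cy = rad * np.sin(a) + j * 0.2 * size * rng.uniform(-1, 1)
            img += fg * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)
                                 / (2 * sig ** 2)))
        img = np.clip(img, 0.0, 1.0)

    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# appearance transforms
# ---------------------------------------------------------------------------

def apply_domain_transform(image: np.ndarray, spec: DomainSpec,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply the domain's appearance transforms in order; output in [0, 1].

    Stochastic transforms (background texture, additive noise) draw from
    ``rng``, which must then be provided.
    """
    img = np.asarray(image, dtype=np.float64)
    for t in spec.appearance:
        kind = t["kind"]
        if kind in _STOCHASTIC and rng is None:
            raise ValueError(f"transform {kind!r} needs an rng")
        if kind == "gamma":
            img = np.clip(img, 0.0, 1.0) ** t["gamma"]
        elif kind == "blur":
            if t["sigma"] > 0:
                img = ndimage.gaussian_filter(img, t["sigma"])
        elif kind == "intensity_scale":
            img = t["a"] + t["b"] * img
        elif kind == "background_texture":
            noise = rng.normal(size=img.shape)
            smooth = ndimage.gaussian_filter(noise, t["corr_len"] / 2.0)
            sd = smooth.std()
            if sd > 0:
                smooth /= sd
            img = img + t["amplitude"] * 0.5 * (smooth + 1.0) * (1.0 - img)
        elif kind == "additive_noise":
            img = img + rng.normal(0.0, t["sd"], size=img.shape)
        img = np.clip(img, 0.0, 1.0)
    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _labels_for(n: int, balance: float, rng: np.random.Generator):
    n1 = int(round(n * balance))
    labels = np.array([1] * n1 + [0] * (n - n1), dtype=np.int64)
    rng.shuffle(labels)
    return labels


def generate_dataset(config: SyntheticConfig) -> DomainDatasetPair:
    """Generate the unpaired two-domain dataset. Pure function of the config
    (including its seed): independent rng streams are spawned for source
    geometry, target geometry, appearance, and label shuffling."""
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(5)]
    rng_geom_s, rng_geom_t, rng_app_s, rng_app_t, rng_shuffle = streams

    by_id = {c.class_id: c for c in config.class_specs}
    n = config.n_per_domain

    def make_domain(dspec, rng_geom, rng_app):
        labels = _labels_for(n, config.class_balance, rng_shuffle)
        imgs = np.empty((n, 1, config.image_size, config.image_size),
                        dtype=np.float32)
        for i, y in enumerate(labels):
            clean = render_class_instance(by_id[int(y)], rng_geom,
                                          config.image_size)
            imgs[i, 0] = apply_domain_transform(clean, dspec, rng_app)
        return imgs, labels

    src_imgs, src_labels = make_domain(config.source_spec, rng_geom_s, rng_app_s)
    tgt_imgs, tgt_labels = make_domain(config.target_spec, rng_geom_t, rng_app_t)

    return DomainDatasetPair(
        source_images=src_imgs,
        source_labels=src_labels,
        target_images=tgt_imgs,
        target_eval_labels=tgt_labels,
        image_size=config.image_size,
    )


# ---------------------------------------------------------------------------
# domain-shift probe
# ---------------------------------------------------------------------------

def _global_stats(images: np.ndarray) -> np.ndarray:
    """Per-image fixed global pixel statistics: mean, variance, gradient
    energy (mean squared finite difference)."""
    x = images.reshape(images.shape[0], -1)
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    imgs = images[:, 0]
    gx = np.diff(imgs, axis=2)
    gy = np.diff(imgs, axis=1)
    grad = (gx ** 2).mean(axis=(1, 2)) + (gy ** 2).mean(axis=(1, 2))
    return np.stack([mean, var, grad], axis=1)


def domain_shift_probe(pair: DomainDatasetPair) -> float:
    """Held-out accuracy of a linear domain classifier on global pixel
    statistics; ~0.5 means no detectable shift, 1.0 a fully separable one."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    ns, nt = len(pair.source_images), len(pair.target_images)
    if ns < 10 or nt < 10:
        raise ValueError("domain_shift_probe needs at least 10 samples per domain")
    feats = np.concatenate([_global_stats(pair.source_images),
                            _global_stats(pair.target_images)])
    dom = np.concatenate([np.zeros(ns), np.ones(nt)])
    # deterministic interleaved split, stratified by domain
    idx = np.arange(len(dom))
    train = idx % 2 == 0
    test = ~train
    scaler = StandardScaler().fit(feats[train])
    clf = LogisticRegression(max_iter=2000)
    clf.fit(scaler.transform(feats[train]), dom[train])
    return float(clf.score(scaler.transform(feats[test]), dom[test]))


def with_target_appearance(config: SyntheticConfig, **updates) -> SyntheticConfig:
    """Convenience: replace parameters of the target domain's transforms by
    kind, e.g. ``with_target_appearance(cfg, blur={"sigma": 2.0})``."""
    new = []
    for t in config.target_spec.appearance:
        t = dict(t)
        if t["kind"] in updates:
            t.update(updates[t["kind"]])
        new.append(t)
    return replace(config,
                   target_spec=DomainSpec("target", tuple(new)))
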