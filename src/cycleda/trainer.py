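"""Four-phase alternating optimization with strict parameter isolation.

Each training step performs exactly four sequential sub-updates, in the
order D -> G -> C -> F:

1. D-phase: discriminators D_S/D_T minimize the real-vs-generated loss;
   encoder, decoders and classifier are frozen (inference mode, no graph).
2. G-phase: decoders G_S/G_T minimize the adversarial confusion term plus
   (when enabled) the classification cycle-consistency term, everything
   else frozen.
3. C-phase: the classifier minimizes cross-entropy on real source latents
   and on cross-domain translations of source images; the translations are
   recomputed without a graph, so no gradient ever reaches F or G.
4. F-phase: the shared encoder minimizes label prediction + cycle terms +
   cross-domain adversarial terms + alpha/beta-weighted same-domain terms +
   latent L2.

Forward passes are recomputed per phase with the current parameters, and
batch-norm running statistics update only inside the phase that owns a
module; all other phases run foreign modules in inference mode.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import DomainDatasetPair
from .losses import (LossBundle, LossWeights, classifier_loss, decoder_loss,
                     discriminator_loss, encoder_loss)
from .networks import ModelBundle, NetShapeConfig, build_bundle, save_checkpoint
from .nn import Adam, Tensor, no_grad


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 2
    batch_size: int = 24
    lr_D: float = 2e-4
    lr_G: float = 2e-4
    lr_C: float = 2e-4
    lr_F: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.99   # the "momentum of 0.99" honored as second moment
    weights: LossWeights = field(default_factory=LossWeights)
    cycle_consistency: bool = True
    saturating: bool = False
    seed: int = 0
    checkpoint_every: int = 0  # 0: only a final checkpoint when run_dir given
    phase_order: tuple = ("D", "G", "C", "F")

    def __post_init__(self):
        if min(self.lr_D, self.lr_G, self.lr_C, self.lr_F) <= 0:
            raise ValueError("learning rates must be > 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        for b in (self.adam_beta1, self.adam_beta2):
            if not 0.0 <= b < 1.0:
                raise ValueError("Adam decay rates must be in [0, 1)")
        if sorted(self.phase_order) != ["C", "D", "F", "G"]:
            raise ValueError("phase_order must be a permutation of D,G,C,F")


@dataclass
class TrainState:
    bundle: ModelBundle
    optimizers: dict
    cfg: TrainConfig
    step: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))

    def save(self, path: str):
        save_checkpoint(self.bundle, path)


def _make_state(pair_or_side, cfg: TrainConfig,
                net_cfg: NetShapeConfig | None, source_only: bool) -> TrainState:
    side = (pair_or_side.image_size if isinstance(pair_or_side, DomainDatasetPair)
            else pair_or_side)
    if net_cfg is None:
        net_cfg = NetShapeConfig(image_side=side)
    bundle = build_bundle(net_cfg, seed=cfg.seed, source_only=source_only)
    if source_only:
        params = dict(**{f"F.{k}": v for k, v in bundle.F.parameters().items()},
                      **{f"C.{k}": v for k, v in bundle.C.parameters().items()})
        optimizers = {"FC": Adam(params, cfg.lr_C, cfg.adam_beta1, cfg.adam_beta2)}
    else:
        def group(names, lr):
            params = {}
            for n in names:
                for k, v in bundle.modules()[n].parameters().items():
                    params[f"{n}.{k}"] = v
            return Adam(params, lr, cfg.adam_beta1, cfg.adam_beta2)

        optimizers = {"D": group(("D_S", "D_T"), cfg.lr_D),
                      "G": group(("G_S", "G_T"), cfg.lr_G),
                      "C": group(("C",), cfg.lr_C),
                      "F": group(("F",), cfg.lr_F)}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5A11]))
    return TrainState(bundle=bundle, optimizers=optimizers, cfg=cfg, rng=rng)


def _set_phase(bundle: ModelBundle, owned: set):
    """Phase ownership: every module normalizes with current-batch statistics
    (standard GAN practice — early running averages are uncalibrated), but
    only the owned modules update their stored running statistics."""
    from .nn.layers import BatchNorm2d
    for name, m in bundle.modules().items():
        m.train(True)
        frozen = name not in owned
        for sub in m.modules():
            if isinstance(sub, BatchNorm2d):
                sub.frozen_stats = frozen


def _zero_all(bundle: ModelBundle):
    for m in bundle.modules().values():
        m.zero_grad()


def _probs_true(classifier, z, labels) -> Tensor:
    return classifier.probs(z).gather_rows(labels)


def train_step(state: TrainState, batch_S, batch_T,
               phase_callback=None) -> LossBundle:
    """One four-phase update. ``batch_S`` is (images, labels), ``batch_T``
    images only; images preprocessed to [-1, 1], equal batch sizes.
    ``phase_callback(name)``, if given, runs after each phase completes
    (used to audit per-phase parameter isolation)."""
    xs, ys = batch_S
    xt = batch_T
    if len(xs) != len(xt):
        raise ValueError(f"unequal batch sizes: {len(xs)} vs {len(xt)}")
    if len(xs) == 0:
        raise ValueError("empty batch")
    cfg = state.cfg
    w = cfg.weights
    b = state.bundle
    if b.G_S is None:
        raise ValueError("train_step needs a full six-module bundle")
    xs_t, xt_t = Tensor(xs), Tensor(xt)
    ys = np.asarray(ys, dtype=np.intp)
    cyc = cfg.cycle_consistency
    results = {}
    breakdown = {}

    def phase_D():
        _set_phase(b, {"D_S", "D_T"})
        with no_grad():
            z_s, z_t = b.F(xs_t), b.F(xt_t)
            x_ss, x_st = b.G_S(z_s), b.G_T(z_s)
            x_tt, x_ts = b.G_T(z_t), b.G_S(z_t)
        loss_s, br_s = discriminator_loss(
            b.D_S(xs_t), b.D_S(x_ss), b.D_S(x_ts),
            eps=w.eps, return_breakdown=True)
        loss_t, br_t = discriminator_loss(
            b.D_T(xt_t), b.D_T(x_tt), b.D_T(x_st),
            eps=w.eps, return_breakdown=True)
        loss = loss_s + loss_t
        _zero_all(b)
        loss.backward()
        state.optimizers["D"].step()
        _zero_all(b)
        results["D"] = loss.item()
        breakdown.update({f"d_s_{k}": v for k, v in br_s.items()})
        breakdown.update({f"d_t_{k}": v for k, v in br_t.items()})

    def phase_G():
        _set_phase(b, {"G_S", "G_T"})
        with no_grad():
            z_s, z_t = b.F(xs_t), b.F(xt_t)
        x_ss, x_st = b.G_S(z_s), b.G_T(z_s)
        x_tt = b.G_T(z_t)
        p_ss = p_st = None
        if cyc:
            p_ss = _probs_true(b.C, b.F(x_ss), ys)
            p_st = _probs_true(b.C, b.F(x_st), ys)
        loss_s, br_s = decoder_loss(p_ss, b.D_S(x_ss), saturating=cfg.saturating,
                                    eps=w.eps, return_breakdown=True)
        loss_t, br_t = decoder_loss(p_st, b.D_T(x_tt), saturating=cfg.saturating,
                                    eps=w.eps, return_breakdown=True)
        loss = loss_s + loss_t
        _zero_all(b)
        loss.backward()
        state.optimizers["G"].step()
        _zero_all(b)
        results["G"] = loss.item()
        breakdown.update({f"g_s_{k}": v for k, v in br_s.items()})
        breakdown.update({f"g_t_{k}": v for k, v in br_t.items()})

    def phase_C():
        _set_phase(b, {"C"})
        with no_grad():
            z_s = b.F(xs_t)
            z_st = b.F(b.G_T(z_s)) if cyc else None
        p_src = _probs_true(b.C, z_s, ys)
        p_cross = _probs_true(b.C, z_st, ys) if cyc else None
        loss, br = classifier_loss(p_src, p_cross, eps=w.eps,
                                   return_breakdown=True)
        _zero_all(b)
        loss.backward()
        state.optimizers["C"].step()
        _zero_all(b)
        results["C"] = loss.item()
        breakdown.update({f"c_{k}": v for k, v in br.items()})

    def phase_F():
        _set_phase(b, {"F"})
        z_s, z_t = b.F(xs_t), b.F(xt_t)
        # running statistics estimate the real-data distribution only: freeze
        # them before re-encoding generated images (batch stats still used)
        _set_phase(b, set())
        x_ss, x_st = b.G_S(z_s), b.G_T(z_s)
        x_tt, x_ts = b.G_T(z_t), b.G_S(z_t)
        p_src = _probs_true(b.C, z_s, ys)
        p_cyc_same = _probs_true(b.C, b.F(x_ss), ys) if cyc else None
        p_cyc_cross = _probs_true(b.C, b.F(x_st), ys) if cyc else None
        latents = (x_st, x_ts) if w.l2_on_images else (z_s, z_t)
        loss, br = encoder_loss(
            p_src, p_cyc_same, p_cyc_cross,
            d_cross_t=b.D_T(x_st), d_cross_s=b.D_S(x_ts),
            d_same_s=b.D_S(x_ss), d_same_t=b.D_T(x_tt),
            latents=latents, w=w, saturating=cfg.saturating,
            return_breakdown=True)
        _zero_all(b)
        loss.backward()
        state.optimizers["F"].step()
        _zero_all(b)
        results["F"] = loss.item()
        breakdown.update({f"f_{k}": v for k, v in br.items()})

    phases = {"D": phase_D, "G": phase_G, "C": phase_C, "F": phase_F}
    for name in cfg.phase_order:
        phases[name]()
        if phase_callback is not None:
            phase_callback(name)

    state.step += 1
    state.bundle.step = state.step
    return LossBundle(loss_D=results["D"], loss_G=results["G"],
                      loss_C=results["C"], loss_F=results["F"],
                      breakdown=breakdown)


# ---------------------------------------------------------------------------
# epoch loops
# ---------------------------------------------------------------------------


class _BatchStream:
    """Endless shuffled batches over one domain; reshuffles independently
    whenever the index pool is exhausted (shorter sets recycle)."""

    def __init__(self, n: int, batch: int, rng: np.random.Generator):
        self.n, self.batch, self.rng = n, batch, rng
        self.pool = rng.permutation(n)
        self.pos = 0

    def next(self) -> np.ndarray:
        out = []
        need = self.batch
        while need:
            take = min(need, self.n - self.pos)
            out.append(self.pool[self.pos:self.pos + take])
            self.pos += take
            need -= take
            if self.pos == self.n:
                self.pool = self.rng.permutation(self.n)
                self.pos = 0
        return np.concatenate(out)


def _to_pm1(images: np.ndarray) -> np.ndarray:
    return (2.0 * images - 1.0).astype(np.float32)


def _recalibrate_bn(module, batches):
    """Replace batch-norm running statistics with the running average of
    batch statistics over the given batches (label-free, deterministic).

    During alternating training the EMA statistics mostly reflect the last
    few batches seen, which makes end-of-training evaluation a lottery; a
    final calibration pass over a fixed sample removes that."""
    from .nn.layers import BatchNorm2d
    bns = [m for m in module.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0
        bn.frozen_stats = False
    module.train(True)
    with no_grad():
        for i, xb in enumerate(batches):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            module(Tensor(xb))
    for bn in bns:
        bn.momentum = 0.1
    module.eval()


def _calibration_batches(arrays, batch: int, seed: int, max_batches: int = 32):
    """Interleaved, seeded batches drawn from each array in turn."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11B]))
    pools = [rng.permutation(len(a)) for a in arrays]
    out = []
    pos = [0] * len(arrays)
    while len(out) < max_batches:
        progressed = False
        for k, a in enumerate(arrays):
            if pos[k] + batch <= len(pools[k]):
                out.append(a[pools[k][pos[k]:pos[k] + batch]])
                pos[k] += batch
                progressed = True
                if len(out) >= max_batches:
                    break
        if not progressed:
            break
    return out or [a[:batch] for a in arrays]


def fit(pair: DomainDatasetPair, cfg: TrainConfig,
        net_cfg: NetShapeConfig | None = None,
        run_dir: str | None = None):
    """Train the full adaptation model; returns (TrainState, log).

    The log is a list of per-step dicts (headline losses plus named
    sub-terms); with a run_dir it is also written as logs/train.jsonl and the
    end-of-training checkpoint as checkpoints/final.npz. Training touches
    only the source labels and target images; target eval labels are never
    read.
    """
    if len(pair.source_images) == 0 or len(pair.target_images) == 0:
        raise ValueError("both domains must be non-empty")
    state = _make_state(pair, cfg, net_cfg, source_only=False)
    xs_all = _to_pm1(pair.source_images)
    xt_all = _to_pm1(pair.target_images)
    ys_all = pair.source_labels
    ns, nt = len(xs_all), len(xt_all)
    steps_per_epoch = math.ceil(max(ns, nt) / cfg.batch_size)
    ss = np.random.SeedSequence([cfg.seed, 0xBA7C4])
    rng_s, rng_t = (np.random.default_rng(s) for s in ss.spawn(2))
    stream_s = _BatchStream(ns, cfg.batch_size, rng_s)
    stream_t = _BatchStream(nt, cfg.batch_size, rng_t)

    log = []
    for _ in range(cfg.epochs):
        for _ in range(steps_per_epoch):
            i_s = stream_s.next()
            i_t = stream_t.next()
            lb = train_step(state, (xs_all[i_s], ys_all[i_s]), xt_all[i_t])
            log.append({"step": state.step, **lb.as_dict()})
            if run_dir and cfg.checkpoint_every and \
                    state.step % cfg.checkpoint_every == 0:
                ckpt_dir = os.path.join(run_dir, "checkpoints")
                os.makedirs(ckpt_dir, exist_ok=True)
                state.save(os.path.join(ckpt_dir, f"step{state.step:06d}.npz"))

    if cfg.epochs > 0:
        _recalibrate_bn(state.bundle.F,
                        _calibration_batches([xs_all, xt_all],
                                             cfg.batch_size, cfg.seed))

    if run_dir:
        os.makedirs(os.path.join(run_dir, "checkpoints"), exist_ok=True)
        os.makedirs(os.path.join(run_dir, "logs"), exist_ok=True)
        state.save(os.path.join(run_dir, "checkpoints", "final.npz"))
        with open(os.path.join(run_dir, "logs", "train.jsonl"), "w") as fh:
            for row in log:
                fh.write(json.dumps(row) + "\n")
    return state, log


def train_source_only(pair: DomainDatasetPair, cfg: TrainConfig,
                      net_cfg: NetShapeConfig | None = None,
                      run_dir: str | None = None):
    """Source-only baseline: encoder F + classifier C trained with plain
    cross-entropy on labeled source images; no decoders or discriminators
    are instantiated. Returns (TrainState, log)."""
    if len(pair.source_images) == 0:
        raise ValueError("labeled source set must be non-empty")
    state = _make_state(pair, cfg, net_cfg, source_only=True)
    b = state.bundle
    xs_all = _to_pm1(pair.source_images)
    ys_all = pair.source_labels
    ns = len(xs_all)
    steps_per_epoch = math.ceil(ns / cfg.batch_size)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBA5E]))
    stream = _BatchStream(ns, cfg.batch_size, rng)

    log = []
    b.F.train(True)
    b.C.train(True)
    for _ in range(cfg.epochs):
        for _ in range(steps_per_epoch):
            idx = stream.next()
            ys = np.asarray(ys_all[idx], dtype=np.intp)
            p = _probs_true(b.C, b.F(Tensor(xs_all[idx])), ys)
            loss = classifier_loss(p, None, eps=cfg.weights.eps)
            _zero_all(b)
            loss.backward()
            state.optimizers["FC"].step()
            _zero_all(b)
            state.step += 1
            b.step = state.step
            log.append({"step": state.step, "loss_C": loss.item()})

    # the baseline never sees target data: statistics come from source only
    if cfg.epochs > 0:
        _recalibrate_bn(b.F, _calibration_batches([xs_all], cfg.batch_size,
                                                  cfg.seed))

    if run_dir:
        os.makedirs(os.path.join(run_dir, "checkpoints"), exist_ok=True)
        state.save(os.path.join(run_dir, "checkpoints", "baseline.npz"))
    return state, log


def config_without_cycle(cfg: TrainConfig) -> TrainConfig:
    return replace(cfg, cycle_consistency=False)
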