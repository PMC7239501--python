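"""Verification and evaluation protocol machinery.

Verification keeps only the frozen encoder and classifier. The k-fold
protocol re-trains per fold: each fold of the labeled source set (and the
matching fold of the eval-labeled target set) is held out, the model is
trained on the remainder (with the full unlabeled target set always
available), and held-out accuracies are aggregated as mean +/- sample std.
The comparison and ablation harnesses run their two arms on identical folds
and seeds so the contrast is controlled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .dataio import DomainDatasetPair, FoldSplit, make_stratified_folds
from .networks import ModelBundle, NetShapeConfig, load_checkpoint
from .nn import Tensor, no_grad
from .trainer import TrainConfig, TrainState, fit, train_source_only, _to_pm1


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def _resolve_bundle(model) -> ModelBundle:
    if isinstance(model, ModelBundle):
        return model
    if isinstance(model, TrainState):
        return model.bundle
    if isinstance(model, str):
        return load_checkpoint(model)
    raise TypeError(f"cannot verify a {type(model).__name__}")


def predict(model, images: np.ndarray, batch: int = 256) -> np.ndarray:
    """Predicted class per image (images in [0,1], shape (N,1,H,W))."""
    b = _resolve_bundle(model)
    was_training = {name: m.training for name, m in b.modules().items()}
    b.F.eval()
    b.C.eval()
    x = _to_pm1(images)
    preds = []
    with no_grad():
        for i in range(0, len(x), batch):
            logits = b.C(b.F(Tensor(x[i:i + batch])))
            preds.append(logits.data.argmax(axis=1))
    for name, m in b.modules().items():
        m.train(was_training[name])
    return np.concatenate(preds)


def verify(model, dataset) -> float:
    """Accuracy (percent) of the frozen encoder + classifier on a labeled
    set; pure inference, no parameter or statistic is modified."""
    images, labels = dataset
    if len(images) == 0:
        raise ValueError("empty dataset")
    preds = predict(model, images)
    return 100.0 * float((preds == np.asarray(labels)).mean())


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _agg(vals) -> tuple:
    arr = np.asarray(vals, dtype=np.float64)
    std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), std


@dataclass
class EvalReport:
    per_fold_source_acc: list
    per_fold_target_acc: list
    mean_source: float
    std_source: float
    mean_target: float
    std_target: float
    config_fingerprint: str
    seeds: list

    @classmethod
    def from_folds(cls, src_accs, tgt_accs, fingerprint, seeds) -> "EvalReport":
        ms, ss = _agg(src_accs)
        mt, st = _agg(tgt_accs)
        return cls(list(map(float, src_accs)), list(map(float, tgt_accs)),
                   ms, ss, mt, st, fingerprint, list(seeds))

    def __post_init__(self):
        for v in self.per_fold_source_acc + self.per_fold_target_acc:
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"accuracy {v} outside [0, 100]")
        ms, ss = _agg(self.per_fold_source_acc)
        mt, st = _agg(self.per_fold_target_acc)
        for stored, recomputed in ((self.mean_source, ms), (self.std_source, ss),
                                   (self.mean_target, mt), (self.std_target, st)):
            if abs(stored - recomputed) > 1e-9:
                raise ValueError("stored aggregates disagree with per-fold lists")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonReport:
    source_only: EvalReport
    adapted: EvalReport

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in (("source_only", self.source_only),
                          ("adapted", self.adapted)):
            rows.append({"model": name,
                         "mean_source": rep.mean_source,
                         "std_source": rep.std_source,
                         "mean_target": rep.mean_target,
                         "std_target": rep.std_target})
        return pd.DataFrame(rows)


@dataclass
class AblationReport:
    with_cycle: EvalReport
    without_cycle: EvalReport
    delta_target_mean: float

    def __post_init__(self):
        expect = self.with_cycle.mean_target - self.without_cycle.mean_target
        if abs(self.delta_target_mean - expect) > 1e-9:
            raise ValueError("delta_target_mean must equal with - without")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"arm": "with_cycle",
             "mean_target": self.with_cycle.mean_target,
             "std_target": self.with_cycle.std_target},
            {"arm": "without_cycle",
             "mean_target": self.without_cycle.mean_target,
             "std_target": self.without_cycle.std_target},
        ])


# ---------------------------------------------------------------------------
# k-fold protocol
# ---------------------------------------------------------------------------

def _fingerprint(cfg: TrainConfig, net_cfg, k: int, seed: int) -> str:
    payload = json.dumps({"train": asdict(cfg),
                          "net": asdict(net_cfg) if net_cfg else None,
                          "k": k, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fold_pair(pair: DomainDatasetPair, folds_src: FoldSplit, fold: int):
    tr = folds_src.train_idx(fold)
    return DomainDatasetPair(
        source_images=pair.source_images[tr],
        source_labels=pair.source_labels[tr],
        target_images=pair.target_images,   # unlabeled set fully available
        target_eval_labels=None,
        image_size=pair.image_size,
    )


def _run_protocol(pair: DomainDatasetPair, cfg: TrainConfig, k: int, seed: int,
                  net_cfg: NetShapeConfig | None, trainer) -> EvalReport:
    tgt_imgs, tgt_labels = pair.target_eval
    folds_src = make_stratified_folds(pair.source_labels, k, seed)
    folds_tgt = make_stratified_folds(tgt_labels, k, seed + 1)
    src_accs, tgt_accs, seeds = [], [], []
    for fold in range(k):
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0]
                        % (2 ** 31))
        seeds.append(fold_seed)
        fold_cfg = replace(cfg, seed=fold_seed)
        sub = _fold_pair(pair, folds_src, fold)
        state, _ = trainer(sub, fold_cfg, net_cfg)
        vs = folds_src.val_idx(fold)
        vt = folds_tgt.val_idx(fold)
        src_accs.append(verify(state, (pair.source_images[vs],
                                       pair.source_labels[vs])))
        tgt_accs.append(verify(state, (tgt_imgs[vt], tgt_labels[vt])))
    return EvalReport.from_folds(
        src_accs, tgt_accs, _fingerprint(cfg, net_cfg, k, seed), seeds)


def k_fold_evaluate(pair: DomainDatasetPair, cfg: TrainConfig, k: int,
                    seed: int, net_cfg: NetShapeConfig | None = None,
                    source_only: bool = False) -> EvalReport:
    """Re-train per fold and report held-out source / target accuracies."""
    if k < 2:
        raise ValueError("k must be >= 2")
    trainer = train_source_only if source_only else fit
    return _run_protocol(pair, cfg, k, seed, net_cfg, trainer)


def compare_adaptation(pair: DomainDatasetPair, cfg: TrainConfig, k: int,
                       seed: int, net_cfg: NetShapeConfig | None = None
                       ) -> ComparisonReport:
    """Source-only baseline vs adapted model on identical folds and seeds."""
    baseline = k_fold_evaluate(pair, cfg, k, seed, net_cfg, source_only=True)
    adapted = k_fold_evaluate(pair, cfg, k, seed, net_cfg, source_only=False)
    return ComparisonReport(source_only=baseline, adapted=adapted)


def ablate_cycle_consistency(pair: DomainDatasetPair, cfg: TrainConfig, k: int,
                             seed: int, net_cfg: NetShapeConfig | None = None
                             ) -> AblationReport:
    """Run the adaptation twice, identical except the cycle-consistency flag."""
    cfg_on = replace(cfg, cycle_consistency=True)
    cfg_off = replace(cfg, cycle_consistency=False)
    with_cycle = k_fold_evaluate(pair, cfg_on, k, seed, net_cfg)
    without_cycle = k_fold_evaluate(pair, cfg_off, k, seed, net_cfg)
    return AblationReport(
        with_cycle=with_cycle, without_cycle=without_cycle,
        delta_target_mean=with_cycle.mean_target - without_cycle.mean_target)


def full_protocol(pair: DomainDatasetPair, cfg: TrainConfig, k: int, seed: int,
                  net_cfg: NetShapeConfig | None = None
                  ) -> tuple[ComparisonReport, AblationReport]:
    """Comparison + ablation sharing the with-cycle arm (one set of folds)."""
    cfg_on = replace(cfg, cycle_consistency=True)
    cfg_off = replace(cfg, cycle_consistency=False)
    baseline = k_fold_evaluate(pair, cfg_on, k, seed, net_cfg, source_only=True)
    with_cycle = k_fold_evaluate(pair, cfg_on, k, seed, net_cfg)
    without_cycle = k_fold_evaluate(pair, cfg_off, k, seed, net_cfg)
    comparison = ComparisonReport(source_only=baseline, adapted=with_cycle)
    ablation = AblationReport(
        with_cycle=with_cycle, without_cycle=without_cycle,
        delta_target_mean=with_cycle.mean_target - without_cycle.mean_target)
    return comparison, ablation
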