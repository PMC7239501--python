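"""Loss functions for the four alternately trained modules.

All expectations are realized as batch means, and every probability is
clamped to [eps, 1-eps] before a log. Each function returns the scalar its
module MINIMIZES:

- discriminator (per domain):  -E[log D(x_real) + log(1-D(x_same')) + log(1-D(x_cross'))]
- decoder (per domain):        cycle term -E[log C(F(x_gen))_y] plus the
  adversarial confusion term, saturating E[log(1-D(x_same'))] or
  non-saturating -E[log D(x_same')] (the default);
- classifier:                  -E[log C(F(x_S))_y + log C(F(x_{S->T}))_y]
  with the generated images treated as constants;
- encoder: source + cycle classification terms, cross-domain adversarial
  terms, alpha/beta-weighted same-domain adversarial terms (alpha = beta =
  0.1 by default), and an L2 penalty on the latent codes.

Functions accept autodiff tensors (gradients flow) or plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, as_tensor


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.1        # same-domain source adversarial weight in L_F
    beta: float = 0.1         # same-domain target adversarial weight in L_F
    lambda_l2: float = 1e-4   # latent L2 regularization weight in L_F
    eps: float = 1e-7         # probability clamp before logs
    l2_on_images: bool = False  # alternative reading: penalize generated images

    def __post_init__(self):
        for name in ("alpha", "beta", "lambda_l2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.eps <= 1e-3:
            raise ValueError("eps must be in (0, 1e-3]")


@dataclass
class LossBundle:
    """Headline per-phase scalars plus the named sub-terms they sum from."""
    loss_D: float
    loss_G: float
    loss_C: float
    loss_F: float
    breakdown: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = [self.loss_D, self.loss_G, self.loss_C, self.loss_F]
        if not all(np.isfinite(vals)):
            raise FloatingPointError(
                f"non-finite loss: D={self.loss_D} G={self.loss_G} "
                f"C={self.loss_C} F={self.loss_F}; breakdown={self.breakdown}")

    def as_dict(self) -> dict:
        d = {"loss_D": self.loss_D, "loss_G": self.loss_G,
             "loss_C": self.loss_C, "loss_F": self.loss_F}
        d.update(self.breakdown)
        return d


def _checked(x, name: str) -> Tensor:
    t = as_tensor(x)
    if t.data.size == 0:
        raise ValueError(f"empty batch for {name}")
    return t


def _log(p: Tensor, eps: float) -> Tensor:
    return p.clip(eps, 1.0 - eps).log()


def _adv(d: Tensor, saturating: bool, eps: float) -> Tensor:
    """Generator-side adversarial term to minimize for discriminator output d:
    saturating E[log(1-d)] (literal) or non-saturating -E[log d]."""
    if saturating:
        return _log(1.0 - d, eps).mean()
    return -_log(d, eps).mean()


# ---------------------------------------------------------------------------


def discriminator_loss(d_real, d_gen_same, d_gen_cross, *, eps: float = 1e-7,
                       return_breakdown: bool = False):
    """One domain's discriminator loss (the two domains are summed by the
    trainer). ``d_real`` is D on real images of its domain, ``d_gen_same`` D
    on same-domain reconstructions, ``d_gen_cross`` D on cross-domain
    translations into this domain."""
    d_real = _checked(d_real, "d_real")
    d_gen_same = _checked(d_gen_same, "d_gen_same")
    d_gen_cross = _checked(d_gen_cross, "d_gen_cross")
    terms = {
        "real": -_log(d_real, eps).mean(),
        "gen_same": -_log(1.0 - d_gen_same, eps).mean(),
        "gen_cross": -_log(1.0 - d_gen_cross, eps).mean(),
    }
    total = terms["real"] + terms["gen_same"] + terms["gen_cross"]
    if return_breakdown:
        return total, {k: v.item() for k, v in terms.items()}
    return total


def decoder_loss(class_probs_cycle, d_gen_same, *, saturating: bool = False,
                 eps: float = 1e-7, return_breakdown: bool = False):
    """One domain's decoder loss: classification cycle-consistency term on the
    generated image (``class_probs_cycle`` = probability of the true source
    label after re-encoding; pass None to ablate it) plus the adversarial
    confusion term."""
    d_gen_same = _checked(d_gen_same, "d_gen_same")
    terms = {"adv": _adv(d_gen_same, saturating, eps)}
    if class_probs_cycle is not None:
        p = _checked(class_probs_cycle, "class_probs_cycle")
        terms["cycle"] = -_log(p, eps).mean()
    total = terms["adv"]
    if "cycle" in terms:
        total = terms["cycle"] + total
    if return_breakdown:
        return total, {k: v.item() for k, v in terms.items()}
    return total


def classifier_loss(probs_source, probs_cross=None, *, eps: float = 1e-7,
                    return_breakdown: bool = False):
    """Binary cross-entropy on real source images plus (unless ablated) on
    cross-domain translations of source images, which carry the source
    labels; the translations are constants here (no gradient into F or G)."""
    probs_source = _checked(probs_source, "probs_source")
    terms = {"source": -_log(probs_source, eps).mean()}
    if probs_cross is not None:
        probs_cross = _checked(probs_cross, "probs_cross")
        terms["cross"] = -_log(probs_cross, eps).mean()
    total = terms["source"] + terms.get("cross", 0.0)
    if return_breakdown:
        return total, {k: v.item() for k, v in terms.items()}
    return total


def encoder_loss(probs_source, probs_cycle_same, probs_cycle_cross,
                 d_cross_t, d_cross_s, d_same_s, d_same_t,
                 latents, w: LossWeights, *, saturating: bool = False,
                 return_breakdown: bool = False):
    """Encoder loss: label prediction on source, cycle-consistency terms
    (None to ablate), adversarial terms on cross-domain translations, the
    alpha/beta-weighted same-domain terms, and L2 regularization of the
    latent codes z_S, z_T (scaled by 1/batch)."""
    probs_source = _checked(probs_source, "probs_source")
    eps = w.eps
    terms = {"source": -_log(probs_source, eps).mean()}
    if probs_cycle_same is not None:
        terms["cycle_same"] = -_log(_checked(probs_cycle_same,
                                             "probs_cycle_same"), eps).mean()
    if probs_cycle_cross is not None:
        terms["cycle_cross"] = -_log(_checked(probs_cycle_cross,
                                              "probs_cycle_cross"), eps).mean()
    terms["adv_cross_t"] = _adv(_checked(d_cross_t, "d_cross_t"), saturating, eps)
    terms["adv_cross_s"] = _adv(_checked(d_cross_s, "d_cross_s"), saturating, eps)
    terms["adv_same_s"] = w.alpha * _adv(_checked(d_same_s, "d_same_s"),
                                         saturating, eps)
    terms["adv_same_t"] = w.beta * _adv(_checked(d_same_t, "d_same_t"),
                                        saturating, eps)
    if w.lambda_l2 > 0 and latents is not None:
        z_s, z_t = latents
        z_s, z_t = as_tensor(z_s), as_tensor(z_t)
        batch = z_s.shape[0]
        terms["l2"] = (w.lambda_l2 / batch) * ((z_s * z_s).sum()
                                               + (z_t * z_t).sum())
    total = None
    for v in terms.values():
        total = v if total is None else total + v
    if return_breakdown:
        return total, {k: v.item() for k, v in terms.items()}
    return total
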