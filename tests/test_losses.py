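"""The loss formulas against hand-computed values and a per-sample oracle."""

import math

import numpy as np
import pytest

from cycleda import (LossWeights, classifier_loss, decoder_loss,
                     discriminator_loss, encoder_loss)

LN2 = math.log(2.0)


def t(*vals):
    return np.array(vals, dtype=np.float64)


# ---------------------------------------------------------------------------
# per-sample scalar oracle (plain math.log, no shared code with the package)
# ---------------------------------------------------------------------------

def oracle_disc(d_real, d_same, d_cross):
    per = [-(math.log(a) + math.log(1 - b) + math.log(1 - c))
           for a, b, c in zip(d_real, d_same, d_cross)]
    return sum(per) / len(per)


def oracle_dec(p_cycle, d_same, saturating):
    out = 0.0
    for p, d in zip(p_cycle, d_same):
        adv = math.log(1 - d) if saturating else -math.log(d)
        out += -math.log(p) + adv
    return out / len(d_same)


def oracle_clf(p_src, p_cross):
    per = [-math.log(a) - math.log(b) for a, b in zip(p_src, p_cross)]
    return sum(per) / len(per)


def oracle_enc(p_src, p_cs, p_cc, dct, dcs, dss, dtt, z_s, z_t, w, saturating):
    def adv(ds):
        if saturating:
            return sum(math.log(1 - d) for d in ds) / len(ds)
        return sum(-math.log(d) for d in ds) / len(ds)

    cls = sum(-math.log(a) - math.log(b) - math.log(c)
              for a, b, c in zip(p_src, p_cs, p_cc)) / len(p_src)
    l2 = w.lambda_l2 * (float((z_s ** 2).sum()) + float((z_t ** 2).sum())) \
        / z_s.shape[0]
    return (cls + adv(dct) + adv(dcs) + w.alpha * adv(dss)
            + w.beta * adv(dtt) + l2)


# ---------------------------------------------------------------------------


def test_discriminator_loss_hand_values():
    half = t(0.5, 0.5)
    assert discriminator_loss(half, half, half).item() == pytest.approx(3 * LN2, abs=1e-6)
    near0, near1 = t(1e-9, 1e-9), t(1 - 1e-9, 1 - 1e-9)
    assert discriminator_loss(near1, near0, near0).item() == pytest.approx(0.0, abs=1e-4)
    got = discriminator_loss(t(0.8), t(0.3), t(0.4)).item()
    assert got == pytest.approx(-(math.log(.8) + math.log(.7) + math.log(.6)), abs=1e-6)
    assert got == pytest.approx(1.0906, abs=1e-4)


def test_decoder_loss_hand_values():
    assert decoder_loss(t(0.5), t(0.5), saturating=True).item() == pytest.approx(0.0, abs=1e-6)
    assert decoder_loss(t(0.5), t(0.5), saturating=False).item() == pytest.approx(2 * LN2, abs=1e-6)
    assert decoder_loss(t(0.9), t(0.8), saturating=True).item() == \
        pytest.approx(-math.log(0.9) + math.log(0.2), abs=1e-6)


def test_classifier_loss_hand_values():
    assert classifier_loss(t(0.5), t(0.5)).item() == pytest.approx(2 * LN2, abs=1e-6)
    one = t(1 - 1e-9)
    assert classifier_loss(one, one).item() == pytest.approx(0.0, abs=1e-5)
    assert classifier_loss(t(0.8), t(0.6)).item() == \
        pytest.approx(-math.log(0.8) - math.log(0.6), abs=1e-6)


def test_encoder_loss_hand_values():
    w0 = LossWeights(alpha=0, beta=0, lambda_l2=0)
    one, half = t(1 - 1e-9), t(0.5)
    z = np.zeros((1, 2))
    got = encoder_loss(one, one, one, half, half, half, half, (z, z), w0,
                       saturating=True).item()
    assert got == pytest.approx(-2 * LN2, abs=1e-5)

    w = LossWeights(alpha=0.1, beta=0.1, lambda_l2=0)
    got = encoder_loss(half, half, half, half, half, half, half, (z, z), w,
                       saturating=True).item()
    assert got == pytest.approx(0.8 * LN2, abs=1e-6)


def test_default_weights_match_shipped_values():
    w = LossWeights()
    assert w.alpha == 0.1 and w.beta == 0.1


@pytest.mark.parametrize("saturating", [False, True])
def test_losses_match_per_sample_oracle(rng, saturating):
    w = LossWeights(alpha=0.1, beta=0.1, lambda_l2=1e-3)
    for _ in range(25):
        n = int(rng.integers(1, 9))
        p = {k: rng.uniform(0.02, 0.98, size=n) for k in
             ("src", "cs", "cc", "dr", "ds", "dc", "dct", "dcs", "dss", "dtt")}
        z_s = rng.normal(size=(n, 4)).astype(np.float32)
        z_t = rng.normal(size=(n, 4)).astype(np.float32)

        assert discriminator_loss(p["dr"], p["ds"], p["dc"]).item() == \
            pytest.approx(oracle_disc(p["dr"], p["ds"], p["dc"]), abs=1e-6)
        assert decoder_loss(p["cs"], p["ds"], saturating=saturating).item() == \
            pytest.approx(oracle_dec(p["cs"], p["ds"], saturating), abs=1e-6)
        assert classifier_loss(p["src"], p["cc"]).item() == \
            pytest.approx(oracle_clf(p["src"], p["cc"]), abs=1e-6)
        got = encoder_loss(p["src"], p["cs"], p["cc"], p["dct"], p["dcs"],
                           p["dss"], p["dtt"], (z_s, z_t), w,
                           saturating=saturating).item()
        want = oracle_enc(p["src"], p["cs"], p["cc"], p["dct"], p["dcs"],
                          p["dss"], p["dtt"], z_s, z_t, w, saturating)
        assert got == pytest.approx(want, rel=1e-6, abs=1e-6)


def test_clamp_keeps_losses_finite_at_exact_0_and_1():
    z = np.zeros((2, 2))
    zero, one = t(0.0, 0.0), t(1.0, 1.0)
    for loss in (discriminator_loss(zero, one, one),
                 decoder_loss(zero, zero),
                 classifier_loss(one, zero),
                 encoder_loss(zero, one, zero, one, zero, one, zero,
                              (z, z), LossWeights())):
        assert np.isfinite(loss.item())


def test_loss_is_mean_of_per_sample_losses(rng):
    d = rng.uniform(0.1, 0.9, size=6)
    s = rng.uniform(0.1, 0.9, size=6)
    c = rng.uniform(0.1, 0.9, size=6)
    whole = discriminator_loss(d, s, c).item()
    per = [discriminator_loss(d[i:i + 1], s[i:i + 1], c[i:i + 1]).item()
           for i in range(6)]
    assert whole == pytest.approx(np.mean(per), rel=1e-6)


def test_zero_alpha_beta_removes_same_domain_terms(rng):
    n = 4
    args = [rng.uniform(0.1, 0.9, size=n) for _ in range(7)]
    z = rng.normal(size=(n, 3))
    w0 = LossWeights(alpha=0.0, beta=0.0, lambda_l2=0)
    _, br = encoder_loss(*args, (z, z), w0, return_breakdown=True)
    assert br["adv_same_s"] == 0.0 and br["adv_same_t"] == 0.0
    total, br = encoder_loss(*args, (z, z), LossWeights(lambda_l2=1e-3),
                             return_breakdown=True)
    assert total.item() == pytest.approx(sum(br.values()), abs=1e-6)


def test_empty_batch_raises():
    empty = np.array([])
    with pytest.raises(ValueError, match="empty"):
        discriminator_loss(empty, empty, empty)
    with pytest.raises(ValueError, match="empty"):
        classifier_loss(empty)


def test_invalid_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(alpha=-1)
    with pytest.raises(ValueError):
        LossWeights(eps=0.5)
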