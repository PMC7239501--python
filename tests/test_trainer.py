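"""Phase isolation, label hygiene, determinism, and loop accounting."""

import numpy as np
import pytest

from cycleda import TrainConfig, fit, train_source_only, train_step
from cycleda.dataio import DomainDatasetPair
from cycleda.networks import checkpoint_bytes
from cycleda.trainer import _make_state, _to_pm1

PHASE_OWNERSHIP = {"D": {"D_S", "D_T"}, "G": {"G_S", "G_T"},
                   "C": {"C"}, "F": {"F"}}


def batches(pair, n=8):
    return ((_to_pm1(pair.source_images[:n]), pair.source_labels[:n]),
            _to_pm1(pair.target_images[:n]))


def snapshot_diff(before, after):
    changed = set()
    for name in before:
        for k in before[name]:
            if not np.array_equal(before[name][k], after[name][k]):
                changed.add(name)
                break
    return changed


def test_each_phase_changes_exactly_its_own_parameters(tiny_pair, tiny_net,
                                                       quick_cfg):
    state = _make_state(tiny_pair, quick_cfg, tiny_net, source_only=False)
    bs, bt = batches(tiny_pair)
    observed = {}
    last = {"snap": state.bundle.param_snapshot()}

    def audit(phase):
        now = state.bundle.param_snapshot()
        observed[phase] = snapshot_diff(last["snap"], now)
        last["snap"] = now

    train_step(state, bs, bt, phase_callback=audit)
    for phase, owned in PHASE_OWNERSHIP.items():
        assert observed[phase] == owned, \
            f"phase {phase} changed {observed[phase]}, expected {owned}"


def test_unequal_batch_sizes_rejected(tiny_pair, tiny_net, quick_cfg):
    state = _make_state(tiny_pair, quick_cfg, tiny_net, source_only=False)
    (xs, ys), xt = batches(tiny_pair)
    with pytest.raises(ValueError, match="unequal"):
        train_step(state, (xs, ys), xt[:4])


def test_step_losses_are_finite_and_logged(tiny_pair, tiny_net, quick_cfg):
    state = _make_state(tiny_pair, quick_cfg, tiny_net, source_only=False)
    lb = train_step(state, *batches(tiny_pair))
    d = lb.as_dict()
    assert all(np.isfinite(v) for v in d.values())
    # breakdown sums to headline values
    assert d["loss_D"] == pytest.approx(
        sum(v for k, v in d.items() if k.startswith(("d_s_", "d_t_"))), abs=1e-5)
    assert d["loss_F"] == pytest.approx(
        sum(v for k, v in d.items() if k.startswith("f_")), abs=1e-5)


def test_cycle_gradient_reaches_decoders(tiny_pair, tiny_net, quick_cfg):
    """With discriminators frozen at exactly 0.5 output, only the cycle
    term can move the decoders; ablating it must leave them untouched."""
    from dataclasses import replace

    def frozen_state(cfg):
        state = _make_state(tiny_pair, cfg, tiny_net, source_only=False)
        for disc in (state.bundle.D_S, state.bundle.D_T):
            final = [m for m in disc.net.layers if hasattr(m, "kernel")][-1]
            final.weight.data[...] = 0.0
            final.bias.data[...] = 0.0
        return state

    bs, bt = batches(tiny_pair)
    # run the G phase first so the D update cannot un-freeze the 0.5 output
    quick_cfg = replace(quick_cfg, phase_order=("G", "D", "C", "F"))

    state_off = frozen_state(replace(quick_cfg, cycle_consistency=False))
    before = {k: v.data.copy()
              for k, v in state_off.bundle.G_S.parameters().items()}
    train_step(state_off, bs, bt)
    for k, v in state_off.bundle.G_S.parameters().items():
        np.testing.assert_array_equal(v.data, before[k])

    state_on = frozen_state(replace(quick_cfg, cycle_consistency=True))
    before = {k: v.data.copy()
              for k, v in state_on.bundle.G_S.parameters().items()}
    train_step(state_on, bs, bt)
    assert any(np.abs(v.data - before[k]).max() > 0
               for k, v in state_on.bundle.G_S.parameters().items())


def test_cycle_flag_drops_terms_from_breakdown(tiny_pair, tiny_net, quick_cfg):
    from dataclasses import replace
    cfg_off = replace(quick_cfg, cycle_consistency=False)
    state = _make_state(tiny_pair, cfg_off, tiny_net, source_only=False)
    lb = train_step(state, *batches(tiny_pair))
    keys = set(lb.breakdown)
    assert "g_s_cycle" not in keys and "c_cross" not in keys
    assert "f_cycle_same" not in keys and "f_cycle_cross" not in keys


def test_training_never_reads_target_eval_labels(tiny_pair, tiny_net, quick_cfg):
    corrupted = DomainDatasetPair(
        tiny_pair.source_images, tiny_pair.source_labels,
        tiny_pair.target_images,
        1 - tiny_pair.target_eval_labels,   # garbage labels
        tiny_pair.image_size)
    state_a, _ = fit(tiny_pair, quick_cfg, tiny_net)
    state_b, _ = fit(corrupted, quick_cfg, tiny_net)
    assert checkpoint_bytes(state_a.bundle) == checkpoint_bytes(state_b.bundle)


def test_fixed_seed_reproduces_loss_trajectory(tiny_pair, tiny_net, quick_cfg):
    _, log_a = fit(tiny_pair, quick_cfg, tiny_net)
    _, log_b = fit(tiny_pair, quick_cfg, tiny_net)
    assert log_a == log_b


def test_zero_epochs_returns_initial_model(tiny_pair, tiny_net):
    cfg = TrainConfig(epochs=0, batch_size=16, seed=0)
    state, log = fit(tiny_pair, cfg, tiny_net)
    assert log == [] and state.step == 0


def test_step_count_matches_epoch_arithmetic(tiny_net):
    from cycleda import default_benchmark_config, generate_dataset
    pair = generate_dataset(default_benchmark_config(seed=1, n_per_domain=64))
    cfg = TrainConfig(epochs=1, batch_size=16, seed=0)
    _, log = fit(pair, cfg, tiny_net)
    assert len(log) == 4
    assert [row["step"] for row in log] == [1, 2, 3, 4]


def test_source_only_trains_only_f_and_c(tiny_pair, tiny_net, quick_cfg):
    state, log = train_source_only(tiny_pair, quick_cfg, tiny_net)
    assert set(state.bundle.modules()) == {"F", "C"}
    assert len(log) == 4 * quick_cfg.epochs
    assert all(np.isfinite(row["loss_C"]) for row in log)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr_F=0.0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=1)
    with pytest.raises(ValueError):
        TrainConfig(adam_beta2=1.0)
    with pytest.raises(ValueError):
        TrainConfig(phase_order=("D", "G", "C"))


def test_fit_writes_run_artifacts(tiny_pair, tiny_net, quick_cfg, tmp_path):
    import os
    fit(tiny_pair, quick_cfg, tiny_net, run_dir=str(tmp_path))
    assert os.path.exists(tmp_path / "checkpoints" / "final.npz")
    assert os.path.exists(tmp_path / "logs" / "train.jsonl")
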