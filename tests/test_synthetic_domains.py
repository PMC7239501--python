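"""Generator behaviour: rendering, transforms, reproducibility, shift probe."""

import numpy as np
import pytest

from cycleda import (ClassSpec, DomainSpec, SyntheticConfig,
                     apply_domain_transform, default_benchmark_config,
                     domain_shift_probe, generate_dataset,
                     render_class_instance)
from cycleda.dataio import DomainDatasetPair
from cycleda.synthetic_domains import with_target_appearance


def test_render_is_deterministic_given_rng_state():
    spec = ClassSpec(0, "disc", 0.3)
    a = render_class_instance(spec, np.random.default_rng(5), 32)
    b = render_class_instance(spec, np.random.default_rng(5), 32)
    np.testing.assert_array_equal(a, b)


def test_centered_disc_is_mirror_symmetric():
    spec = ClassSpec(0, "disc", 0.0)
    img = render_class_instance(spec, np.random.default_rng(0), 32)
    np.testing.assert_allclose(img, img[:, ::-1], atol=1e-6)
    assert img.min() >= 0.0 and img.max() <= 1.0


def test_disc_and_annulus_differ_in_mean_intensity():
    rng = np.random.default_rng(0)
    disc = render_class_instance(ClassSpec(0, "disc", 0.0), rng, 32)
    rng = np.random.default_rng(0)
    annulus = render_class_instance(ClassSpec(1, "annulus", 0.0), rng, 32)
    # the annulus hollow center removes foreground mass: direct pixel sums
    assert disc.sum() > annulus.sum()
    assert abs(disc.mean() - annulus.mean()) > 0.01


def test_unknown_geometry_rejected():
    with pytest.raises(ValueError, match="geometry"):
        ClassSpec(0, "star", 0.1)


@pytest.mark.parametrize("bad", [
    dict(class_id=2, geometry="disc"),
    dict(class_id=0, geometry="disc", geometry_jitter=0.9),
])
def test_class_spec_validation(bad):
    with pytest.raises(ValueError):
        ClassSpec(**bad)


def test_identity_appearance_is_identity():
    img = np.random.default_rng(0).uniform(size=(16, 16)).astype(np.float32)
    out = apply_domain_transform(img, DomainSpec("source", ()))
    np.testing.assert_allclose(out, img, atol=1e-7)


def test_intensity_scale_zero_gives_black_image():
    img = np.random.default_rng(0).uniform(size=(16, 16)).astype(np.float32)
    spec = DomainSpec("source", ({"kind": "intensity_scale", "a": 0.0, "b": 0.0},))
    assert apply_domain_transform(img, spec).max() == 0.0


def test_gamma_two_squares_constant_half():
    img = np.full((8, 8), 0.5, dtype=np.float32)
    spec = DomainSpec("target", ({"kind": "gamma", "gamma": 2.0},))
    np.testing.assert_allclose(apply_domain_transform(img, spec), 0.25,
                               atol=1e-6)


def test_transform_parameters_validated_at_config_time():
    with pytest.raises(ValueError, match="gamma"):
        DomainSpec("target", ({"kind": "gamma", "gamma": -1.0},))
    with pytest.raises(ValueError, match="unknown transform"):
        DomainSpec("target", ({"kind": "hounsfield"},))


def test_generate_dataset_exact_balance_and_determinism():
    cfg = default_benchmark_config(seed=11, n_per_domain=100)
    pair = generate_dataset(cfg)
    assert (pair.source_labels == 0).sum() == 50
    assert (pair.source_labels == 1).sum() == 50
    assert (pair.target_eval_labels == 0).sum() == 50
    pair2 = generate_dataset(default_benchmark_config(seed=11, n_per_domain=100))
    np.testing.assert_array_equal(pair.source_images, pair2.source_images)
    np.testing.assert_array_equal(pair.target_images, pair2.target_images)
    np.testing.assert_array_equal(pair.source_labels, pair2.source_labels)


def test_generate_dataset_rejects_tiny_n():
    with pytest.raises(ValueError, match="n_per_domain"):
        SyntheticConfig(n_per_domain=2)


def test_probe_is_chance_level_without_shift():
    cfg = SyntheticConfig(image_size=32, n_per_domain=150, seed=4)
    score = domain_shift_probe(generate_dataset(cfg))
    assert abs(score - 0.5) <= 0.1


def test_probe_is_chance_level_on_duplicated_domain():
    pair = generate_dataset(default_benchmark_config(seed=5, n_per_domain=150))
    dup = DomainDatasetPair(pair.source_images, pair.source_labels,
                            pair.source_images.copy(), pair.source_labels,
                            pair.image_size)
    assert abs(domain_shift_probe(dup) - 0.5) <= 0.1


def test_probe_detects_benchmark_shift():
    pair = generate_dataset(default_benchmark_config(seed=6, n_per_domain=200))
    assert domain_shift_probe(pair) > 0.9


def test_probe_needs_enough_samples():
    pair = generate_dataset(default_benchmark_config(seed=6, n_per_domain=8))
    with pytest.raises(ValueError, match="at least 10"):
        domain_shift_probe(pair)


@pytest.mark.parametrize("knob,param,grid", [
    ("blur", "sigma", [0.0, 0.7, 1.4, 2.1]),
    ("background_texture", "amplitude", [0.0, 0.2, 0.4, 0.6]),
])
def test_shift_probe_monotone_in_shift_strength(knob, param, grid):
    """More blur / stronger texture must not make domains less separable
    (tolerance 0.05 between consecutive grid points, 3 seeds, n=500)."""
    scores = []
    for value in grid:
        seed_scores = []
        for seed in (0, 1, 2):
            cfg = default_benchmark_config(seed=seed, n_per_domain=500)
            cfg = with_target_appearance(cfg, **{knob: {param: value}})
            seed_scores.append(domain_shift_probe(generate_dataset(cfg)))
        scores.append(np.mean(seed_scores))
    for lo, hi in zip(scores, scores[1:]):
        assert hi >= lo - 0.05, f"probe dropped from {lo:.3f} to {hi:.3f}"


def test_within_domain_classes_stay_separable():
    """A linear pixel classifier reaches >=0.9 within each domain, so the
    fixture can support adaptation experiments."""
    from sklearn.linear_model import LogisticRegression
    pair = generate_dataset(default_benchmark_config(seed=9, n_per_domain=300))
    for images, labels in (pair.source, pair.target_eval):
        flat = images.reshape(len(images), -1)
        clf = LogisticRegression(max_iter=500).fit(flat[::2], labels[::2])
        assert clf.score(flat[1::2], labels[1::2]) >= 0.9
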