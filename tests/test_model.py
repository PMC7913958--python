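"""Architecture contracts: parameter accounting, probability outputs,
absence of shortcuts, checkpoint round-trips."""

import numpy as np
import pytest

from bifocal import nn
from bifocal.model import (
    BCNNConfig,
    BifocalNet,
    SubnetNet,
    build_bcnn,
    build_subnet,
    count_parameters,
    load_model,
    parameter_ratio,
    resnet50_parameter_count,
    save_model,
    _iter_modules,
)

TINY = BCNNConfig(num_classes=6, base_width=4, blocks_per_stage=(1, 1), input_sizes=(32, 16), rng_seed=3)


def test_resnet50_count_matches_literature_value():
    """The 50-layer residual reference with the canonical 1000-class head
    counts 25,557,032 trainable parameters, the figure reported by standard
    implementations."""
    assert resnet50_parameter_count(num_classes=1000) == 25_557_032


def test_default_bifocal_is_under_half_the_reference():
    model = build_bcnn()
    ratio = parameter_ratio(model, resnet50_parameter_count(6))
    assert ratio <= 0.5
    assert model.within_parameter_budget


def test_subnet_is_a_strict_submodel():
    cfg = BCNNConfig(num_classes=6, base_width=8, blocks_per_stage=(1, 1, 1, 1), input_sizes=(64, 32))
    assert count_parameters(build_subnet(cfg)) < count_parameters(build_bcnn(cfg))
    assert parameter_ratio(build_subnet(cfg), build_bcnn(cfg)) < 1.0


def test_parameter_ratio_of_model_with_itself_is_one():
    m = build_subnet(TINY)
    assert parameter_ratio(m, m) == 1.0
    with pytest.raises(ValueError):
        parameter_ratio(m, 0)


def test_forward_returns_normalized_probabilities(rng):
    model = build_bcnn(TINY)
    wide = rng.normal(size=(5, 3, 32, 32)).astype(np.float32)
    narrow = rng.normal(size=(5, 3, 16, 16)).astype(np.float32)
    probs = model.predict_proba(wide, narrow)
    assert probs.shape == (5, 6)
    assert np.all(probs >= 0)
    assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6


def test_batch_permutation_permutes_outputs(rng):
    """No cross-example leakage in eval mode: permuting the batch permutes
    the outputs identically (oracle: per-example forward)."""
    model = build_bcnn(TINY)
    wide = rng.normal(size=(4, 3, 32, 32)).astype(np.float32)
    narrow = rng.normal(size=(4, 3, 16, 16)).astype(np.float32)
    probs = model.predict_proba(wide, narrow)
    perm = np.array([2, 0, 3, 1])
    probs_perm = model.predict_proba(wide[perm], narrow[perm])
    np.testing.assert_allclose(probs_perm, probs[perm], rtol=1e-5, atol=1e-6)
    singles = np.concatenate(
        [model.predict_proba(wide[i : i + 1], narrow[i : i + 1]) for i in range(4)]
    )
    np.testing.assert_allclose(singles, probs, rtol=1e-4, atol=1e-5)


def test_subnets_contain_no_shortcut_junctions():
    """Architecture introspection: the paths are pure layer sequences of
    conv/BN/ReLU/pool — no module implements an additive skip."""
    model = build_bcnn(TINY)
    allowed = (nn.Conv2d, nn.BatchNorm2d, nn.ReLU, nn.MaxPool2d, nn.GlobalAvgPool, nn.Linear)
    for layer in _iter_modules(model):
        assert isinstance(layer, allowed)
    for path in (model.wide_path, model.narrow_path):
        assert isinstance(path, nn.Sequential)


def test_wide_input_changes_output(rng):
    """The context path is wired in: zeroing the wide tile changes the
    prediction."""
    model = build_bcnn(TINY)
    wide = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
    narrow = rng.normal(size=(2, 3, 16, 16)).astype(np.float32)
    a = model.predict_proba(wide, narrow)
    b = model.predict_proba(np.zeros_like(wide), narrow)
    assert np.abs(a - b).max() > 1e-6


def test_checkpoint_roundtrip_preserves_outputs(tmp_path, rng):
    model = build_bcnn(TINY)
    wide = rng.normal(size=(3, 3, 32, 32)).astype(np.float32)
    narrow = rng.normal(size=(3, 3, 16, 16)).astype(np.float32)
    before = model.predict_proba(wide, narrow)
    save_model(model, tmp_path / "ckpt.npz")
    loaded = load_model(tmp_path / "ckpt.npz")
    assert isinstance(loaded, BifocalNet)
    np.testing.assert_array_equal(loaded.predict_proba(wide, narrow), before)


def test_oversized_config_flags_budget_violation():
    big = BCNNConfig(num_classes=6, base_width=96, blocks_per_stage=(3, 4, 6, 3), input_sizes=(64, 32))
    with pytest.warns(UserWarning, match="parameter budget"):
        model = build_bcnn(big)
    assert not model.within_parameter_budget


def test_wrong_input_size_is_rejected(rng):
    model = build_bcnn(TINY)
    with pytest.raises(ValueError, match="input size"):
        model.forward(
            rng.normal(size=(1, 3, 64, 64)).astype(np.float32),
            rng.normal(size=(1, 3, 16, 16)).astype(np.float32),
        )


def test_closed_form_layer_counts(rng):
    lin = nn.Linear(10, 4, rng=rng)
    assert sum(p.size for p in lin.parameters()) == 4 * (10 + 1)
    conv = nn.Conv2d(3, 8, 5, bias=True, rng=rng)
    assert sum(p.size for p in conv.parameters()) == 8 * (3 * 25 + 1)
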