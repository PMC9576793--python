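"""Architecture-search algebra: softmax weights, mixture identities,
genotype derivation, and a micro search run."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratseg import (
    Genotype,
    SearchConfig,
    SearchState,
    TrainingSet,
    derive_genotype,
    gamma_weights,
    generate_phantom,
    search_architecture,
)
from stratseg.nas import SearchLog, mixed_block_forward, split_cases
from stratseg.nn import OP_ORDER, MixedBlock, OpSpec, make_candidates

RNG = np.random.default_rng(7)


def test_uniform_logits_give_equal_weights():
    w = gamma_weights(np.zeros(6))
    np.testing.assert_allclose(w, np.full(6, 1 / 6), atol=1e-15)


def test_dominant_logit_closed_form():
    w = gamma_weights(np.array([10.0, 0, 0, 0, 0, 0]))
    expected = np.exp(10) / (np.exp(10) + 5)
    assert w[0] == pytest.approx(expected, rel=1e-12)
    assert w[0] == pytest.approx(0.99977, abs=1e-5)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-200, max_value=200, allow_nan=False),
        min_size=6,
        max_size=6,
    )
)
def test_gamma_weights_normalized_and_positive(logits):
    w = gamma_weights(np.array(logits))
    assert abs(w.sum() - 1.0) < 1e-12
    assert (w > 0).all()


def test_gamma_weights_reject_non_finite():
    with pytest.raises(ValueError, match="finite"):
        gamma_weights(np.array([np.nan, 0, 0, 0, 0, 0]))


def test_one_hot_mixture_equals_single_op():
    ops = make_candidates(2, 3, np.random.default_rng(0), dtype=np.float64)
    x = RNG.standard_normal((2, 4, 6, 6))
    weights = np.zeros(6)
    weights[3] = 1.0
    mixed = mixed_block_forward(x, ops, weights)
    np.testing.assert_allclose(mixed, ops[3].forward(x), atol=1e-12)


def test_mixture_is_convex_combination():
    ops = make_candidates(1, 2, np.random.default_rng(1), dtype=np.float64)
    x = RNG.standard_normal((1, 4, 6, 6))
    w = gamma_weights(RNG.standard_normal(6))
    mixed = mixed_block_forward(x, ops, w)
    manual = sum(wk * op.forward(x) for wk, op in zip(w, ops))
    np.testing.assert_allclose(mixed, manual, atol=1e-12)


def test_mixed_block_spatial_shape_preserved():
    block = MixedBlock(2, 4, np.random.default_rng(2))
    x = RNG.standard_normal((2, 8, 16, 16)).astype(np.float32)
    out = block.forward(x, np.full(6, 1 / 6))
    assert out.shape == (4, 8, 16, 16)


def test_mixed_block_gamma_gradient_matches_finite_differences():
    block = MixedBlock(1, 2, np.random.default_rng(3), dtype=np.float64)
    x = RNG.standard_normal((1, 4, 4, 4))
    gam = gamma_weights(np.array([0.3, -0.2, 0.5, 0.0, 0.1, -0.4]))

    def loss(g):
        return float((block.forward(x, g) ** 2).sum())

    out = block.forward(x, gam)
    block.backward(2 * out)
    eps = 1e-6
    for k in (0, 3, 5):
        gp = gam.copy()
        gp[k] += eps
        gm = gam.copy()
        gm[k] -= eps
        num = (loss(gp) - loss(gm)) / (2 * eps)
        assert num == pytest.approx(block.gamma_grad[k], rel=1e-6, abs=1e-6)


def test_derive_genotype_argmax_and_tie_rules():
    state = SearchState(
        {
            "enc0": np.array([0.1, 2.0, -1.0, 0.0, 0.0, 0.0]),
            "enc1": np.zeros(6),
            "dec0": np.array([1.0, 1.0, 1.0, 5.0, 1.0, 5.0]),
        }
    )
    geno = derive_genotype(state)
    assert geno.op_specs["enc0"] == OpSpec("2D", 5)  # index 1
    assert geno.op_specs["enc1"] == OpSpec("2D", 3)  # all-equal tie -> index 0
    assert geno.op_specs["dec0"] == OpSpec("3D", 5)  # tie among maxima -> lowest index
    # softmax is order-preserving: gammas give the same selection
    gam_state = SearchState({k: gamma_weights(v) for k, v in state.alphas.items()})
    assert derive_genotype(gam_state).op_specs == geno.op_specs


def test_genotype_json_round_trip():
    geno = Genotype(
        {"enc0": OpSpec("P3D", 5), "enc1": OpSpec("3D", 3), "dec0": OpSpec("2D", 3)},
        levels=2,
        base_channels=8,
    )
    again = Genotype.from_json(geno.to_json())
    assert again.op_specs == geno.op_specs
    assert (again.levels, again.base_channels) == (2, 8)


def test_split_cases_two_to_one():
    w, a = split_cases(6, 2 / 3)
    assert (len(w), len(a)) == (4, 2)
    assert set(w) | set(a) == set(range(6))
    with pytest.raises(ValueError, match="partitions"):
        split_cases(1, 2 / 3)


def test_zero_epoch_search_returns_first_op_everywhere(small_training):
    train_set, registry = small_training
    geno = search_architecture(
        train_set,
        "anchor_seg",
        registry,
        SearchConfig(epochs=0, levels=2, base_channels=4),
        seed=0,
    )
    assert all(spec == OpSpec("2D", 3) for spec in geno.op_specs.values())
    assert set(geno.op_specs) == {"enc0", "enc1", "dec0"}


def test_micro_search_is_reproducible_and_valid(registry):
    """A small executed search: every selection is in the operator space,
    logged losses are finite, and the same seed reproduces the genotype."""
    from stratseg import PhantomConfig, StructureSpec

    cases = []
    for seed in (21, 22, 23):
        config = PhantomConfig(
            shape=(16, 24, 24),
            anchor=StructureSpec(3, (4.0, 6.0), 300.0),
            mid=StructureSpec(2, (3.0, 4.0), 100.0),
            small_hard=StructureSpec(2, (2.0, 3.0), 30.0),
            seed=seed,
        )
        vol, ss = generate_phantom(config)
        cases.append((vol, ss))
    train_set = TrainingSet(cases)
    config = SearchConfig(epochs=2, levels=2, base_channels=4)
    log = SearchLog()
    g1 = search_architecture(train_set, "anchor_seg", registry, config, seed=9, log=log)
    g2 = search_architecture(train_set, "anchor_seg", registry, config, seed=9)
    assert g1.op_specs == g2.op_specs
    assert all((s.kind, s.kernel) in OP_ORDER for s in g1.op_specs.values())
    assert np.isfinite(log.weight_losses).all() and np.isfinite(log.arch_losses).all()
    for gammas in log.gamma_history:
        for vec in gammas.values():
            assert abs(vec.sum() - 1) < 1e-9 and (vec > 0).all()
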