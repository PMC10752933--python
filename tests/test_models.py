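"""Model architecture and output-head tests.

The parameter-count oracle below is a closed-form gate-arithmetic
computation, independent of the implementation's weight arrays.
"""

import itertools

import numpy as np
import pytest

from glucast._nn import MLP, Dense
from glucast.models import (
    DEFAULT_QUANTILES,
    ForecastModel,
    RecurrentConfig,
    build_model,
    cat_head,
    count_parameters,
    format_parameter_count,
    init_hidden_from_statics,
    quantile_loss,
)

GATES = {"rnn": 1, "gru": 3, "lstm": 4}


def closed_form_count(cell, n_layers, n_units, integration="none", static_dim=0,
                      n_features=7, n_outputs=1):
    """Gate arithmetic under the dual-bias convention."""
    g = GATES[cell]
    u = n_units
    total = g * ((n_features + u) * u + 2 * u)  # first layer
    total += (n_layers - 1) * g * ((u + u) * u + 2 * u)  # deeper layers
    if integration in ("init", "both"):
        init = (static_dim + 1) * u + (u + 1) * u
        total += init * (2 if cell == "lstm" else 1)
    if integration in ("cat", "both"):
        s = static_dim
        total += (s + 1) * 2 * s + (2 * s + 1) * 2  # MLP_cat
        total += (u + 2 + 1) * 2 * u + (2 * u + 1) * u + (u + 1) * n_outputs
    else:
        total += u * n_outputs + n_outputs  # linear head
    return total


class TestArchitecture:
    def test_dilation_schedule_exponential(self):
        cfg = RecurrentConfig("rnn", 3, 16, dilated=True)
        assert cfg.dilation_schedule() == [1, 2, 4]
        model = build_model(cfg)
        assert [l.dilation for l in model.layers] == [1, 2, 4]

    def test_dilation_schedule_vanilla(self):
        cfg = RecurrentConfig("gru", 5, 16, dilated=False)
        assert cfg.dilation_schedule() == [1, 1, 1, 1, 1]

    def test_invalid_enums_rejected(self):
        with pytest.raises(ValueError):
            RecurrentConfig("cnn", 3, 16)
        with pytest.raises(ValueError):
            RecurrentConfig("rnn", 3, 16, integration="concat")
        with pytest.raises(ValueError):
            RecurrentConfig("rnn", 3, 16, integration="cat", static_dim=0)

    @pytest.mark.parametrize(
        "cell,layers,units,expected",
        [("rnn", 3, 16, 1505), ("lstm", 5, 32, 39073)],
    )
    def test_published_parameter_count_bounds(self, cell, layers, units, expected):
        """The extremes of the hyperparameter grid reproduce the published
        [1.5k, 39k] range."""
        model = build_model(RecurrentConfig(cell, layers, units))
        n = count_parameters(model)
        assert n == expected
        assert format_parameter_count(n) in ("1.5k", "39k")

    def test_parameter_counts_closed_form_all_grid_configs(self):
        """Shape-summed counts match the closed form for every cell x depth
        x width x dilation grid point."""
        for cell, layers, units, dilated in itertools.product(
            GATES, (3, 5), (16, 32), (False, True)
        ):
            model = build_model(RecurrentConfig(cell, layers, units, dilated=dilated))
            assert count_parameters(model) == closed_form_count(cell, layers, units)

    def test_parameter_counts_with_static_integration(self):
        for cell, integ, sd in itertools.product(
            GATES, ("init", "cat", "both"), (6, 11)
        ):
            model = build_model(
                RecurrentConfig(cell, 3, 16, integration=integ, static_dim=sd)
            )
            assert count_parameters(model) == closed_form_count(
                cell, 3, 16, integ, sd
            )

    def test_count_invariant_under_forward(self):
        model = build_model(RecurrentConfig("gru", 3, 16))
        before = count_parameters(model)
        model.reset()
        model.forward(np.zeros((10, 7)))
        assert count_parameters(model) == before


class TestStaticIntegration:
    def test_none_integration_starts_from_zero_state(self):
        model = build_model(RecurrentConfig("lstm", 2, 8))
        model.reset()
        assert np.all(model.layers[0].h_buf == 0)
        assert np.all(model.layers[0].c_buf == 0)

    def test_zero_statics_with_zero_biases_give_zero_state(self):
        model = build_model(
            RecurrentConfig("rnn", 2, 8, integration="init", static_dim=6)
        )
        for layer in model.mlp_init_h.layers:
            layer.b.value[...] = 0.0
        h0 = init_hidden_from_statics(model, np.zeros(6))
        assert np.allclose(h0, 0.0)

    def test_distinct_statics_give_distinct_states(self):
        model = build_model(
            RecurrentConfig("rnn", 2, 8, integration="init", static_dim=6)
        )
        a = init_hidden_from_statics(model, np.ones(6))
        b = init_hidden_from_statics(model, -np.ones(6))
        assert not np.allclose(a, b)

    def test_lstm_has_distinct_cell_state_initializer(self):
        model = build_model(
            RecurrentConfig("lstm", 2, 8, integration="both", static_dim=6)
        )
        assert model.mlp_init_c is not None
        model.reset(np.ones(6))
        assert not np.allclose(model.layers[0].h_buf, model.layers[0].c_buf)

    def test_cat_head_widths(self):
        model = build_model(
            RecurrentConfig("rnn", 3, 32, integration="cat", static_dim=6)
        )
        # MLP_cat: 6 -> 12 -> 2
        assert model.mlp_cat.layers[0].W.value.shape == (6, 12)
        assert model.mlp_cat.layers[1].W.value.shape == (12, 2)
        # MLP_head: 34 -> 64 -> 32 -> 1
        assert model.head.layers[0].W.value.shape == (34, 64)
        assert model.head.layers[1].W.value.shape == (64, 32)
        assert model.head.layers[2].W.value.shape == (32, 1)

    def test_cat_head_input_width_eleven_statics(self):
        model = build_model(
            RecurrentConfig("rnn", 3, 16, integration="cat", static_dim=11)
        )
        assert model.head.layers[0].W.value.shape[0] == 18  # 16 + 2

    def test_cat_head_requires_cat_integration(self):
        model = build_model(RecurrentConfig("rnn", 2, 8))
        with pytest.raises(ValueError):
            cat_head(model, np.zeros(8), np.zeros(6))

    def test_init_requires_matching_dimension(self):
        model = build_model(
            RecurrentConfig("rnn", 2, 8, integration="init", static_dim=6)
        )
        with pytest.raises(ValueError):
            model.reset(np.zeros(11))

    def test_cat_model_reduces_to_plain_model_when_head_ignores_statics(self):
        """Construction: with MLP_head weights arranged as a ReLU identity
        (relu(x) - relu(-x) = x) on the recurrent channels and zeros on the
        two static channels, the cat model equals the none model."""
        rng = np.random.default_rng(0)
        u = 8
        base = build_model(RecurrentConfig("gru", 2, u, horizon=1), seed=1)
        cat = build_model(
            RecurrentConfig("gru", 2, u, integration="cat", static_dim=6, horizon=1),
            seed=1,
        )
        # same recurrent weights
        for lb, lc in zip(base.layers, cat.layers):
            for pb, pc in zip(lb.parameters(), lc.parameters()):
                pc.value[...] = pb.value
        # head: (u+2) -> 2u -> u -> 1 arranged to compute w.o + c while
        # ignoring the two static channels: layer 0 emits the pair
        # (w.o + c, -(w.o + c)), layer 1 recombines it (relu(x) - relu(-x)
        # = x) with a large positive offset M so its own ReLU passes, and
        # layer 2 removes M again.
        w = base.head.W.value[:, 0]
        c = base.head.b.value[0]
        M = 10.0 * (np.abs(w).sum() + abs(c) + 1.0)
        h = cat.head.layers
        h[0].W.value[...] = 0.0
        h[0].W.value[:u, 0] = w
        h[0].W.value[:u, 1] = -w
        h[0].b.value[...] = 0.0
        h[0].b.value[0] = c
        h[0].b.value[1] = -c
        h[1].W.value[...] = 0.0
        h[1].W.value[0, 0] = 1.0
        h[1].W.value[1, 0] = -1.0
        h[1].b.value[...] = 0.0
        h[1].b.value[0] = M
        h[2].W.value[...] = 0.0
        h[2].W.value[0, 0] = 1.0
        h[2].b.value[...] = -M
        X = rng.normal(size=(30, 7))
        s = rng.normal(size=6)
        base.reset()
        cat.reset(s)
        assert np.allclose(base.forward(X), cat.forward(X, s), atol=1e-12)


class TestForwardContract:
    def test_stateful_split_equals_single_pass(self):
        rng = np.random.default_rng(3)
        model = build_model(RecurrentConfig("lstm", 3, 8, dilated=True))
        X = rng.normal(size=(40, 7))
        model.reset()
        whole = model.forward(X)
        model.reset()
        parts = np.vstack([model.forward(X[:17]), model.forward(X[17:])])
        assert np.allclose(whole, parts, atol=1e-12)

    def test_reset_restores_identical_outputs(self):
        rng = np.random.default_rng(4)
        model = build_model(RecurrentConfig("gru", 2, 8))
        X = rng.normal(size=(15, 7))
        model.reset()
        a = model.forward(X)
        model.reset()
        b = model.forward(X)
        assert np.array_equal(a, b)

    def test_wrong_feature_count_rejected(self):
        model = build_model(RecurrentConfig("rnn", 2, 8))
        model.reset()
        with pytest.raises(ValueError):
            model.forward(np.zeros((10, 5)))

    def test_quantile_head_emits_sorted_levels(self):
        rng = np.random.default_rng(5)
        model = build_model(
            RecurrentConfig("rnn", 2, 8, quantile_head=True)
        )
        model.reset()
        out = model.predict(rng.normal(size=(20, 7)))
        assert out.shape == (20, 7)
        assert np.all(np.diff(out, axis=1) >= 0)

    def test_dilated_perturbation_arrives_at_lag_d(self):
        """Perturbing the pre-chunk state of a dilated layer first shows up
        d steps later, not at the next step."""
        from glucast._nn import RecurrentLayer

        for cell in ("rnn", "gru", "lstm"):
            for d in (2, 4):
                rng = np.random.default_rng(7)
                a = RecurrentLayer(cell, 4, 6, d, rng)
                rng = np.random.default_rng(7)
                b = RecurrentLayer(cell, 4, 6, d, rng)
                a.reset()
                b.reset()
                b.h_buf[-1] += 1.0  # state at step -1
                X = np.random.default_rng(8).normal(size=(10, 4))
                ha, hb = a.forward(X), b.forward(X)
                differs = np.nonzero(np.any(ha != hb, axis=1))[0]
                assert differs[0] == d - 1  # first effect at lag d from t=-1


class TestQuantileLoss:
    def test_point_examples(self):
        assert quantile_loss(np.array([1.0]), np.array([[0.0]]), (0.5,)) == 0.5
        assert quantile_loss(np.array([0.0]), np.array([[1.0]]), (0.9,)) == pytest.approx(0.1)

    def test_zero_for_perfect_prediction(self):
        y = np.array([3.0, 4.0])
        y_q = np.tile(y[:, None], (1, 7))
        assert quantile_loss(y, y_q, DEFAULT_QUANTILES) == 0.0

    def test_mismatched_levels_rejected(self):
        with pytest.raises(ValueError):
            quantile_loss(np.array([1.0]), np.array([[0.0, 1.0]]), (0.5,))

    def test_quantile_config_validation(self):
        with pytest.raises(ValueError):
            RecurrentConfig("rnn", 2, 8, quantile_head=True, quantiles=(0.1, 0.9))
        with pytest.raises(ValueError):
            RecurrentConfig("rnn", 2, 8, quantile_head=True, quantiles=(0.5, 0.2))

    def test_empirical_minimizer_is_the_quantile(self):
        """Minimising the pinball loss over a large sample recovers the
        distribution quantile."""
        from scipy import optimize, stats

        rng = np.random.default_rng(11)
        sample = rng.normal(size=20_000)
        for q in (0.1, 0.5, 0.9):
            res = optimize.minimize_scalar(
                lambda c: quantile_loss(sample, np.full((len(sample), 1), c), (q,)),
                bounds=(-4, 4),
                method="bounded",
            )
            assert abs(res.x - stats.norm.ppf(q)) < 0.05
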