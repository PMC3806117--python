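import numpy as np
import pytest

from srs_chaos.anfis import (
    AnfisConfig,
    _premise_gradient,
    _solve_consequents,
    anfis_predict,
    decode_codes,
    train_anfis,
)


@pytest.fixture(scope="module")
def cluster_data():
    """Feature-space-like clusters with class labels."""
    rng = np.random.default_rng(4)
    n = 300
    X = np.vstack(
        [
            rng.normal([0.05, 4.2], [0.01, 0.35], (n, 2)),
            rng.normal([0.08, 2.8], [0.012, 0.6], (n, 2)),
            rng.normal([0.12, 0.15], [0.006, 0.3], (n, 2)),
        ]
    )
    y = np.array(["snore"] * n + ["breathing"] * n + ["silence"] * n)
    return X, y


class TestHybridLearning:
    def test_realizable_model_exact_after_lse(self):
        # targets produced by a Sugeno system with the same grid premises
        # are fit exactly by the consequent least-squares pass alone
        rng = np.random.default_rng(0)
        X = rng.uniform(0.0, 1.0, (200, 2))
        scaffold = train_anfis((X, np.zeros(200)), config=AnfisConfig(epochs=0))
        scaffold.consequents = rng.normal(size=(scaffold.n_rules, 3))
        targets = scaffold.crisp_output(X)
        fitted = train_anfis((X, targets), config=AnfisConfig(epochs=0))
        assert fitted.epoch_rmse[-1] < 1e-6

    def test_zero_epochs_contract(self, cluster_data):
        model = train_anfis(cluster_data, config=AnfisConfig(epochs=0))
        assert len(model.epoch_rmse) == 1

    def test_rmse_non_increasing(self, cluster_data):
        model = train_anfis(cluster_data, config=AnfisConfig(epochs=10))
        diffs = np.diff(model.epoch_rmse)
        assert (diffs <= 1e-8).all()

    def test_zero_learning_rate_freezes_premises(self, cluster_data):
        cfg = AnfisConfig(epochs=5, learning_rate=0.0)
        model = train_anfis(cluster_data, config=cfg)
        frozen = train_anfis(cluster_data, config=AnfisConfig(epochs=0))
        assert np.array_equal(model.premises, frozen.premises)

    def test_training_order_invariance(self, cluster_data):
        X, y = cluster_data
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(y))
        m1 = train_anfis((X, y))
        m2 = train_anfis((X[perm], y[perm]))
        grid = np.column_stack(
            [np.linspace(0.03, 0.14, 50), np.linspace(0.0, 4.5, 50)]
        )
        assert np.allclose(m1.crisp_output(grid), m2.crisp_output(grid), atol=1e-6)

    def test_degenerate_input_rejected(self):
        X = np.column_stack([np.ones(50), np.linspace(0, 1, 50)])
        with pytest.raises(ValueError, match="constant"):
            train_anfis((X, np.zeros(50)))

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-1, 1, (60, 2))
        t = np.sin(X[:, 0]) + X[:, 1] ** 2
        model = train_anfis((X, t), config=AnfisConfig(epochs=0))
        grad = _premise_gradient(model, X, t)

        def sse():
            return float(np.sum((model.crisp_output(X) - t) ** 2))

        eps = 1e-6
        for d, j, k in [(0, 0, 0), (0, 1, 1), (1, 2, 2), (1, 0, 0)]:
            orig = model.premises[d, j, k]
            model.premises[d, j, k] = orig + eps
            up = sse()
            model.premises[d, j, k] = orig - eps
            down = sse()
            model.premises[d, j, k] = orig
            fd = (up - down) / (2 * eps)
            # gradient defined up to the factor 2 absorbed in the step
            assert np.isclose(2 * grad[d, j, k], fd, rtol=1e-4, atol=1e-6)


class TestInference:
    def test_normalized_firing_sums_to_one(self, cluster_data):
        X, y = cluster_data
        model = train_anfis((X, y))
        wbar = model.firing_strengths(X)
        assert np.allclose(wbar.sum(axis=1), 1.0, atol=1e-12)

    def test_rule_count_is_grid_squared(self, cluster_data):
        model = train_anfis(cluster_data, config=AnfisConfig(mfs_per_input=3))
        assert model.n_rules == 9
        assert model.consequents.shape == (9, 3)

    @pytest.mark.parametrize(
        "crisp,code",
        [(2.4, 2), (7.0, 3), (-1.0, 1), (1.5, 1), (2.5, 2), (1.51, 2)],
    )
    def test_code_decoding(self, crisp, code):
        assert decode_codes(np.array([crisp]))[0] == code

    def test_cluster_accuracy(self, cluster_data):
        X, y = cluster_data
        model = train_anfis((X, y))
        assert (model.predict(X) == y).mean() > 0.95

    def test_anfis_predict_wrapper(self, cluster_data):
        X, y = cluster_data
        model = train_anfis((X, y))
        out = anfis_predict(model, X[0])
        assert out["label"] == y[0]
        assert np.isfinite(out["crisp_output"])

    def test_non_finite_rejected(self, cluster_data):
        model = train_anfis(cluster_data, config=AnfisConfig(epochs=0))
        with pytest.raises(ValueError):
            model.crisp_output(np.array([[np.inf, 0.0]]))


def test_config_validation():
    with pytest.raises(ValueError):
        AnfisConfig(epochs=-1)
    with pytest.raises(ValueError):
        AnfisConfig(mfs_per_input=1)
    with pytest.raises(ValueError):
        AnfisConfig(learning_rate=-0.1)
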