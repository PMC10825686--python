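import copy

import numpy as np
import pytest

from lvqanfis import anfis
from lvqanfis.anfis import (ANFISConfig, ANFISModel, DegenerateCoverageError,
                            MembershipFunction, RuleBase, fit_hybrid, forward,
                            init_grid, lse_consequents, mf_eval,
                            premise_gradients, premise_step)


class TestMembershipFunctions:
    def test_gaussian_center_and_formula(self):
        mf = MembershipFunction("gaussian", [5.0, 2.0])
        assert mf_eval(mf, 5.0) == 1.0
        assert mf_eval(mf, 7.0) == pytest.approx(np.exp(-0.5))

    def test_triangular_foot_and_peak(self):
        mf = MembershipFunction("triangular", [0.0, 1.0, 2.0])
        assert mf_eval(mf, 0.0) == 0.0
        assert mf_eval(mf, 1.0) == 1.0
        assert mf_eval(mf, 3.0) == 0.0  # exactly zero beyond the feet

    def test_gbell_half_crossing(self):
        mf = MembershipFunction("gbell", [2.0, 1.0, 0.0])
        assert mf_eval(mf, 2.0) == pytest.approx(0.5)
        assert mf_eval(mf, 0.0) == 1.0

    def test_trapezoidal_plateau(self):
        mf = MembershipFunction("trapezoidal", [0.0, 1.0, 2.0, 3.0])
        assert mf_eval(mf, 1.5) == 1.0
        assert mf_eval(mf, 0.5) == pytest.approx(0.5)

    def test_shoulders_clamp_to_one(self):
        mf = MembershipFunction("triangular", [0.0, 1.0, 2.0], shoulder="left")
        assert mf_eval(mf, -100.0) == 1.0
        mf = MembershipFunction("trapezoidal", [0, 1, 2, 3], shoulder="right")
        assert mf_eval(mf, 100.0) == 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MembershipFunction("triangular", [2.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            MembershipFunction("gaussian", [0.0, -1.0])

    @pytest.mark.parametrize("family", anfis.FAMILIES)
    def test_unit_interval_over_triple_range(self, family):
        """Every family evaluates within [0,1] on a dense grid spanning
        three times the data range used to build it."""
        X = np.random.default_rng(1).uniform(0, 10, size=(50, 1))
        rb = init_grid(X, ANFISConfig(mf_family=family))
        grid = np.linspace(-10, 20, 4001)
        for mf in rb.input_mfs[0]:
            vals = mf(grid)
            assert np.all(vals >= 0.0) and np.all(vals <= 1.0)


class TestRuleGeneration:
    def test_two_inputs_three_mfs_grid(self):
        X = np.random.default_rng(0).uniform(size=(30, 2))
        rb = init_grid(X, ANFISConfig())
        assert rb.n_rules == 9

    def test_combinatorial_explosion_refused(self):
        X = np.random.default_rng(0).uniform(size=(30, 16))
        with pytest.raises(ValueError, match="scatter"):
            init_grid(X, ANFISConfig())

    def test_one_input_centers_at_min_mid_max(self):
        X = np.array([[0.0], [5.0], [10.0]])
        rb = init_grid(X, ANFISConfig(mf_family="gaussian"))
        assert rb.n_rules == 3
        centers = [mf.params[0] for mf in rb.input_mfs[0]]
        np.testing.assert_allclose(centers, [0.0, 5.0, 10.0])

    def test_scatter_mode_bounded_rule_count(self):
        X = np.random.default_rng(2).uniform(size=(100, 16))
        rb = init_grid(X, ANFISConfig(rule_generation="scatter", scatter_rules=5))
        assert 1 <= rb.n_rules <= 5
        assert len(rb.input_mfs) == 16

    def test_duplicate_rules_rejected(self):
        mfs = [[MembershipFunction("gaussian", [0.0, 1.0])]]
        with pytest.raises(ValueError, match="duplicate"):
            RuleBase(mfs, [(0,), (0,)])


def _single_rule_model(slope=3.0, intercept=1.0):
    mfs = [[MembershipFunction("gaussian", [0.0, 5.0])]]
    rb = RuleBase(mfs, [(0,)])
    return ANFISModel(rb, np.array([[slope, intercept]]), ANFISConfig())


class TestForward:
    def test_single_rule_normalization_of_one(self):
        m = _single_rule_model()
        w, wn, out = forward(m, np.array([2.0]))
        np.testing.assert_allclose(wn, [1.0])
        assert out == pytest.approx(3 * 2 + 1)

    def test_equal_firing_symmetry_average(self):
        mf = MembershipFunction("gaussian", [0.0, 1.0])
        rb = RuleBase([[mf, copy.deepcopy(mf)]], [(0,), (1,)])
        m = ANFISModel(rb, np.array([[0.0, 2.0], [0.0, 4.0]]), ANFISConfig())
        _, wn, out = forward(m, np.array([0.7]))
        np.testing.assert_allclose(wn, [0.5, 0.5])
        assert out == pytest.approx(3.0)

    def test_matches_layer_by_layer_oracle(self):
        """Independent five-layer reimplementation on a seeded 2-input model."""
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 10, size=(40, 2))
        cfg = ANFISConfig(seed=3)
        rb = init_grid(X, cfg)
        model = ANFISModel(rb, rng.normal(size=(9, 3)), cfg)
        x = rng.uniform(0, 10, size=2)
        # oracle: explicit layers
        w = np.array([np.prod([rb.input_mfs[i][k](x[i])
                               for i, k in enumerate(rule)])
                      for rule in rb.rules])                       # layers 1-2
        wn = w / w.sum()                                           # layer 3
        rule_out = model.consequents @ np.append(x, 1.0)           # layer 4
        expected = float(np.sum(wn * rule_out))                    # layer 5
        W, WN, out = forward(model, x)
        np.testing.assert_allclose(W, w, rtol=1e-12)
        np.testing.assert_allclose(WN, wn, rtol=1e-12)
        assert out == pytest.approx(expected, rel=1e-12)

    def test_normalized_strengths_sum_to_one(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-5, 5, size=(60, 2))
        cfg = ANFISConfig(mf_family="gbell")
        rb = init_grid(X, cfg)
        m = ANFISModel(rb, rng.normal(size=(rb.n_rules, 3)), cfg)
        for x in X[:20]:
            _, wn, _ = forward(m, x)
            assert abs(wn.sum() - 1.0) < 1e-12

    def test_degenerate_coverage_raises_outside_support(self):
        mfs = [[MembershipFunction("triangular", [0.0, 1.0, 2.0])]]
        m = ANFISModel(RuleBase(mfs, [(0,)]), np.zeros((1, 2)), ANFISConfig())
        with pytest.raises(DegenerateCoverageError):
            forward(m, np.array([50.0]))


class TestLSE:
    def test_exact_linear_fit_single_rule(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-3, 3, size=(50, 1))
        y = 3.0 * X[:, 0] + 1.0
        m = _single_rule_model(0.0, 0.0)
        C = lse_consequents(m, X, y, ridge=0.0)
        np.testing.assert_allclose(C, [[3.0, 1.0]], atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        X = rng.uniform(0, 10, size=(60, 2))
        y = np.sin(X[:, 0]) + 0.2 * X[:, 1] + rng.normal(0, 0.1, 60)
        cfg = ANFISConfig()
        rb = init_grid(X, cfg)
        m = ANFISModel(rb, np.zeros((9, 3)), cfg)
        ridge = 1e-8
        C = lse_consequents(m, X, y, ridge=ridge)
        # oracle: explicit Gram-matrix solve
        W = anfis.firing_strengths(rb, X)
        Wn = W / W.sum(axis=1, keepdims=True)
        Xa = np.column_stack([X, np.ones(60)])
        A = (Wn[:, :, None] * Xa[:, None, :]).reshape(60, 27)
        beta = np.linalg.solve(A.T @ A + ridge * np.eye(27), A.T @ y)
        np.testing.assert_allclose(C.ravel(), beta, rtol=1e-8, atol=1e-10)

    def test_optimality_against_perturbation(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 10, size=(50, 1))
        y = rng.normal(size=50)
        cfg = ANFISConfig()
        rb = init_grid(X, cfg)
        m = ANFISModel(rb, np.zeros((3, 2)), cfg)
        m.consequents = lse_consequents(m, X, y, ridge=0.0)
        best = float(np.sum((anfis.predict(m, X) - y) ** 2))
        for _ in range(5):
            m2 = ANFISModel(rb, m.consequents + rng.normal(0, 0.1, (3, 2)), cfg)
            assert float(np.sum((anfis.predict(m2, X) - y) ** 2)) >= best


class TestPremiseTraining:
    def _small_model(self, family="gaussian", seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 10, size=(40, 2))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
        cfg = ANFISConfig(mf_family=family)
        rb = init_grid(X, cfg)
        m = ANFISModel(rb, np.zeros((rb.n_rules, 3)), cfg)
        m.consequents = lse_consequents(m, X, y)
        return m, X, y

    def test_zero_step_is_identity(self):
        m, X, y = self._small_model()
        m2 = premise_step(m, X, y, 0.0)
        assert m2 is m

    def test_small_step_descends(self):
        m, X, y = self._small_model()
        sse0 = float(np.sum((anfis.predict(m, X) - y) ** 2))
        step = 1e-3
        for _ in range(12):
            m2 = premise_step(m, X, y, step)
            sse1 = float(np.sum((anfis.predict(m2, X) - y) ** 2))
            if sse1 <= sse0:
                break
            step /= 2
        assert sse1 <= sse0

    @pytest.mark.parametrize("family", ["gaussian", "gbell"])
    def test_analytic_gradient_matches_finite_differences(self, family):
        m, X, y = self._small_model(family)
        grads = premise_gradients(m, X, y)

        def sse_of(model):
            return float(np.sum((anfis.predict(model, X) - y) ** 2))

        for i in range(2):
            for k in range(3):
                params = m.rulebase.input_mfs[i][k].params
                for q in range(len(params)):
                    h = 1e-6 * max(1.0, abs(params[q]))
                    mp, mm = copy.deepcopy(m), copy.deepcopy(m)
                    mp.rulebase.input_mfs[i][k].params[q] += h
                    mm.rulebase.input_mfs[i][k].params[q] -= h
                    fd = (sse_of(mp) - sse_of(mm)) / (2 * h)
                    if abs(fd) > 1e-6:
                        assert grads[i][k][q] == pytest.approx(fd, rel=1e-5)

    def test_constraint_repair_preserves_ordering(self):
        m, X, y = self._small_model("triangular")
        m2 = premise_step(m, X, y, 0.5)  # deliberately large step
        for mfs in m2.rulebase.input_mfs:
            for mf in mfs:
                a, b, c = mf.params
                assert a <= b <= c


class TestFitHybrid:
    def test_noiseless_sugeno_recovery(self, sugeno_1d):
        gen, X, y, y_clean = sugeno_1d
        m = fit_hybrid(X, y, ANFISConfig(epochs=10, seed=2))
        out_range = y_clean.max() - y_clean.min()
        assert m.training_log[-1] <= 0.01 * out_range

    def test_training_log_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 10, size=(120, 1))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.3, 120)
        m = fit_hybrid(X, y, ANFISConfig(epochs=15, seed=4))
        log = np.array(m.training_log)
        assert np.all(np.diff(log) <= 1e-9)
        assert log[-1] <= log[0]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 5, size=(60, 1))
        y = X[:, 0] ** 2 + rng.normal(0, 0.1, 60)
        cfg = ANFISConfig(epochs=5, seed=9)
        m1, m2 = fit_hybrid(X, y, cfg), fit_hybrid(X, y, cfg)
        np.testing.assert_array_equal(m1.consequents, m2.consequents)

    def test_noisy_heldout_within_noise_band(self):
        sigma = 1.0
        gen = anfis.ANFISConfig(seed=50)
        from lvqanfis import synthetic
        system = synthetic.make_sugeno_system([(0, 10)], gen, seed=50)
        X, y, _ = synthetic.sample_sugeno(system, [(0, 10)], 700, sigma, seed=8)
        m = fit_hybrid(X[:500], y[:500], ANFISConfig(epochs=20, seed=1))
        heldout = float(np.sqrt(np.mean((anfis.predict(m, X[500:]) - y[500:]) ** 2)))
        assert heldout <= 1.2 * sigma

    def test_few_rows_warns(self):
        X = np.random.default_rng(1).uniform(0, 1, size=(5, 2))
        y = X.sum(axis=1)
        with pytest.warns(UserWarning, match="rows"):
            fit_hybrid(X, y, ANFISConfig(epochs=1, seed=0))


def test_serialization_round_trip_exact(tmp_path, sugeno_1d):
    _, X, y, _ = sugeno_1d
    m = fit_hybrid(X, y, ANFISConfig(epochs=3, seed=6))
    path = tmp_path / "anfis.json"
    anfis.save_model(m, path)
    again = anfis.load_model(path)
    np.testing.assert_array_equal(m.consequents, again.consequents)
    xq = np.array([[4.2]])
    assert anfis.predict(m, xq)[0] == anfis.predict(again, xq)[0]
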