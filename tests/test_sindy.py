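"""Sparse regression: libraries, STLSQ vs brute-force oracle, constrained SR3."""

import itertools
import json

import numpy as np
import pytest

from gesturedyn import oscillators as osc
from gesturedyn import preprocess as pp
from gesturedyn import sindy
from gesturedyn.sindy import (
    DiscoveryOptions,
    OptimizerConfig,
    SparseModel,
    build_polynomial_library,
    second_order_constraints,
    sr3_constrained,
    stlsq,
)


def best_subset_least_squares(theta, y, tol=1e-8):
    """Exhaustive best-subset oracle: the sparsest mask achieving the
    minimal residual sum of squares (within tol), with its LS coefficients."""
    n, p = theta.shape
    best_sse = np.inf
    fits = {}
    for r in range(p + 1):
        for mask in itertools.combinations(range(p), r):
            idx = list(mask)
            if idx:
                coef, *_ = np.linalg.lstsq(theta[:, idx], y, rcond=None)
                sse = float(np.sum((y - theta[:, idx] @ coef) ** 2))
            else:
                coef, sse = np.empty(0), float(y @ y)
            fits[mask] = (coef, sse)
            best_sse = min(best_sse, sse)
    for r in range(p + 1):  # sparsest first
        for mask in itertools.combinations(range(p), r):
            coef, sse = fits[mask]
            if sse <= best_sse + tol:
                full = np.zeros(p)
                full[list(mask)] = coef
                return full
    raise AssertionError("unreachable")


class TestLibrary:
    def test_single_state_cubic(self):
        lib = build_polynomial_library(["x"], 3)
        assert lib.term_names == ["1", "x", "x^2", "x^3"]

    def test_two_state_linear(self):
        lib = build_polynomial_library(["x", "v"], 1)
        assert lib.term_names == ["1", "x", "v"]

    def test_evaluation_row(self):
        lib = build_polynomial_library(["x"], 2)
        row = lib.transform(np.array([[2.0]]))
        assert np.allclose(row, [[1.0, 2.0, 4.0]])

    def test_two_state_quadratic_order(self):
        lib = build_polynomial_library(["x", "v"], 2)
        assert lib.term_names == ["1", "x", "v", "x^2", "x v", "v^2"]

    def test_empty_state_list_rejected(self):
        with pytest.raises(ValueError):
            build_polynomial_library([], 2)


class TestSTLSQ:
    def test_recovers_linear_decay(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-2, 2, 100)
        lib = build_polynomial_library(["x"], 2)
        theta = lib.transform(x[:, None])
        xdot = -3.0 * x
        coef, _, converged = stlsq(theta, xdot, threshold=0.1, alpha=0.0)
        assert converged
        assert coef[0] == 0.0 and coef[2] == 0.0
        assert coef[1] == pytest.approx(-3.0, abs=1e-8)

    def test_huge_threshold_zeroes_everything(self):
        rng = np.random.default_rng(1)
        theta = rng.standard_normal((50, 4))
        y = theta @ np.array([0.5, 0.0, -0.2, 0.1])
        coef, _, _ = stlsq(theta, y, threshold=1e9, alpha=0.0)
        assert np.all(coef == 0.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_best_subset_oracle(self, seed):
        # noiseless sparse truth: STLSQ support and coefficients equal the
        # exhaustive best-subset least-squares solution
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 9))
        n = int(rng.integers(40, 201))
        theta = rng.standard_normal((n, p))
        n_active = int(rng.integers(1, 4))
        support = rng.choice(p, size=n_active, replace=False)
        truth = np.zeros(p)
        truth[support] = rng.uniform(0.5, 3.0, n_active) \
            * rng.choice([-1.0, 1.0], n_active)
        y = theta @ truth
        coef, _, _ = stlsq(theta, y, threshold=0.05, alpha=0.0)
        oracle = best_subset_least_squares(theta, y)
        assert np.allclose(coef, oracle, atol=1e-6)
        assert np.array_equal(coef != 0, oracle != 0)

    def test_rank_deficiency_with_zero_alpha_raises(self):
        theta = np.ones((20, 3))  # identical columns
        y = np.ones(20)
        with pytest.raises(np.linalg.LinAlgError):
            stlsq(theta, y, threshold=0.0, alpha=0.0)


class TestSR3:
    def _second_order_data(self, k=2000.0, b=None, kT=400.0, n=250,
                           dt=1e-3, x0=1.0):
        b = 2.0 * np.sqrt(k) if b is None else b
        T = kT / k
        params = osc.GestureParams(k=k, b=b, T=T, x0=x0, v0=0.0)
        traj = osc.simulate(params, duration=(n - 1) * dt, dt=dt)
        X = np.column_stack([traj.x, traj.v])
        targets = np.column_stack([traj.v, traj.a])
        return X, targets

    def test_constraint_satisfied_exactly(self):
        lib = build_polynomial_library(["x", "v"], 2)
        X, targets = self._second_order_data()
        theta = lib.transform(X)
        C, dvec = second_order_constraints(lib)
        coef, _, _ = sr3_constrained(theta, targets, C, dvec, threshold=0.1)
        assert np.max(np.abs(C @ coef.ravel(order="F") - dvec)) < 1e-10
        # first equation is exactly y = 1.00 * xdot
        expected = np.zeros(lib.n_terms)
        expected[lib.term_index("v")] = 1.0
        assert np.array_equal(coef[:, 0], expected)

    def test_recovers_closed_loop_coefficients(self):
        # x'' = -89.44 x' - 2000 x + 400 with exact state derivatives
        lib = build_polynomial_library(["x", "v"], 1)
        X, targets = self._second_order_data()
        theta = lib.transform(X)
        C, dvec = second_order_constraints(lib)
        coef, _, _ = sr3_constrained(theta, targets, C, dvec, threshold=0.1)
        b = 2.0 * np.sqrt(2000.0)
        assert coef[lib.term_index("1"), 1] == pytest.approx(400.0, rel=1e-3)
        assert coef[lib.term_index("x"), 1] == pytest.approx(-2000.0, rel=1e-3)
        assert coef[lib.term_index("v"), 1] == pytest.approx(-b, rel=1e-3)

    def test_zero_threshold_matches_constrained_least_squares(self):
        lib = build_polynomial_library(["x", "v"], 2)
        X, targets = self._second_order_data()
        theta = lib.transform(X)
        C, dvec = second_order_constraints(lib)
        coef, _, _ = sr3_constrained(theta, targets, C, dvec, threshold=0.0)
        # direct KKT solve of the equality-constrained least squares
        p, k = theta.shape[1], targets.shape[1]
        H = np.kron(np.eye(k), theta.T @ theta)
        g = (theta.T @ targets).ravel(order="F")
        m = C.shape[0]
        KKT = np.block([[H, C.T], [C, np.zeros((m, m))]])
        sol = np.linalg.lstsq(KKT, np.concatenate([g, dvec]), rcond=None)[0]
        ref = sol[:p * k].reshape((p, k), order="F")
        # the raw-space reference KKT is ill-conditioned; compare fits
        scale = np.abs(targets).max()
        assert np.allclose(theta @ coef, theta @ ref, atol=1e-6 * scale)

    def test_infeasible_constraints_rejected(self):
        lib = build_polynomial_library(["x", "v"], 1)
        X, targets = self._second_order_data(n=50)
        theta = lib.transform(X)
        p = lib.n_terms
        C = np.zeros((2, 2 * p))
        C[0, 0] = 1.0
        C[1, 0] = 1.0
        dvec = np.array([0.0, 1.0])  # contradictory: coef both 0 and 1
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            coef, _, _ = sr3_constrained(theta, targets, C, dvec,
                                         threshold=1e9)
            resid = np.max(np.abs(C @ coef.ravel(order="F") - dvec))
            if resid > 1e-6:
                raise ValueError("constraints not satisfied")


class TestDiscovery:
    def test_first_order_cubic_self_consistency(self):
        # integrate xdot = a - b x + c x^2 - d x^3 and rediscover it
        from scipy.integrate import solve_ivp

        a, b, c, d = 2.0, 3.0, 0.8, 0.9
        sr = 1000.0
        t = np.arange(0, 2.0, 1 / sr)
        sol = solve_ivp(lambda _, y: a - b * y[0] + c * y[0]**2 - d * y[0]**3,
                        (0, t[-1]), [0.0], t_eval=t, rtol=1e-10, atol=1e-12)
        x = sol.y[0]
        model = sindy.discover_first_order(
            x, sr, config=OptimizerConfig(threshold=0.01, alpha=0.0))
        coef = model.coef[:, 0]
        names = model.library.term_names
        assert coef[names.index("1")] == pytest.approx(a, rel=0.01)
        assert coef[names.index("x")] == pytest.approx(-b, rel=0.01)
        assert coef[names.index("x^2")] == pytest.approx(c, rel=0.01)
        assert coef[names.index("x^3")] == pytest.approx(-d, rel=0.01)

    def test_constant_position_gives_null_model(self):
        model = sindy.discover_first_order(np.full(100, 2.0), 160.0)
        assert np.all(model.coef == 0.0)

    def test_replication_within_tenth_percent(self, replication_trajectory):
        traj = replication_trajectory
        model = sindy.discover_second_order(traj.x, None, traj.sample_rate)
        est = sindy.extract_oscillator_params(model, x0=1.0)
        assert est.k == pytest.approx(2000.0, rel=1e-3)
        assert est.b == pytest.approx(2.0 * np.sqrt(2000.0), rel=1e-3)
        assert est.k * est.Tv == pytest.approx(400.0, rel=1e-3)

    def test_undamped_token_reports_zero_damping_within_threshold(self):
        params = osc.GestureParams(k=900.0, b=0.0, T=0.5, x0=1.0, v0=0.0)
        traj = osc.simulate(params, duration=np.pi / 30.0, dt=1e-3)
        model = sindy.discover_second_order(traj.x, None, traj.sample_rate)
        b_hat = -model.coef[model.library.term_index("v"), 1]
        assert abs(b_hat) < 0.5  # orders below k and kT

    def test_cubic_stiffness_term_recovered(self):
        k = 2000.0
        d = 0.95 * k
        params = osc.GestureParams(k=k, b=2 * np.sqrt(k), T=0.0, d=d, x0=1.0)
        traj = osc.simulate(params, duration=0.25, dt=1e-3)
        # custom library with linear terms and a cubic position term;
        # the simulated force is d (x - T)^3 with T = 0, i.e. +d x^3
        lib = sindy.FeatureLibrary(
            ["x", "v"], [(0, 0), (1, 0), (0, 1), (3, 0)])
        model = sindy.discover_second_order(
            traj.x, None, traj.sample_rate, library=lib)
        c3 = model.coef[lib.term_names.index("x^3"), 1]
        assert c3 == pytest.approx(d, rel=0.10)
        assert np.sign(c3) == 1.0


class TestGridSearch:
    def test_truth_survives_only_smallest_threshold(self):
        # a small coefficient is killed by larger thresholds, degrading fit
        rng = np.random.default_rng(5)
        sr = 1000.0
        from scipy.integrate import solve_ivp
        t = np.arange(0, 3.0, 1 / sr)
        sol = solve_ivp(lambda _, y: 1.0 - 0.9 * y[0] - 0.08 * y[0]**2,
                        (0, t[-1]), [3.0], t_eval=t, rtol=1e-10, atol=1e-12)
        x = sol.y[0]
        lib = build_polynomial_library(["x"], 2)
        model, thr, score = sindy.threshold_grid_search(
            x, sr, library=lib, grid=(0.001, 0.5, 5.0), order="first",
            config=OptimizerConfig(alpha=0.0),
            options=DiscoveryOptions(upsample=1))
        assert thr == 0.001
        assert score > 0.99

    def test_tie_break_keeps_first_threshold(self):
        params = osc.GestureParams(k=2000.0, b=2 * np.sqrt(2000.0), T=0.2,
                                   x0=1.0)
        traj = osc.simulate(params, duration=0.25, dt=1e-3)
        model, thr, _ = sindy.threshold_grid_search(
            traj.x, traj.sample_rate, grid=(0.001, 0.01, 0.1))
        assert thr == 0.001  # identical masks at every threshold


class TestExtraction:
    def test_reference_coefficients(self):
        lib = build_polynomial_library(["x", "v"], 1)
        coef = np.zeros((3, 2))
        coef[lib.term_index("v"), 0] = 1.0
        coef[lib.term_index("1"), 1] = 400.0
        coef[lib.term_index("x"), 1] = -2000.0
        coef[lib.term_index("v"), 1] = -89.44
        model = SparseModel(lib, coef, order="second")
        est = sindy.extract_oscillator_params(model)
        assert est.k == 2000.0
        assert est.b == 89.44
        assert est.Tv == pytest.approx(0.2)

    def test_zero_constant_zero_start(self):
        lib = build_polynomial_library(["x", "v"], 1)
        coef = np.zeros((3, 2))
        coef[lib.term_index("v"), 0] = 1.0
        coef[lib.term_index("x"), 1] = -500.0
        model = SparseModel(lib, coef, order="second")
        est = sindy.extract_oscillator_params(model, x0=0.0)
        assert est.Tv == 0.0 and est.T == 0.0

    def test_nonoscillatory_model_rejected(self):
        lib = build_polynomial_library(["x", "v"], 1)
        coef = np.zeros((3, 2))
        coef[lib.term_index("x"), 1] = +10.0  # positive feedback, k < 0
        model = SparseModel(lib, coef, order="second")
        with pytest.raises(ValueError):
            sindy.extract_oscillator_params(model)

    def test_virtual_target_round_trip(self):
        est = sindy.extract_oscillator_params(
            _make_linear_model(k=800.0, b=3.0, Tv=7.0), x0=4.0)
        assert osc.virtual_from_target(est.T, 4.0) == pytest.approx(est.Tv)


def _make_linear_model(k, b, Tv):
    lib = build_polynomial_library(["x", "v"], 1)
    coef = np.zeros((3, 2))
    coef[lib.term_index("v"), 0] = 1.0
    coef[lib.term_index("1"), 1] = k * Tv
    coef[lib.term_index("x"), 1] = -k
    coef[lib.term_index("v"), 1] = -b
    return SparseModel(lib, coef, order="second")


class TestRefinement:
    def test_exact_on_clean_token(self):
        k, Tv = 900.0, 10.0
        params = osc.GestureParams(k=k, b=0.0, T=Tv, x0=8.0, v0=0.0)
        sr = 160.0
        traj = osc.simulate(params, duration=np.pi / np.sqrt(k), dt=1 / sr)
        k2, b2, Tv2 = sindy.refine_linear_parameters(
            traj.x, sr, k0=k * 1.1, Tv0=Tv + 0.5)
        assert k2 == pytest.approx(k, rel=1e-6)
        assert Tv2 == pytest.approx(Tv, rel=1e-6)
        assert b2 == 0.0

    def test_damped_variant_selected_when_real(self):
        k = 900.0
        b = 0.6 * 2 * np.sqrt(k)  # substantial subcritical damping
        params = osc.GestureParams(k=k, b=b, T=10.0, x0=8.0, v0=0.0)
        sr = 160.0
        om_d = np.sqrt(k - b * b / 4)
        traj = osc.simulate(params, duration=np.pi / om_d, dt=1 / sr)
        k2, b2, _ = sindy.refine_linear_parameters(
            traj.x, sr, k0=k, Tv0=10.0, b0=b, fit_damping=True)
        assert b2 == pytest.approx(b, rel=0.01)
        assert k2 == pytest.approx(k, rel=0.01)


def test_sparse_model_json_round_trip():
    model = _make_linear_model(700.0, 2.5, 9.0)
    model.sample_rate = 160.0
    back = SparseModel.from_json(model.to_json())
    assert back.library == model.library
    assert np.array_equal(back.coef, model.coef)
    assert back.order == "second"
    assert back.sample_rate == 160.0


def test_equation_strings_readable():
    model = _make_linear_model(2000.0, 89.44, 0.2)
    eqs = model.equation_strings(2)
    assert eqs[0] == "+1.00 v"
    assert "x" in eqs[1] and "-2000.00" in eqs[1]
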