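"""Spline-engine tests: hinge algebra, constrained selection, pruning, cubic mode."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splinepriors.mars import (BasisFunction, FitConstraints, HingeTerm,
                               MarsModel, admissible_knots, backward_prune,
                               fit_mars, forward_pass, gcv, hinge_eval,
                               r_squared, select_penalty_cv, to_cubic)


@pytest.mark.parametrize("x,t,d,expected", [
    (5.0, 3.0, "+", 2.0),
    (2.0, 3.0, "+", 0.0),
    (3.0, 3.0, "+", 0.0),
    (3.0, 3.0, "-", 0.0),
    (2.0, 3.0, "-", 1.0),
    (5.0, 3.0, -1, 0.0),
])
def test_hinge_eval(x, t, d, expected):
    assert hinge_eval(x, t, d) == expected


def test_hinge_eval_bad_direction():
    with pytest.raises(ValueError):
        hinge_eval(1.0, 0.0, "up")


class TestAdmissibleKnots:
    def test_edge_constraint_n25(self):
        # 25 sorted observations, 10 required on each side of a knot:
        # only sorted positions 11..15 (1-based) qualify
        x = np.arange(25, dtype=float)
        cand = admissible_knots(x, [], min_between=20, min_edge=10)
        assert list(cand) == [10.0, 11.0, 12.0, 13.0, 14.0]

    def test_between_constraint_blocks_second_knot(self):
        # with one knot placed, 20 subjects strictly between is impossible
        # for n=25, so no further knot is admissible
        x = np.arange(25, dtype=float)
        cand = admissible_knots(x, [12.0], min_between=20, min_edge=10)
        assert cand.size == 0

    def test_ties_count_with_multiplicity(self):
        x = np.array([-1.0] * 4 + [0.0] * 4 + [1.0] * 5 + [2.0] * 4 + [3.0] * 4)
        cand = admissible_knots(x, [0.0], min_between=5, min_edge=3)
        # the five 1.0 ties all count as lying strictly between 0 and 2,
        # so 2.0 is admissible; nothing lies strictly between 0 and 1
        assert 2.0 in cand and 1.0 not in cand


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.floats(-10, 10, allow_nan=False, allow_infinity=False),
                min_size=8, max_size=40),
       st.integers(1, 4), st.integers(1, 5))
def test_admissible_knots_respect_counts(values, edge, between):
    """Every admissible knot satisfies the edge and between-knot subject
    counts by direct enumeration, for arbitrary (tied) predictor data."""
    x = np.asarray(values, dtype=float)
    s = np.sort(x)
    cand = admissible_knots(x, [], between, edge)
    for t in cand:
        assert (s < t).sum() >= edge and (s > t).sum() >= edge
    if cand.size:
        t0 = float(cand[0])
        for t in admissible_knots(x, [t0], between, edge):
            lo, hi = min(t, t0), max(t, t0)
            assert ((s > lo) & (s < hi)).sum() >= between
            assert t != t0


class TestForwardPass:
    def test_noiseless_line_is_exact(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 10, 40))[:, None]
        y = 2 * x[:, 0] + 1
        m = forward_pass(x, y, FitConstraints(penalty=0.0, cubic=False))
        assert m.training_sse <= 1e-9

    def test_constant_response_gives_intercept_only(self):
        x = np.linspace(0, 1, 50)[:, None]
        m = forward_pass(x, np.full(50, 0.37),
                         FitConstraints(penalty=0.0, cubic=False))
        assert m.n_basis == 0
        assert np.allclose(m.predict(x), 0.37)

    def test_too_few_rows_raises(self):
        x = np.linspace(0, 1, 15)[:, None]
        with pytest.raises(ValueError, match="rows"):
            forward_pass(x, x[:, 0], FitConstraints(min_obs_to_edge=10))

    def test_binary_predictor_enters_linearly(self):
        rng = np.random.default_rng(1)
        x0 = np.sort(rng.uniform(0, 10, 120))
        x1 = rng.integers(0, 2, 120).astype(float)
        X = np.column_stack([x0, x1])
        y = np.maximum(0, x0 - 5) + 0.8 * x1
        m = forward_pass(X, y, FitConstraints(penalty=0.0, cubic=False))
        for b in m.basis:
            for t in b.terms:
                if t.variable == 1:
                    assert t.linear

    def test_oracle_nesting_unconstrained_fits_at_least_as_well(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (80, 2))
        y = np.sin(6 * X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.1, 80)
        constrained = forward_pass(X, y, FitConstraints(penalty=0.0, cubic=False))
        free = forward_pass(X, y, FitConstraints(
            penalty=0.0, cubic=False, min_obs_between_knots=1, min_obs_to_edge=1))
        assert free.training_sse <= constrained.training_sse + 1e-9


def brute_force_first_knot(x, y, min_between, min_edge):
    """Exhaustive one-knot oracle: best reflected hinge pair by SSE,
    ties toward the smaller knot."""
    best = (np.inf, None)
    for t in admissible_knots(x, [], min_between, min_edge):
        B = np.column_stack([np.ones_like(x),
                             np.maximum(0, x - t), np.maximum(0, t - x)])
        coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
        sse = float(np.sum((y - B @ coef) ** 2))
        if sse < best[0] * (1 - 1e-9):
            best = (sse, t)
    return best[1]


@pytest.mark.parametrize("seed", range(10))
def test_first_knot_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 13))
    x = np.sort(rng.uniform(0, 1, n))
    y = rng.normal(0, 1, n) + 2 * np.maximum(0, x - x[n // 2])
    c = FitConstraints(penalty=0.0, cubic=False,
                       min_obs_between_knots=3, min_obs_to_edge=2,
                       max_initial_funcs=2, max_final_funcs=2)
    m = forward_pass(x[:, None], y, c)
    expected = brute_force_first_knot(x, y, 3, 2)
    if expected is None:
        assert m.n_basis == 0
    else:
        assert m.basis[0].terms[0].knot == expected


class TestBackwardPrune:
    def test_intercept_only_unchanged(self):
        x = np.linspace(0, 1, 30)[:, None]
        y = np.full(30, 2.0)
        m = forward_pass(x, y, FitConstraints(penalty=0.0, cubic=False))
        p = backward_prune(m, x, y, FitConstraints(penalty=0.0, cubic=False))
        assert p.n_basis == 0 and p.intercept == pytest.approx(2.0)

    def test_redundant_basis_removed_without_sse_increase(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 60))
        y = 1.0 + 2.0 * np.maximum(0, x - 4.0)
        # hand-built model with a basis function the response never needs
        basis = [BasisFunction((HingeTerm(0, 4.0, +1),)),
                 BasisFunction((HingeTerm(0, 4.0, -1),)),
                 BasisFunction((HingeTerm(0, 7.0, +1),))]
        B = np.column_stack([np.ones_like(x)] +
                            [b.eval(x[:, None]) for b in basis])
        coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
        sse0 = float(np.sum((y - B @ coef) ** 2))
        m = MarsModel(intercept=coef[0], coefficients=coef[1:], basis=basis,
                      n_vars=1, var_min=x.min(keepdims=True),
                      var_max=x.max(keepdims=True), training_sse=sse0,
                      n_train=x.size)
        p = backward_prune(m, x[:, None], y,
                           FitConstraints(penalty=1.0, cubic=False))
        assert p.n_basis < 3
        assert p.training_sse <= sse0 + 1e-9

    def test_gcv_not_worse_than_unpruned(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.uniform(0, 1, (70, 2))
            y = np.maximum(0, X[:, 0] - 0.5) + r.normal(0, 0.2, 70)
            c = FitConstraints(penalty=1.0, cubic=False,
                               min_obs_between_knots=5, min_obs_to_edge=3)
            un = forward_pass(X, y, c)
            pr = backward_prune(un, X, y, c)
            g_un = gcv(un.training_sse, 70, un.n_basis, un.n_knots, 1.0)
            g_pr = gcv(pr.training_sse, 70, pr.n_basis, pr.n_knots, 1.0)
            assert g_pr <= g_un + 1e-12


class TestGcv:
    def test_closed_form_no_basis(self):
        assert gcv(2.0, 20, 0, 0, 0.0) == pytest.approx(
            (2.0 / 20) / (1 - 1 / 20) ** 2)

    def test_linear_in_sse(self):
        assert gcv(4.0, 50, 3, 2, 1.0) == pytest.approx(2 * gcv(2.0, 50, 3, 2, 1.0))

    def test_monotone_in_penalty(self):
        vals = [gcv(1.0, 50, 4, 3, p) for p in (0, 1, 2, 3, 4, 5)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_inadmissible_is_infinite(self):
        assert gcv(1.0, 10, 9, 5, 2.0) == np.inf


class TestPenaltySelection:
    def test_noiseless_ties_break_to_smallest(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 10, 60))[:, None]
        y = 3 * x[:, 0] - 1
        c = FitConstraints(cubic=False, rng_seed=5)
        assert select_penalty_cv(x, y, c, grid=[0, 2, 4]) == 0.0

    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (60, 2))
        y = np.maximum(0, X[:, 0] - 0.4) + rng.normal(0, 0.3, 60)
        c = FitConstraints(cubic=False, rng_seed=11,
                           min_obs_between_knots=5, min_obs_to_edge=3)
        assert select_penalty_cv(X, y, c) == select_penalty_cv(X, y, c)

    def test_empty_grid_raises(self):
        x = np.linspace(0, 1, 30)[:, None]
        with pytest.raises(ValueError):
            select_penalty_cv(x, x[:, 0], FitConstraints(cubic=False), grid=[])

    def test_heavy_noise_prefers_positive_penalty(self):
        # sharp piecewise-linear truth buried in noise: the cross-validated
        # penalty should usually exceed 0
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = np.sort(rng.uniform(0, 10, 60))
            y = np.abs(x - 5.0) + rng.normal(0, 2.0, 60)
            c = FitConstraints(cubic=False, rng_seed=seed,
                               min_obs_between_knots=5, min_obs_to_edge=3)
            if select_penalty_cv(x[:, None], y, c,
                                 grid=[0.0, 1.0, 3.0, 5.0]) > 0:
                hits += 1
        assert hits > 10


class TestRSquared:
    def test_perfect_and_intercept_only(self):
        x = np.linspace(0, 1, 30)[:, None]
        y = 2 * x[:, 0]
        m, _ = fit_mars(x, y, FitConstraints(penalty=0.0, cubic=False,
                                             min_obs_between_knots=5,
                                             min_obs_to_edge=3))
        assert r_squared(m, x, y) == pytest.approx(1.0, abs=1e-9)
        m0 = MarsModel(intercept=float(y.mean()), coefficients=np.empty(0),
                       basis=[], n_vars=1, var_min=x.min(0), var_max=x.max(0))
        assert r_squared(m0, x, y) == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_pearson_correlation(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 10, 100))[:, None]
        y = np.maximum(0, x[:, 0] - 4) + rng.normal(0, 0.3, 100)
        m, _ = fit_mars(x, y, FitConstraints(penalty=1.0, cubic=False))
        r2 = r_squared(m, x, y)
        rho = np.corrcoef(m.predict(x), y)[0, 1]
        assert r2 == pytest.approx(rho ** 2, abs=1e-8)

    def test_zero_variance_response_warns(self):
        x = np.linspace(0, 1, 10)[:, None]
        m0 = MarsModel(intercept=1.0, coefficients=np.empty(0), basis=[],
                       n_vars=1, var_min=x.min(0), var_max=x.max(0))
        with pytest.warns(UserWarning):
            assert r_squared(m0, x, np.ones(10)) == 0.0


class TestCubicMode:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 10, 200))[:, None]
        y = 1 + 2 * np.maximum(0, x[:, 0] - 4) + rng.normal(0, 0.05, 200)
        c = FitConstraints(penalty=1.0, cubic=False)
        lin, _ = fit_mars(x, y, c)
        return x, y, lin, to_cubic(lin, x, y)

    def test_agrees_with_linear_outside_side_knot_spans(self, fitted):
        x, y, lin, cub = fitted
        spans = [(t.t_minus, t.t_plus) for b in cub.basis for t in b.terms
                 if not t.linear]
        grid = np.linspace(x.min(), x.max(), 400)
        outside = np.ones_like(grid, dtype=bool)
        for lo, hi in spans:
            outside &= (grid <= lo) | (grid >= hi)
        assert outside.any()
        # identical basis values outside every smoothing interval, so the
        # two modes differ only through the least-squares refit
        Bl = lin.basis_matrix(grid[:, None])[outside]
        Bc = cub.basis_matrix(grid[:, None])[outside]
        assert np.allclose(Bl, Bc, atol=1e-12)

    def test_first_derivative_is_continuous(self, fitted):
        x, _, _, cub = fitted
        grid = np.linspace(float(x.min()), float(x.max()), 20001)
        f = cub.predict(grid[:, None])
        d = np.diff(f) / np.diff(grid)
        # jump in the numeric derivative stays at discretisation scale
        assert np.max(np.abs(np.diff(d))) < 1e-2

    def test_no_hinge_model_unchanged(self):
        x = np.linspace(0, 1, 30)[:, None]
        m0 = MarsModel(intercept=1.5, coefficients=np.empty(0), basis=[],
                       n_vars=1, var_min=x.min(0), var_max=x.max(0))
        assert to_cubic(m0, x).intercept == 1.5


def test_hinge_parameter_recovery():
    """y = th0 + th1 (x-t)+ + noise at n=500: knot recovered within the data
    spacing and coefficients within 5 sigma/sqrt(n)."""
    rng = np.random.default_rng(9)
    n, sigma, t_true, th0, th1 = 500, 0.05, 4.2371, 1.0, 2.0
    x = np.sort(rng.uniform(0, 10, n))
    y = th0 + th1 * np.maximum(0, x - t_true) + rng.normal(0, sigma, n)
    c = FitConstraints(penalty=0.0, cubic=False, max_final_funcs=2,
                       max_initial_funcs=2)
    m, _ = fit_mars(x[:, None], y, c)
    knots = [t.knot for b in m.basis for t in b.terms]
    spacing = np.max(np.diff(x))
    assert min(abs(k - t_true) for k in knots) <= spacing
    slope = [c_ for c_, b in zip(m.coefficients, m.basis)
             if b.terms[0].direction == 1][0]
    assert abs(slope - th1) < 5 * sigma / np.sqrt(n)


def test_serialization_roundtrip_bit_identical(tmp_path):
    rng = np.random.default_rng(10)
    X = rng.uniform(0, 1, (100, 3))
    X[:, 2] = (X[:, 2] > 0.5).astype(float)
    y = np.maximum(0, X[:, 0] - 0.5) + X[:, 2] + rng.normal(0, 0.1, 100)
    m, _ = fit_mars(X, y, FitConstraints(penalty=1.0, cubic=True,
                                         min_obs_between_knots=10,
                                         min_obs_to_edge=5))
    path = tmp_path / "model.json"
    m.save(path)
    m2 = MarsModel.load(path)
    assert np.array_equal(m.predict(X), m2.predict(X))


def test_predict_column_mismatch_raises():
    x = np.linspace(0, 1, 30)[:, None]
    m = forward_pass(x, x[:, 0], FitConstraints(penalty=0.0, cubic=False,
                                                min_obs_between_knots=5,
                                                min_obs_to_edge=3))
    with pytest.raises(ValueError, match="columns"):
        m.predict(np.zeros((4, 2)))
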