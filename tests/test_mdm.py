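"""Core DLM: standardization, regressors, filtering, smoothing, scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdmgroup import (
    NodePrior,
    PriorPolicy,
    build_regressors,
    filter_node,
    local_score,
    smooth_node,
    standardize,
)
from mdmgroup.mdm import _HAVE_NUMBA, _filter_loop, _filter_loop_py

from conftest import make_series


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------


class TestStandardize:
    def test_three_point_column(self):
        out = standardize(make_series([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])
        assert out.standardized

    def test_idempotent(self, rng):
        s = standardize(make_series(rng.normal(size=(50, 3))))
        again = standardize(s)
        np.testing.assert_allclose(again.values, s.values, atol=1e-12)

    def test_column_moments(self, rng):
        out = standardize(make_series(rng.normal(2.0, 5.0, size=(100, 3))))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_names_region(self):
        bad = make_series(np.column_stack([np.ones(10), np.arange(10.0)]),
                          names=("flat", "ok"))
        with pytest.raises(ValueError, match="flat"):
            standardize(bad)


# ---------------------------------------------------------------------------
# build_regressors
# ---------------------------------------------------------------------------


class TestBuildRegressors:
    def test_no_parents_gives_intercept_only(self, rng):
        s = make_series(rng.normal(size=(7, 3)))
        F = build_regressors(s, 0, [])
        np.testing.assert_array_equal(F, np.ones((7, 1)))

    def test_parent_columns_contemporaneous(self):
        s = make_series([[0.0, 5.0], [1.0, 7.0]])
        F = build_regressors(s, 0, [1])
        np.testing.assert_array_equal(F, [[1.0, 5.0], [1.0, 7.0]])

    def test_ordering_follows_given_sequence(self, rng):
        s = make_series(rng.normal(size=(6, 4)))
        F = build_regressors(s, 0, [3, 1])
        np.testing.assert_array_equal(F[:, 1], s.values[:, 3])
        np.testing.assert_array_equal(F[:, 2], s.values[:, 1])

    def test_self_loop_rejected(self, rng):
        s = make_series(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="self-loop"):
            build_regressors(s, 1, [1])


# ---------------------------------------------------------------------------
# filter_node
# ---------------------------------------------------------------------------


def batch_normal_gamma_logml(y, F, c0_scale, n0, d0):
    """Independent oracle: closed-form marginal likelihood of the batch
    conjugate regression (coefficients N(0, c0_scale*I / phi), precision
    phi ~ Gamma(n0/2, d0/2))."""
    T, p = F.shape
    Lam0 = np.eye(p) / c0_scale
    LamN = Lam0 + F.T @ F
    mN = np.linalg.solve(LamN, F.T @ y)
    dN = d0 + y @ y - mN @ LamN @ mN
    nN = n0 + T
    return (
        -T / 2 * math.log(2 * math.pi)
        + 0.5 * np.linalg.slogdet(Lam0)[1]
        - 0.5 * np.linalg.slogdet(LamN)[1]
        + (n0 / 2) * math.log(d0 / 2)
        - (nN / 2) * math.log(dN / 2)
        + math.lgamma(nN / 2)
        - math.lgamma(n0 / 2)
    )


class TestFilterNode:
    @pytest.mark.parametrize("p", [1, 2, 4])
    def test_prequential_identity_delta_one(self, rng, p):
        """At delta=1 the summed one-step log densities equal the batch
        conjugate normal-gamma marginal likelihood."""
        T = 60
        F = np.column_stack([np.ones(T), rng.normal(size=(T, p - 1))])[:, :p]
        y = F @ rng.normal(size=p) + rng.normal(size=T)
        prior = NodePrior(m0=np.zeros(p), c0_scale=3.0, n0=0.001, d0=0.001, delta=1.0)
        fr = filter_node(y, F, prior)
        oracle = batch_normal_gamma_logml(y, F, 3.0, 0.001, 0.001)
        assert fr.total == pytest.approx(oracle, abs=1e-8)

    def test_zero_data_zero_forecasts(self):
        T = 10
        y = np.zeros(T)
        F = np.ones((T, 1))
        fr = filter_node(y, F, NodePrior(m0=np.zeros(1)))
        np.testing.assert_allclose(fr.means, 0.0)

    def test_per_time_density_is_student_t(self):
        """T=3 toy: each log density matches a hand evaluation of the t pdf
        at the forecast mean/scale/df."""
        y = np.array([0.5, -0.2, 1.0])
        F = np.ones((3, 1))
        c0, n0, d0, delta = 2.0, 1.0, 1.0, 0.9
        fr = filter_node(y, F, NodePrior(np.zeros(1), c0, n0, d0, delta))

        def t_logpdf(x, df, loc, scale2):
            z2 = (x - loc) ** 2 / scale2
            return (
                math.lgamma((df + 1) / 2)
                - math.lgamma(df / 2)
                - 0.5 * math.log(df * math.pi * scale2)
                - (df + 1) / 2 * math.log(1 + z2 / df)
            )

        m, C = 0.0, c0 * (d0 / n0)
        n, d = n0, d0
        for t in range(3):
            S = d / n
            R = C / delta
            q = R + S
            assert fr.loglik[t] == pytest.approx(t_logpdf(y[t], n, m, q), abs=1e-12)
            e = y[t] - m
            A = R / q
            n1, d1 = n + 1, d + S * e * e / q
            m = m + A * e
            C = (d1 / n1 / S) * (R - A * A * q)
            n, d = n1, d1

    def test_precision_bookkeeping(self, rng):
        y = rng.normal(size=25)
        F = np.ones((25, 1))
        fr = filter_node(y, F, NodePrior(np.zeros(1), 3.0, 0.001, 0.001, 0.9))
        np.testing.assert_allclose(fr.ns, 0.001 + np.arange(1, 26))
        assert np.all(fr.ds > 0)

    def test_nonfinite_input_rejected(self):
        y = np.array([1.0, np.nan])
        with pytest.raises(ValueError, match="non-finite"):
            filter_node(y, np.ones((2, 1)), NodePrior(np.zeros(1)))

    def test_python_fallback_matches_jit(self, rng):
        y = rng.normal(size=30)
        F = np.column_stack([np.ones(30), rng.normal(size=30)])
        args = (y, F, np.zeros(2), 3.0, 0.001, 0.001, 0.9)
        out_py = _filter_loop_py(*args)
        out = _filter_loop(*args)
        for a, b in zip(out_py, out):
            np.testing.assert_allclose(a, b, atol=1e-12)
        assert _HAVE_NUMBA  # the fast path is expected in this environment


# ---------------------------------------------------------------------------
# smooth_node
# ---------------------------------------------------------------------------


class TestSmoothNode:
    def test_delta_one_smoothed_equals_final_filtered(self, rng):
        y = rng.normal(size=40)
        F = np.column_stack([np.ones(40), rng.normal(size=40)])
        fr = filter_node(y, F, NodePrior(np.zeros(2), delta=1.0))
        sm = smooth_node(fr)
        np.testing.assert_allclose(
            sm.means, np.broadcast_to(fr.means[-1], sm.means.shape), atol=1e-10
        )

    def test_single_step_boundary(self, rng):
        fr = filter_node(np.array([1.3]), np.ones((1, 1)), NodePrior(np.zeros(1)))
        sm = smooth_node(fr)
        np.testing.assert_allclose(sm.means, fr.means)

    def test_matches_dense_joint_gaussian_oracle(self, rng):
        """delta=0.95, T=4: smoothed moments equal the conditional of the
        dense joint Gaussian built from the implied state covariances (the
        known-variance limit, enforced with a huge precision prior)."""
        T, p, delta = 4, 2, 0.95
        F = np.column_stack([np.ones(T), rng.normal(size=T)])
        y = rng.normal(size=T)
        prior = NodePrior(np.zeros(p), 3.0, 1e12, 1e12, delta)
        fr = filter_node(y, F, prior)
        sm = smooth_node(fr)

        C0 = 3.0 * np.eye(p)
        covs = [C0] + [fr.covs[t] for t in range(T)]
        Ws = [covs[t] * (1 - delta) / delta for t in range(T)]
        cum = []
        acc = C0.copy()
        for k in range(T):
            acc = acc + Ws[k]
            cum.append(acc.copy())
        d = T * p
        Sig = np.zeros((d, d))
        for s in range(T):
            for t in range(T):
                Sig[s * p:(s + 1) * p, t * p:(t + 1) * p] = cum[min(s, t)]
        H = np.zeros((T, d))
        for t in range(T):
            H[t, t * p:(t + 1) * p] = F[t]
        Syy = H @ Sig @ H.T + np.eye(T)
        Sty = Sig @ H.T
        mean_post = (Sty @ np.linalg.solve(Syy, y)).reshape(T, p)
        cov_post = Sig - Sty @ np.linalg.solve(Syy, Sty.T)
        var_post = np.diag(cov_post).reshape(T, p)
        np.testing.assert_allclose(sm.means, mean_post, atol=1e-8)
        np.testing.assert_allclose(sm.variances, var_post, atol=1e-8)

    def test_variances_positive_and_theta_bar_is_time_mean(self, rng):
        y = rng.normal(size=30)
        F = np.column_stack([np.ones(30), rng.normal(size=30)])
        sm = smooth_node(filter_node(y, F, NodePrior(np.zeros(2), delta=0.9)))
        assert np.all(sm.variances > 0)
        np.testing.assert_allclose(sm.theta_bar, sm.means.mean(axis=0))


# ---------------------------------------------------------------------------
# local_score
# ---------------------------------------------------------------------------


class TestLocalScore:
    def test_permutation_invariance(self, rng, fast_policy):
        s = make_series(rng.normal(size=(50, 4)))
        a = local_score(s, 0, [2, 3], fast_policy)
        b = local_score(s, 0, [3, 2], fast_policy)
        assert a == b

    def test_logbf_from_two_calls(self, rng, fast_policy):
        s = standardize(make_series(rng.normal(size=(60, 3))))
        lpl_pair = sum(local_score(s, r, [], fast_policy) for r in range(3))
        alt = local_score(s, 0, [1], fast_policy) + sum(
            local_score(s, r, [], fast_policy) for r in (1, 2)
        )
        logbf = alt - lpl_pair
        direct = local_score(s, 0, [1], fast_policy) - local_score(s, 0, [], fast_policy)
        assert logbf == pytest.approx(direct, abs=1e-10)

    def test_discount_selection_takes_grid_maximum(self, rng):
        s = make_series(rng.normal(size=(40, 2)))
        grid = (0.85, 0.95, 1.0)
        best = local_score(s, 0, [1], PriorPolicy(delta_grid=grid))
        singles = [
            local_score(s, 0, [1], PriorPolicy(delta_grid=(d,))) for d in grid
        ]
        assert best == pytest.approx(max(singles), abs=1e-12)

    def test_true_parent_beats_empty_set(self, fast_policy):
        """Monte-Carlo oracle: with a true contemporaneous parent of weight
        0.7 at T=300, the parent model wins in >= 95% of 100 replicates."""
        wins = 0
        for rep in range(100):
            rg = np.random.default_rng(1000 + rep)
            x = rg.normal(size=300)
            y = 0.7 * x + rg.normal(size=300)
            s = standardize(make_series(np.column_stack([x, y])))
            wins += local_score(s, 1, [0], fast_policy) > local_score(
                s, 1, [], fast_policy
            )
        assert wins >= 95


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.sampled_from([0.85, 1.0]))
def test_filter_bookkeeping_properties(seed, delta):
    """d_t stays positive and n_t = n0 + t for arbitrary Gaussian inputs."""
    rg = np.random.default_rng(seed)
    T = 20
    y = rg.normal(size=T)
    F = np.column_stack([np.ones(T), rg.normal(size=T)])
    fr = filter_node(y, F, NodePrior(np.zeros(2), 3.0, 0.001, 0.001, delta))
    assert np.all(fr.ds > 0)
    np.testing.assert_allclose(fr.ns, 0.001 + np.arange(1, T + 1))
    assert np.all(np.isfinite(fr.loglik))
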