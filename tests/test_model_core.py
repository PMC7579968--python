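"""Likelihood, E-step, M-step and EM driver, checked against independent
brute-force oracles (config enumeration, scalar-loop objective)."""

import numpy as np
import pytest
from scipy.stats import norm

from pandm.matrices import ValidationError
from pandm.model import (
    PanDM,
    PanDMParams,
    Posteriors,
    Q_CLAMP,
    complete_loglik,
    e_step,
    fit_em,
    m_step,
    observed_loglik,
)

from conftest import (
    best_permutation_error,
    enum_posteriors,
    q_function,
    random_small_instance,
)


def _permute(params: PanDMParams, perm) -> PanDMParams:
    perm = list(perm)
    return PanDMParams(pi=params.pi[perm], Q=params.Q[perm],
                       mu0=params.mu0, sigma0=params.sigma0,
                       mu1=params.mu1, sigma1=params.sigma1)


class TestCompleteLoglik:
    def test_single_site_closed_form(self):
        params = PanDMParams(pi=[1.0], Q=[[0.5]], mu0=[0.0], sigma0=[1.0],
                             mu1=[0.0], sigma1=[1.0])
        z = np.array([[0.0]])
        value = complete_loglik(z, A=[1], H=[[0]], params=params)
        assert value == pytest.approx(np.log(0.5) - 0.5 * np.log(2 * np.pi),
                                      abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z, mask, params = random_small_instance(seed, G=10, C=3, K=3,
                                                missing_rate=0.2)
        A = rng.integers(1, params.K + 1, size=10)
        H = rng.integers(0, 2, size=(10, 3))
        expected = 0.0
        for g in range(10):
            k = A[g] - 1
            expected += np.log(params.pi[k])
            for c in range(3):
                if not mask[g, c]:
                    continue
                if H[g, c]:
                    expected += np.log(params.Q[k, c]) + norm.logpdf(
                        z[g, c], params.mu1[c], params.sigma1[c])
                else:
                    expected += np.log1p(-params.Q[k, c]) + norm.logpdf(
                        z[g, c], params.mu0[c], params.sigma0[c])
        assert complete_loglik(z, A, H, params) == pytest.approx(expected,
                                                                 abs=1e-10)

    def test_invariant_under_joint_label_permutation(self):
        rng = np.random.default_rng(3)
        z, mask, params = random_small_instance(3, G=6, C=2, K=3)
        A = rng.integers(1, 4, size=6)
        H = rng.integers(0, 2, size=(6, 2))
        perm = [2, 0, 1]
        inv = np.argsort(perm)
        A_perm = np.array([inv[a - 1] + 1 for a in A])
        assert complete_loglik(z, A, H, params) == pytest.approx(
            complete_loglik(z, A_perm, H, _permute(params, perm)), abs=1e-10)

    def test_label_out_of_range_rejected(self):
        _, _, params = random_small_instance(0, G=2, C=2, K=2)
        with pytest.raises(ValidationError, match="1..2"):
            complete_loglik(np.zeros((2, 2)), A=[1, 3], H=np.zeros((2, 2)),
                            params=params)


class TestEStep:
    def test_single_cluster_membership_is_one(self):
        z, _, params = random_small_instance(1, G=5, C=2, K=1)
        post = e_step(z, params)
        assert np.allclose(post.membership, 1.0)

    def test_zero_q_gives_zero_dm_probability(self):
        _, _, params = random_small_instance(2, G=4, C=2, K=2)
        params.Q = np.zeros_like(params.Q)
        post = e_step(np.random.default_rng(2).normal(size=(4, 2)), params)
        assert np.allclose(post.dm_prob, 0.0)

    @pytest.mark.parametrize("seed,missing", [(0, 0.0), (1, 0.0), (2, 0.3),
                                              (3, 0.3), (4, 0.5)])
    def test_matches_enumeration_oracle(self, seed, missing):
        z, mask, params = random_small_instance(seed, G=6, C=2, K=2,
                                                missing_rate=missing)
        post = e_step(z, params)
        mem, joint, dm, loglik = enum_posteriors(z, mask, params)
        assert np.allclose(post.membership, mem, atol=1e-10)
        assert np.allclose(post.joint, joint, atol=1e-10)
        assert np.allclose(post.dm_prob, dm, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle_larger(self, seed):
        z, mask, params = random_small_instance(seed + 10, G=20, C=3, K=3,
                                                missing_rate=0.2)
        post = e_step(z, params)
        mem, joint, dm, _ = enum_posteriors(z, mask, params)
        assert np.allclose(post.membership, mem, atol=1e-10)
        assert np.allclose(post.joint, joint, atol=1e-10)

    def test_membership_rows_sum_to_one_and_joint_is_consistent(self):
        z, _, params = random_small_instance(5, G=12, C=3, K=3)
        post = e_step(z, params)
        assert np.allclose(post.membership.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(post.dm_prob, post.joint.sum(axis=1), atol=1e-10)
        assert (post.dm_prob >= 0).all() and (post.dm_prob <= 1).all()

    def test_extreme_z_is_stable_in_log_space(self):
        _, _, params = random_small_instance(6, G=2, C=2, K=2)
        z = np.array([[-300.0, 250.0], [-500.0, -400.0]])
        post = e_step(z, params)
        assert np.isfinite(post.membership).all()
        assert np.allclose(post.membership.sum(axis=1), 1.0)

    def test_missing_column_equals_reduced_model(self):
        """Deleting one cancer from a site's observations must equal running
        the E-step on the model restricted to the remaining cancers."""
        z, _, params = random_small_instance(7, G=4, C=3, K=2)
        z_holed = z.copy()
        z_holed[:, 1] = np.nan
        post_full = e_step(z_holed, params)
        reduced = PanDMParams(pi=params.pi, Q=params.Q[:, [0, 2]],
                              mu0=params.mu0[[0, 2]],
                              sigma0=params.sigma0[[0, 2]],
                              mu1=params.mu1[[0, 2]],
                              sigma1=params.sigma1[[0, 2]])
        post_red = e_step(z[:, [0, 2]], reduced)
        assert np.allclose(post_full.membership, post_red.membership,
                           atol=1e-12)
        # the held-out cancer reports the cluster-weighted prior
        expected = post_full.membership @ params.Q[:, 1]
        assert np.allclose(post_full.dm_prob[:, 1], expected, atol=1e-12)


class TestMStep:
    def test_hard_memberships_give_empirical_fractions(self):
        z, mask, params = random_small_instance(0, G=6, C=2, K=2)
        membership = np.array([[1, 0], [1, 0], [1, 0], [1, 0], [0, 1], [0, 1]],
                              dtype=float)
        joint = membership[:, :, None] * np.full((6, 2, 2), 0.5)
        post = Posteriors(membership=membership, joint=joint,
                          dm_prob=joint.sum(axis=1))
        new = m_step(z, post)
        assert np.allclose(new.pi, [4 / 6, 2 / 6], atol=1e-12)

    def test_zero_joint_gives_clamped_q_and_pooled_null_moments(self):
        z, mask, params = random_small_instance(1, G=8, C=2, K=2)
        post = e_step(z, params)
        post.joint[:] = 0.0
        post.dm_prob[:] = 0.0
        new = m_step(z, post, prev_params=params)
        assert np.allclose(new.Q, Q_CLAMP)
        for c in range(2):
            w = np.ones(8)
            mu = (w * z[:, c]).sum() / w.sum()
            var = (w * (z[:, c] - mu) ** 2).sum() / w.sum()
            assert new.mu0[c] == pytest.approx(mu, abs=1e-12)
            assert new.sigma0[c] ** 2 == pytest.approx(var, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_output_locally_maximizes_q_function(self, seed):
        """Perturbing any single parameter of the M-step output by +-1e-4
        never increases the EM objective."""
        z, mask, params = random_small_instance(seed, G=15, C=2, K=2,
                                                missing_rate=0.1)
        post = e_step(z, params)
        new = m_step(z, post, prev_params=params)
        # the check below assumes no clamp/swap was active at the optimum
        assert (new.Q > Q_CLAMP * 2).all() and (new.Q < 1 - Q_CLAMP * 2).all()
        assert (new.mu1 < new.mu0).all()
        base = q_function(z, mask, post, new)
        eps = 1e-4

        def assert_not_better(perturbed):
            assert q_function(z, mask, post, perturbed) <= base + 1e-10

        for k in range(new.K):
            for j in range(new.K):
                if j == k:
                    continue
                for sign in (+1, -1):
                    p = new.copy()
                    p.pi = p.pi.copy()
                    p.pi[k] += sign * eps
                    p.pi[j] -= sign * eps
                    if (p.pi <= 0).any():
                        continue
                    assert_not_better(p)
            for c in range(new.C):
                for sign in (+1, -1):
                    p = new.copy()
                    p.Q[k, c] += sign * eps
                    assert_not_better(p)
        for name in ("mu0", "mu1", "sigma0", "sigma1"):
            for c in range(new.C):
                for sign in (+1, -1):
                    p = new.copy()
                    getattr(p, name)[c] += sign * eps
                    assert_not_better(p)

    def test_component_swap_restores_identifiability(self):
        """If the weighted moments put the alternative above the null, the
        components are swapped and the pattern column flips."""
        rng = np.random.default_rng(8)
        z = rng.normal(0, 1, size=(20, 1))
        z[:10] += 3.0
        membership = np.ones((20, 1))
        joint = np.zeros((20, 1, 1))
        joint[:10, 0, 0] = 1.0  # "alternative" weight on the positive side
        post = Posteriors(membership=membership, joint=joint,
                          dm_prob=joint.sum(axis=1))
        new = m_step(z, post)
        assert (new.mu1 <= new.mu0).all()


class TestFusedSweep:
    @pytest.mark.parametrize("use_jit", [False, True])
    def test_one_iteration_matches_reference_path(self, use_jit):
        """The fused EM sweep (used by the fit loop) reproduces the reference
        e_step + m_step composition exactly, jitted or not."""
        from pandm.model import _em_iterate
        for seed in range(3):
            z, mask, params = random_small_instance(seed, G=25, C=3, K=3,
                                                    missing_rate=0.25)
            post = e_step(z, params)
            ref = m_step(z, post, prev_params=params)
            new, loglik = _em_iterate(z, mask, params, use_jit=use_jit)
            assert loglik == pytest.approx(post.loglik, abs=1e-9)
            assert np.allclose(new.flat(), ref.flat(), atol=1e-9)


class TestObservedLoglik:
    def test_coincident_components_reduce_to_single_normal(self):
        params = PanDMParams(pi=[1.0], Q=[[0.5]], mu0=[0.0], sigma0=[1.0],
                             mu1=[0.0], sigma1=[1.0])
        assert observed_loglik(np.array([[0.0]]), params) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        z, mask, params = random_small_instance(seed, G=10, C=3, K=3,
                                                missing_rate=0.2)
        _, _, _, expected = enum_posteriors(z, mask, params)
        assert observed_loglik(z, params) == pytest.approx(expected,
                                                           abs=1e-10)

    def test_invariant_under_cluster_permutation(self):
        z, _, params = random_small_instance(4, G=8, C=2, K=3)
        assert observed_loglik(z, params) == pytest.approx(
            observed_loglik(z, _permute(params, [1, 2, 0])), abs=1e-10)


class TestFitEM:
    def test_loglik_trace_non_decreasing(self):
        z, _, params = random_small_instance(0, G=200, C=2, K=2)
        rng = np.random.default_rng(0)
        zdata = rng.normal(-1, 1.5, size=(200, 2))
        record = fit_em(zdata, 2, seed=0)
        diffs = np.diff(record.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        z = rng.normal(-0.5, 1.5, size=(300, 2))
        r1 = fit_em(z, 2, seed=5)
        r2 = fit_em(z, 2, seed=5)
        assert np.array_equal(r1.params.flat(), r2.params.flat())
        assert r1.bic == r2.bic

    def test_parameter_recovery_on_default_design(self, fast_scenario,
                                                  fast_fit):
        """At the study's design size (G = 20,000) the fitted patterns and
        emission means match the generating truth within 0.05 per entry."""
        params, _ = fast_scenario
        record, _ = fast_fit
        assert best_permutation_error(params.Q, record.params.Q) <= 0.05
        # emission means carry a small soft-assignment bias at this overlap
        assert np.abs(record.params.mu1 - params.mu1).max() <= 0.1
        assert np.abs(record.params.mu0 - params.mu0).max() <= 0.1

    def test_c1_k1_matches_independent_two_component_mixture(self):
        """With one cancer and one cluster the model is exactly a
        two-component normal mixture; an independently implemented mixture
        EM must land on the same optimum."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(7)
        n = 4000
        h = rng.random(n) < 0.3
        z = np.where(h, rng.normal(-4.0, 0.8, n), rng.normal(0, 1, n))[:, None]
        record = fit_em(z, 1, tol=1e-12, max_iter=10000, seed=3)
        p = record.params
        gm = GaussianMixture(n_components=2, covariance_type="diag", tol=0,
                             max_iter=10000, random_state=3, n_init=3)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(z)
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        alt = int(np.argmin(means))
        assert p.Q[0, 0] == pytest.approx(gm.weights_[alt], abs=1e-6)
        assert p.mu1[0] == pytest.approx(means[alt], abs=1e-6)
        assert p.sigma1[0] == pytest.approx(sds[alt], abs=1e-6)
        assert p.mu0[0] == pytest.approx(means[1 - alt], abs=1e-6)
        assert p.sigma0[0] == pytest.approx(sds[1 - alt], abs=1e-6)

    def test_invalid_arguments_rejected(self):
        z = np.zeros((5, 2))
        with pytest.raises(ValueError):
            fit_em(z, 0)
        with pytest.raises(ValueError):
            fit_em(z, 2, tol=-1.0)

    def test_all_missing_row_rejected(self):
        z = np.array([[0.1, 0.2], [np.nan, np.nan]])
        with pytest.raises(ValidationError, match="row 1"):
            fit_em(z, 1)


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        est = PanDM(n_patterns=3, tol=1e-3, random_state=4)
        assert est.get_params()["n_patterns"] == 3
        est.set_params(n_patterns=2)
        rng = np.random.default_rng(0)
        z = rng.normal(-0.5, 1.5, size=(400, 2))
        est.fit(z)
        assert est.Q_.shape == (2, 2)
        assert est.labels_.shape == (400,)
        assert set(np.unique(est.labels_)) <= {0, 1}
        assert est.predict_proba(z).shape == (400, 2)
        assert est.dm_proba(z).shape == (400, 2)
        assert np.isfinite(est.score(z))
        assert est.bic_ == pytest.approx(
            -2 * est.loglik_trace_[-1] + (2 - 1 + 2 * 2 + 4 * 2) * np.log(400))
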