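"""Inference engine: MLE, Wilks thresholds, profiles, LRTs, region tracing."""

import numpy as np
import pytest

import spherofit as sf
from spherofit.inference import (
    MeanModel,
    SteadyStateModel,
    maximize_likelihood,
    observed_information,
    profile_parameter,
    trace_confidence_region,
    slice_region_3d,
    wilks_threshold,
)


@pytest.fixture(scope="module")
def mech_data(gp_ref, sigma_ref):
    rng = np.random.default_rng(5)
    mu = sf.steady_state(gp_ref).as_array()
    X = rng.multivariate_normal(mu, sigma_ref, 20)
    return X, sigma_ref


@pytest.fixture(scope="module")
def mech_fit(mech_data):
    return SteadyStateModel().fit([mech_data])


# --------------------------------------------------------------------------
# MLE


def test_mean_model_mle_is_sample_mean(mech_data):
    X, S = mech_data
    model = MeanModel()
    fit = model.fit([(X, S)])
    assert np.allclose(fit.theta_hat, X.mean(axis=0), rtol=1e-12)
    # generic optimizer lands on the same point
    opt = maximize_likelihood(
        lambda th: model.loglik(th, (X, S)), X.mean(axis=0) * 1.05, model.bounds,
        n_starts=1,
    )
    assert np.allclose(opt.theta_hat, X.mean(axis=0), rtol=1e-5)


def test_mechanistic_mle_matches_mean_inversion(mech_data, mech_fit):
    X, _ = mech_data
    inv = sf.invert_steady_state(*X.mean(axis=0))
    assert np.allclose(mech_fit.theta_hat, inv.as_array(), rtol=1e-6)
    assert mech_fit.converged


def test_mle_recovers_truth_from_large_cohort(gp_ref, sigma_ref):
    rng = np.random.default_rng(12)
    mu = sf.steady_state(gp_ref).as_array()
    X = rng.multivariate_normal(mu, sigma_ref, 10_000)
    fit = SteadyStateModel().fit([(X, sigma_ref)])
    assert np.allclose(fit.theta_hat, gp_ref.as_array(), rtol=0.01)


def test_maximize_likelihood_rejects_bad_start():
    with pytest.raises(ValueError):
        maximize_likelihood(lambda th: -np.inf, np.array([0.5]), [(0, 1)])


# --------------------------------------------------------------------------
# thresholds


@pytest.mark.parametrize("alpha,nu,expected", [
    (0.95, 1, 1.9207), (0.95, 2, 2.9957), (0.95, 3, 3.9074),
])
def test_wilks_thresholds(alpha, nu, expected):
    assert wilks_threshold(alpha, nu) == pytest.approx(expected, abs=1e-4)


def test_wilks_threshold_validation():
    with pytest.raises(ValueError):
        wilks_threshold(1.5, 1)
    with pytest.raises(ValueError):
        wilks_threshold(0.95, 0)


# --------------------------------------------------------------------------
# profiles


def test_profile_quadratic_for_mean_model(mech_data):
    """Free-mean profile is exactly quadratic; CI equals mu_hat +/- 1.96 se."""
    X, S = mech_data
    model = MeanModel()
    fit = model.fit([(X, S)])
    obj = lambda th: model.loglik(th, (X, S))
    n = len(X)
    for i in range(3):
        prof = profile_parameter(obj, fit, i, model.bounds)
        # analytic profile: -(psi - mu_i)^2 / (2 Var(mu_hat_i)), with the
        # profile variance the marginal one, Sigma_ii / n
        var = S[i, i] / n
        expected = -((prof.psi_grid - fit.theta_hat[i]) ** 2) / (2 * var)
        assert np.allclose(prof.profile_values, expected, atol=1e-6)
        half = 1.959964 * np.sqrt(var)
        assert prof.ci[0] == pytest.approx(fit.theta_hat[i] - half, abs=1e-4 * half)
        assert prof.ci[1] == pytest.approx(fit.theta_hat[i] + half, abs=1e-4 * half)


def test_profile_normalisation_and_monotone_widening(mech_data, mech_fit):
    X, S = mech_data
    model = SteadyStateModel()
    obj = lambda th: model.loglik(th, (X, S))
    prof95 = profile_parameter(obj, mech_fit, 0, model.bounds, alpha=0.95)
    prof99 = profile_parameter(obj, mech_fit, 0, model.bounds, alpha=0.99)
    assert np.max(prof95.profile_values) == pytest.approx(0.0, abs=1e-8)
    assert np.all(prof95.profile_values <= 1e-12)
    assert prof99.ci[0] < prof95.ci[0] < prof95.ci[1] < prof99.ci[1]
    assert prof95.ci[0] >= model.bounds[0][0] and prof95.ci[1] <= model.bounds[0][1]
    # the MLE's own psi lies inside every CI
    assert prof95.ci[0] < mech_fit.theta_hat[0] < prof95.ci[1]


# --------------------------------------------------------------------------
# likelihood-ratio tests


def test_lrt_identical_groups_is_null(mech_data):
    X, S = mech_data
    model = SteadyStateModel()
    r = sf.lrt_group_equivalence({"a": [(X, S)], "b": [(X.copy(), S)]}, model)
    assert r.T == pytest.approx(0.0, abs=1e-5)
    assert r.p == pytest.approx(1.0, abs=1e-5)
    assert r.nu == 3
    r1 = sf.lrt_single_parameter({"a": [(X, S)], "b": [(X.copy(), S)]}, model, 0)
    assert r1.p == pytest.approx(1.0, abs=1e-4)
    assert r1.nu == 1


def test_lrt_statistic_invariant_to_relabelling(gp_ref, sigma_ref):
    rng = np.random.default_rng(21)
    mu = sf.steady_state(gp_ref).as_array()
    d1 = (rng.multivariate_normal(mu, sigma_ref, 15), sigma_ref)
    d2 = (rng.multivariate_normal(mu, sigma_ref, 15), sigma_ref)
    model = SteadyStateModel()
    r_ab = sf.lrt_group_equivalence({"a": [d1], "b": [d2]}, model)
    r_ba = sf.lrt_group_equivalence({"b": [d2], "a": [d1]}, model)
    assert r_ab.T == pytest.approx(r_ba.T, abs=1e-6)


def test_lrt_power_exceeds_size(gp_ref, sigma_ref):
    """Groups differing in gamma by 50% are rejected more often than null groups."""
    model = SteadyStateModel()
    mu0 = sf.steady_state(gp_ref).as_array()
    gp_alt = sf.GreenspanParams(gp_ref.Q, gp_ref.Rc, 1.5 * gp_ref.gamma)
    mu1 = sf.steady_state(gp_alt).as_array()
    reject_null = reject_alt = 0
    n_rep = 40
    for k in range(n_rep):
        rng = np.random.default_rng(100 + k)
        d0 = (rng.multivariate_normal(mu0, sigma_ref, 20), sigma_ref)
        dn = (rng.multivariate_normal(mu0, sigma_ref, 20), sigma_ref)
        da = (rng.multivariate_normal(mu1, sigma_ref, 20), sigma_ref)
        reject_null += sf.lrt_group_equivalence({"a": [d0], "b": [dn]}, model).p < 0.05
        reject_alt += sf.lrt_group_equivalence({"a": [d0], "b": [da]}, model).p < 0.05
    assert reject_alt > reject_null


def test_lrt_single_parameter_vs_constrained_grid_refit(gp_ref, sigma_ref):
    """T for a single shared parameter matches a brute-force constrained refit."""
    rng = np.random.default_rng(31)
    mu = sf.steady_state(gp_ref).as_array()
    model = SteadyStateModel()
    d1 = (rng.multivariate_normal(mu, sigma_ref, 15), sigma_ref)
    d2 = (rng.multivariate_normal(mu, sigma_ref, 15), sigma_ref)
    r = sf.lrt_single_parameter({"a": [d1], "b": [d2]}, model, index=1)
    fits = [model.fit([d]) for d in (d1, d2)]
    l_alt = sum(f.loglik_hat for f in fits)
    # oracle: dense grid over the shared Rc, nuisances refit per group
    from spherofit.inference import _profile_value
    rc_grid = np.linspace(
        min(f.theta_hat[1] for f in fits) - 5, max(f.theta_hat[1] for f in fits) + 5, 161
    )
    best = -np.inf
    for rc in rc_grid:
        tot = 0.0
        for d, f in zip((d1, d2), fits):
            obj = lambda th, _d=d: model.loglik(th, _d)
            val, _ = _profile_value(obj, 1, rc, f.theta_hat[[0, 2]], model.bounds)
            tot += val
        best = max(best, tot)
    T_oracle = 2.0 * (l_alt - best)
    assert r.T == pytest.approx(T_oracle, abs=5e-3)


def test_mean_model_single_component_test_calibration(sigma_ref):
    """Shared-mean-component test on equal-mean groups rejects at about 5%."""
    model = MeanModel()
    mu = np.array([340.0, 0.9, 0.7])
    rej = 0
    n_rep = 100
    for k in range(n_rep):
        rng = np.random.default_rng(500 + k)
        d1 = (rng.multivariate_normal(mu, sigma_ref, 20), sigma_ref)
        d2 = (rng.multivariate_normal(mu, sigma_ref, 20), sigma_ref)
        rej += sf.lrt_single_parameter({"a": [d1], "b": [d2]}, model, 0).p < 0.05
    assert 0.0 <= rej / n_rep <= 0.11  # 5% +/- binomial noise at 100 replicates


# --------------------------------------------------------------------------
# confidence regions


def test_traced_region_matches_analytic_ellipse():
    Sigma = np.array([[4.0, 1.0], [1.0, 2.0]])
    Si = np.linalg.inv(Sigma)
    mu = np.array([3.0, -1.0])
    obj = lambda th: -0.5 * (th - mu) @ Si @ (th - mu)
    reg = trace_confidence_region(obj, mu, alpha=0.95)
    assert reg.closed
    thr = wilks_threshold(0.95, 2)
    # radial deviation from the exact normal-theory ellipse
    d2 = np.einsum("ni,ij,nj->n", reg.boundary_points - mu, Si, reg.boundary_points - mu)
    assert np.abs(np.sqrt(d2) - np.sqrt(2 * thr)).max() < 1e-4
    # contour constancy
    vals = np.array([obj(p) for p in reg.boundary_points])
    assert np.abs(vals - reg.loglik_level).max() < 1e-6


def test_traced_region_matches_grid_contour(mech_data, mech_fit):
    """Mechanistic (Q, Rc) region agrees with a marching-squares contour."""
    from skimage import measure

    X, S = mech_data
    model = SteadyStateModel()
    gamma_hat = mech_fit.theta_hat[2]

    def obj2(qr):
        return model.loglik(np.array([qr[0], qr[1], gamma_hat]), (X, S))

    reg = trace_confidence_region(obj2, mech_fit.theta_hat[:2], alpha=0.95)
    assert reg.closed
    vals = np.array([obj2(p) for p in reg.boundary_points])
    assert np.abs(vals - reg.loglik_level).max() < 1e-6

    b = reg.boundary_points
    q_lo, q_hi = b[:, 0].min(), b[:, 0].max()
    r_lo, r_hi = b[:, 1].min(), b[:, 1].max()
    pad_q, pad_r = 0.3 * (q_hi - q_lo), 0.3 * (r_hi - r_lo)
    nq = nr = 150
    qs = np.linspace(q_lo - pad_q, q_hi + pad_q, nq)
    rs = np.linspace(r_lo - pad_r, r_hi + pad_r, nr)
    grid = np.array([[obj2(np.array([q, r])) for r in rs] for q in qs])
    contours = measure.find_contours(grid, reg.loglik_level)
    assert len(contours) == 1
    c = contours[0]
    cq = np.interp(c[:, 0], np.arange(nq), qs)
    cr = np.interp(c[:, 1], np.arange(nr), rs)
    # every traced point lies within ~2 grid cells of the marching-squares contour
    cell = np.hypot(qs[1] - qs[0], rs[1] - rs[0])
    d = np.min(
        np.hypot(b[:, 0][:, None] - cq[None, :], b[:, 1][:, None] - cr[None, :]), axis=1
    )
    assert d.max() < 2 * cell


def test_region_slices_through_3d_space(mech_data, mech_fit):
    X, S = mech_data
    model = SteadyStateModel()
    obj3 = lambda th: model.loglik(th, (X, S))
    slices = slice_region_3d(obj3, mech_fit.theta_hat, 0.95, 5, model.bounds, slice_index=2)
    by_val = {round(s.fixed_value, 6): s for s in slices}
    mle_slice = by_val[round(float(mech_fit.theta_hat[2]), 6)]
    # slice through the MLE contains the MLE
    assert len(mle_slice.boundary_points) > 0
    b = mle_slice.boundary_points
    assert b[:, 0].min() < mech_fit.theta_hat[0] < b[:, 0].max()
    assert b[:, 1].min() < mech_fit.theta_hat[1] < b[:, 1].max()
    # far slices (grid edges) are empty: outside the joint region
    vals = sorted(by_val)
    assert len(by_val[vals[0]].boundary_points) == 0 or len(by_val[vals[-1]].boundary_points) == 0


def test_observed_information_on_quadratic():
    A = np.array([[2.0, 0.3], [0.3, 1.0]])
    obj = lambda th: -0.5 * th @ A @ th
    H = observed_information(obj, np.array([0.4, -0.2]))
    assert np.allclose(H, A, rtol=1e-5, atol=1e-6)
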