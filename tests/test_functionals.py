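"""Score/information integrals, estimators and the error decomposition."""

import numpy as np
import pytest

from wfrecomb import (
    ModelParams,
    Selection,
    SimConfig,
    Trajectory,
    error_decomposition,
    euler_maruyama,
    generic_linear_mle,
    multilocus_joint_estimator,
    multilocus_shared_estimator,
    observed_information,
    ode_solution,
    path_functionals,
    rho_hat,
    rho_mle_corrected,
    score_integral,
    selection_estimator,
    xtilde_increments,
)
from wfrecomb.model import marginals, multilocus_marginals
from wfrecomb.ode import deterministic_path_numeric

from conftest import X0_DEFAULT


def _constant_trajectory(x, n=100, dt=0.01, params=None):
    times = np.arange(n + 1) * dt
    X = np.tile(np.asarray(x, dtype=float), (n + 1, 1))
    return Trajectory(times=times, X=X, params=params, dt=dt)


def _ode_trajectory(rho, dt=1e-4, T=1.0, x0=X0_DEFAULT):
    times = np.arange(int(round(T / dt)) + 1) * dt
    X = ode_solution(x0, rho, times)
    params = ModelParams(allele_counts=(2, 2), rho=rho)
    return Trajectory(times=times, X=X, params=params, dt=dt), params


# ------------------------------------------------------------------ xtilde
def test_xtilde_without_compensation_is_raw_increment(short_trajectory):
    params0 = ModelParams(allele_counts=(2, 2))
    dxt = xtilde_increments(short_trajectory, params0)
    np.testing.assert_allclose(dxt, np.diff(short_trajectory.X, axis=0),
                               atol=1e-15)


def test_xtilde_on_constant_path_is_minus_c_dt():
    params = ModelParams(allele_counts=(2, 2), theta_A=1.0, theta_B=1.0)
    traj = _constant_trajectory(X0_DEFAULT, params=params)
    dxt = xtilde_increments(traj, params)
    np.testing.assert_allclose(dxt, -np.tile([-0.1, 0.05, 0.05, 0.0],
                                             (100, 1)) * 0.01, atol=1e-15)
    assert np.abs(dxt.sum(axis=1)).max() < 1e-15


def test_xtilde_on_deterministic_path_is_a_dt():
    traj, params = _ode_trajectory(5.0, dt=1e-4, T=0.1)
    dxt = xtilde_increments(traj, params)
    from wfrecomb.model import drift_recombination
    expected = np.stack([drift_recombination(x, 5.0, 2, 2) * 1e-4
                         for x in traj.X[:-1]])
    np.testing.assert_allclose(dxt, expected, atol=1e-7)


# ------------------------------------------------------------- information
def test_information_of_constant_paths():
    eq = np.outer([0.6, 0.4], [0.6, 0.4]).ravel()
    assert observed_information(
        _constant_trajectory(eq, params=ModelParams())) == 0.0
    traj = _constant_trajectory(X0_DEFAULT, n=100, dt=0.01,
                                params=ModelParams())
    # sum D^2/x = 0.0016/0.4 + 3 * 0.0016/0.2 = 0.028 over unit time
    assert observed_information(traj) == pytest.approx(0.028, rel=1e-12)


def test_information_two_printed_forms_agree(short_trajectory):
    a = observed_information(short_trajectory, form="direct")
    b = observed_information(short_trajectory, form="expanded")
    assert a == pytest.approx(b, abs=1e-10)


def test_information_matches_closed_form_on_ode_path():
    from wfrecomb import info_closed_form
    traj, params = _ode_trajectory(5.0, dt=1e-5, T=1.0)
    riemann = observed_information(traj, params)
    assert riemann == pytest.approx(info_closed_form(X0_DEFAULT, 5.0, 1.0),
                                    rel=1e-4)


def test_information_monotone_in_time(short_trajectory):
    params = short_trajectory.params
    n = len(short_trajectory.times)
    vals = []
    for m in (n // 4, n // 2, n):
        sub = Trajectory(times=short_trajectory.times[:m],
                         X=short_trajectory.X[:m], params=params,
                         dt=short_trajectory.dt)
        vals.append(observed_information(sub))
    assert vals[0] <= vals[1] <= vals[2]


# ------------------------------------------------------------------- score
def test_score_zero_when_increments_vanish():
    traj = _constant_trajectory(X0_DEFAULT, params=ModelParams())
    assert score_integral(traj) == 0.0


def test_score_over_information_recovers_rate_on_ode_path():
    traj, params = _ode_trajectory(5.0, dt=1e-4)
    assert rho_hat(traj, params) == pytest.approx(5.0, abs=1e-2)
    # rho=0 path is constant: zero score, hence zero raw estimate
    traj0, params0 = _ode_trajectory(0.0, dt=1e-3)
    assert rho_hat(traj0, params0) == pytest.approx(0.0, abs=1e-12)
    # a path pinned at linkage equilibrium carries no information at all
    eq = np.outer([0.6, 0.4], [0.6, 0.4]).ravel()
    with pytest.raises(ZeroDivisionError):
        rho_hat(_constant_trajectory(eq, params=ModelParams()))


def test_score_matches_bruteforce_D_form(short_trajectory):
    params = short_trajectory.params
    Y = score_integral(short_trajectory, params)
    # independent accumulation of -sum_i (D_i/X_i) dXtilde_i, step by step
    acc = 0.0
    X = short_trajectory.X
    dt = short_trajectory.dt
    from wfrecomb.model import drift_mutation, linkage_disequilibrium
    for n in range(len(X) - 1):
        x = X[n]
        D = linkage_disequilibrium(x, 2, 2)
        dxt = X[n + 1] - x - drift_mutation(x, params) * dt
        acc -= float((D / x) @ dxt)
    assert Y == pytest.approx(acc, abs=1e-12)


# ----------------------------------------------------------------- rho MLE
def test_corrected_mle_rectifies_and_flags():
    # a path estimated with the wrong sign pressure: use a reversed ODE path,
    # whose LD grows away from equilibrium so the raw estimator is negative
    traj, params = _ode_trajectory(2.0, dt=1e-3, T=1.0)
    reversed_traj = Trajectory(times=traj.times, X=traj.X[::-1],
                               params=params, dt=traj.dt)
    est = rho_mle_corrected(reversed_traj, params)
    assert est.raw < 0
    assert est.value == 0.0
    assert not est.exploded

    traj2, params2 = _ode_trajectory(2.1, dt=1e-3, T=1.0)
    est2 = rho_mle_corrected(traj2, params2)
    assert est2.value == pytest.approx(est2.raw) and est2.raw > 0


def test_truth_assigned_convention_on_exploded_path():
    params = ModelParams(allele_counts=(2, 2), theta_A=1.0, theta_B=1.0,
                         rho=1.0)
    cfg = SimConfig(dt=1e-4, T=1.0, seed=5)
    traj = euler_maruyama(params, X0_DEFAULT, cfg)
    assert traj.exploded
    est = rho_mle_corrected(traj, params, convention="truth_assigned",
                            true_rho=1.0)
    assert est.value == 1.0 and est.exploded
    est_limit = rho_mle_corrected(traj, params, convention="limit_at_S")
    assert est_limit.value >= 0.0
    assert est_limit.T_eff < 1.0
    with pytest.raises(ValueError):
        rho_mle_corrected(traj, params, convention="truth_assigned")


# ------------------------------------------------------- generic linear MLE
def test_generic_mle_reproduces_rho_hat(short_trajectory):
    params = short_trajectory.params

    def Z_fn(x):
        p, q = marginals(x, 2, 2)
        return (np.outer(p, q).ravel() - x)[:, None]

    est, pf = generic_linear_mle(
        short_trajectory, Z_fn,
        c_fn=lambda x: __import__("wfrecomb").model.drift_mutation(x, params),
        r=1)
    assert est.value == pytest.approx(rho_hat(short_trajectory, params),
                                      abs=1e-12)
    assert pf.I_T == pytest.approx(observed_information(short_trajectory),
                                   abs=1e-12)


def test_generic_mle_rejects_singular_information(short_trajectory):
    def Z_fn(x):
        p, q = marginals(x, 2, 2)
        z = (np.outer(p, q).ravel() - x)
        return np.stack([z, 2.0 * z], axis=1)  # linearly dependent columns

    with pytest.raises(np.linalg.LinAlgError, match="deficient|singular|Singular"):
        generic_linear_mle(short_trajectory, Z_fn, c_fn=lambda x: 0 * x, r=2)


def test_joint_rho_selection_information_is_diagonal(short_trajectory):
    params = short_trajectory.params

    def Z_fn(x):
        p, q = marginals(x, 2, 2)
        z_rho = np.outer(p, q).ravel() - x
        z_sel = 0.5 * x * (np.repeat([1.0, 0.0], 2) - p[0])
        return np.stack([z_rho, z_sel], axis=1)

    est, pf = generic_linear_mle(
        short_trajectory, Z_fn,
        c_fn=lambda x: __import__("wfrecomb").model.drift_mutation(
            x, params), r=2)
    I = pf.I_T
    assert abs(I[0, 1]) < 1e-12 * np.sqrt(I[0, 0] * I[1, 1])
    # components match the dedicated marginal estimators
    assert est.value[0] == pytest.approx(rho_hat(short_trajectory, params),
                                         rel=1e-10)
    sel = selection_estimator(short_trajectory, params, k=0)
    assert est.value[1] == pytest.approx(sel.value, rel=1e-10)


# --------------------------------------------------------------- selection
def test_selection_estimator_zero_on_constant_path():
    traj = _constant_trajectory(X0_DEFAULT, params=ModelParams())
    assert selection_estimator(traj, k=0).value == 0.0


def test_selection_estimator_matches_scalar_watterson_form(short_trajectory):
    # theta = 0 compensator: independent scalar implementation of
    # s_hat = 2 (p(T) - p(0)) / int p (1 - p) dt on the locus-A marginal
    params0 = ModelParams(allele_counts=(2, 2))
    est = selection_estimator(short_trajectory, params0, k=0)
    p = short_trajectory.X[:, 0] + short_trajectory.X[:, 1]
    dt = short_trajectory.dt
    scalar = 2 * (p[-1] - p[0]) / float(np.sum(p[:-1] * (1 - p[:-1])) * dt)
    assert est.value == pytest.approx(scalar, rel=1e-12)


def test_selection_estimator_undefined_at_fixation():
    x = np.array([0.6, 0.4, 0.0, 0.0])  # locus-A allele 1 fixed
    traj = _constant_trajectory(x, params=ModelParams())
    with pytest.raises(ZeroDivisionError):
        selection_estimator(traj, k=0)


# ------------------------------------------------------------- multi-locus
def test_multilocus_reduces_to_two_locus(short_trajectory):
    params = short_trajectory.params
    joint = multilocus_joint_estimator(short_trajectory, params)
    shared = multilocus_shared_estimator(short_trajectory, params)
    target = max(0.0, rho_hat(short_trajectory, params))
    assert joint.value == pytest.approx(target, rel=1e-10)
    assert shared.value == pytest.approx(target, rel=1e-10)


def test_multilocus_shared_rate_recovers_rate_on_ode_path():
    params = ModelParams(allele_counts=(2, 2, 2), rho=np.array([2.0, 2.0]))
    rng = np.random.default_rng(4)
    x0 = rng.dirichlet(np.ones(8))
    n = 2000
    times, X = deterministic_path_numeric(params, x0, 1.0, n_eval=n + 1)
    traj = Trajectory(times=times, X=X, params=params, dt=times[1])
    est = multilocus_shared_estimator(traj, params)
    assert est.value == pytest.approx(2.0, abs=0.05)
    joint = multilocus_joint_estimator(traj, params)
    np.testing.assert_allclose(joint.value, [2.0, 2.0], atol=0.1)


def test_multilocus_information_two_forms_agree():
    params = ModelParams(allele_counts=(2, 2, 2), rho=np.array([1.0, 3.0]))
    rng = np.random.default_rng(8)
    x0 = rng.dirichlet(np.ones(8))
    times, X = deterministic_path_numeric(params, x0, 0.5, n_eval=501)
    traj = Trajectory(times=times, X=X, params=params, dt=times[1])
    _, pf = generic_linear_mle(
        traj, _multilocus_Z(params), c_fn=lambda x: 0 * x, r=2)
    dt = times[1]
    # expanded form: int sum_i (prod of cut marginals)/x dt - T, per (j,k)
    I_alt = np.zeros((2, 2))
    for n in range(len(X) - 1):
        x = X[n]
        Zs = []
        for j in (1, 2):
            pre, suf = multilocus_marginals(x, (2, 2, 2), j)
            Zs.append(pre * suf)
        for a in range(2):
            for b in range(2):
                I_alt[a, b] += float(np.sum(Zs[a] * Zs[b] / x)) * dt
    I_alt -= dt * (len(X) - 1)
    np.testing.assert_allclose(pf.I_T, I_alt, rtol=1e-8, atol=1e-12)


def _multilocus_Z(params):
    from wfrecomb.functionals import _multilocus_Z as _mz
    return _mz(params)


# ------------------------------------------------------ error decomposition
def test_error_decomposition_zero_noise():
    params = ModelParams(allele_counts=(2, 2), rho=5.0)
    cfg = SimConfig(dt=1e-3, T=0.5, store_brownian=True)
    n = 500
    traj = euler_maruyama(params, X0_DEFAULT, cfg, noise=np.zeros((n, 4)))
    traj.dW = np.zeros((n, 4))
    N_T, pred = error_decomposition(traj, params, 5.0)
    assert N_T == 0.0 and pred == 0.0


def test_error_decomposition_identity_is_exact(short_trajectory):
    params = short_trajectory.params
    N_T, pred = error_decomposition(short_trajectory, params, params.rho)
    raw = rho_hat(short_trajectory, params)
    assert (raw - params.rho) == pytest.approx(pred, abs=1e-10)


def test_martingale_quadratic_variation_approximates_information():
    params = ModelParams(allele_counts=(2, 2), theta_A=5.0, theta_B=5.0,
                         rho=5.0)
    cfg = SimConfig(dt=1e-4, T=1.0, seed=17, store_brownian=True)
    traj = euler_maruyama(params, X0_DEFAULT, cfg)
    from wfrecomb.model import linkage_disequilibrium, sigma_pal_dot
    m = traj.pre_explosion_length()
    incs = []
    for n in range(m - 1):
        x = traj.X[n]
        D = linkage_disequilibrium(x, 2, 2)
        incs.append(float((D / x) @ sigma_pal_dot(x, traj.dW[n])))
    qv = float(np.sum(np.square(incs)))
    I = observed_information(traj, params)
    assert qv == pytest.approx(I, rel=0.15)


# ------------------------------------------------------------ log-likelihood
def test_loglikelihood_concave_with_maximizer_at_raw(short_trajectory):
    pf = path_functionals(short_trajectory)
    raw = pf.Y / pf.I_T
    assert pf.loglik(raw) >= pf.loglik(raw + 0.5)
    assert pf.loglik(raw) >= pf.loglik(raw - 0.5)
    assert pf.loglik(raw) == pytest.approx(0.5 * pf.Y ** 2 / pf.I_T)


# ------------------------------------------------- confounder invariances
def test_additive_selection_in_compensator_leaves_rho_unchanged(
        short_trajectory):
    base = short_trajectory.params
    sel = Selection(s_A=np.array([[0.0, 0.4], [0.4, 0.8]]),
                    s_B=np.array([[0.1, 0.0], [0.0, -0.3]]))
    with_sel = ModelParams(allele_counts=(2, 2), theta_A=base.theta_A,
                           theta_B=base.theta_B, rho=base.rho, selection=sel)
    r0 = rho_hat(short_trajectory, base)
    r1 = rho_hat(short_trajectory, with_sel)
    assert r1 == pytest.approx(r0, rel=1e-10)
    assert observed_information(short_trajectory, with_sel) == pytest.approx(
        observed_information(short_trajectory, base), rel=1e-12)


def test_recombination_in_compensator_leaves_selection_unchanged(
        short_trajectory):
    from wfrecomb.model import drift_mutation, drift_recombination
    params = short_trajectory.params

    def Z_fn(x):
        p, _ = marginals(x, 2, 2)
        return (0.5 * x * (np.repeat([1.0, 0.0], 2) - p[0]))[:, None]

    est_plain, _ = generic_linear_mle(
        short_trajectory, Z_fn,
        c_fn=lambda x: drift_mutation(x, params), r=1)
    est_rec, _ = generic_linear_mle(
        short_trajectory, Z_fn,
        c_fn=lambda x: drift_mutation(x, params)
        + drift_recombination(x, 7.0, 2, 2), r=1)
    assert est_rec.value == pytest.approx(est_plain.value, rel=1e-10)
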