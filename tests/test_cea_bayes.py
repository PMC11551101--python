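import numpy as np
import pytest
import scipy.stats as st

from beamcea.cea_bayes import (
    CeaModelConfig,
    CeaPosterior,
    ce_plane,
    ceac,
    fit_cea,
    icer,
    net_benefit,
    summarize,
)
from beamcea.trial_data import ValidationError


def _gamma_trial(rng, n_per_arm, mean_cost, mean_one_minus_qaly, shape_c=2.0, shape_e=10.0):
    """Synthetic (cost, qaly, arm, baselines) tuple from the model family."""
    costs, qalys, arms = [], [], []
    for arm in ("intervention", "control"):
        c = rng.gamma(shape_c, mean_cost[arm] / shape_c, n_per_arm)
        e = rng.gamma(shape_e, mean_one_minus_qaly[arm] / shape_e, n_per_arm)
        costs.append(c)
        qalys.append(1.0 - e)
        arms += [arm] * n_per_arm
    costs = np.concatenate(costs)
    qalys = np.concatenate(qalys)
    n = 2 * n_per_arm
    base_cost = rng.gamma(2.0, 1850 / 2.0, n)
    base_util = np.minimum(rng.normal(0.70, 0.2, n), 1.0)
    return costs, qalys, np.array(arms), base_cost, base_util


def _quick_config(**kw):
    defaults = dict(burn_in=800, kept=800, chains=2, seed=0)
    defaults.update(kw)
    return CeaModelConfig(**defaults)


# ---------------------------------------------------------------------------
# fit_cea


def test_fit_requires_valid_inputs():
    rng = np.random.default_rng(0)
    c, q, a, bc, bu = _gamma_trial(rng, 20, {"intervention": 100, "control": 100},
                                   {"intervention": 0.7, "control": 0.7})
    with pytest.raises(ValidationError, match="horizon"):
        fit_cea(c, np.full_like(q, 1.2), a, bc, bu, _quick_config())
    with pytest.raises(ValidationError, match="arms"):
        fit_cea(c, q, np.array(["intervention"] * len(a)), bc, bu, _quick_config())
    with pytest.raises(ValidationError, match="length"):
        fit_cea(c[:-1], q, a, bc, bu, _quick_config())
    with pytest.raises(ValidationError):
        _quick_config(burn_in=0).validate()


def test_fit_seeded_reproducibility():
    rng = np.random.default_rng(1)
    data = _gamma_trial(rng, 100, {"intervention": 1900, "control": 2000},
                        {"intervention": 0.67, "control": 0.70})
    cfg = _quick_config(seed=42, burn_in=300, kept=300)
    p1 = fit_cea(*data, cfg)
    p2 = fit_cea(*data, cfg)
    np.testing.assert_array_equal(p1.delta_cost, p2.delta_cost)
    np.testing.assert_array_equal(p1.delta_qaly, p2.delta_qaly)
    s1, s2 = summarize(p1), summarize(p2)
    assert s1.mean_cost_saving == s2.mean_cost_saving
    assert s1.icer.value == s2.icer.value


def test_fit_draw_counts_and_diagnostics():
    rng = np.random.default_rng(2)
    data = _gamma_trial(rng, 80, {"intervention": 1900, "control": 2000},
                        {"intervention": 0.67, "control": 0.70})
    cfg = _quick_config(chains=2, burn_in=400, kept=500)
    post = fit_cea(*data, cfg)
    assert len(post) == 2 * 500
    assert set(post.rhat) == set(post.ess)
    assert np.all(np.isfinite(post.delta_cost))
    assert np.all(np.isfinite(post.delta_qaly))


def test_fit_parameter_recovery():
    """True increments: cost -100, QALY +0.03 (n=2000/arm)."""
    rng = np.random.default_rng(7)
    data = _gamma_trial(
        rng, 2000,
        {"intervention": 1900.0, "control": 2000.0},
        {"intervention": 0.67, "control": 0.70},  # QALYs 0.33 vs 0.30
    )
    post = fit_cea(*data, _quick_config(burn_in=1500, kept=1500, seed=3))
    dc_mean, dc_sd = post.delta_cost.mean(), post.delta_cost.std()
    dq_mean, dq_sd = post.delta_qaly.mean(), post.delta_qaly.std()
    assert abs(dc_mean - (-100.0)) < 3 * dc_sd
    assert abs(dq_mean - 0.03) < 3 * dq_sd


def test_fit_null_calibration():
    """Identical arms: 95% CrIs cover 0 in >= 90% of 50 seeded replicates."""
    cover_cost = cover_qaly = 0
    n_rep = 50
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        data = _gamma_trial(rng, 500, {"intervention": 2000.0, "control": 2000.0},
                            {"intervention": 0.70, "control": 0.70})
        post = fit_cea(*data, CeaModelConfig(burn_in=400, kept=400, chains=1, seed=rep))
        lo, hi = np.percentile(post.delta_cost, [2.5, 97.5])
        cover_cost += lo <= 0 <= hi
        lo, hi = np.percentile(post.delta_qaly, [2.5, 97.5])
        cover_qaly += lo <= 0 <= hi
    assert cover_cost >= 0.9 * n_rep
    assert cover_qaly >= 0.9 * n_rep


def test_fit_normal_limit_matches_sample_means():
    """Large Gamma shape, no covariate effects: posterior increments track
    the frequentist mean differences within 2 Monte-Carlo SEs (20 replicates)."""
    devs_c, devs_q = [], []
    for rep in range(20):
        rng = np.random.default_rng(500 + rep)
        c, q, a, bc, bu = _gamma_trial(
            rng, 200, {"intervention": 1950.0, "control": 2000.0},
            {"intervention": 0.68, "control": 0.70},
            shape_c=500.0, shape_e=500.0,
        )
        post = fit_cea(c, q, a, bc, bu, CeaModelConfig(burn_in=400, kept=400, chains=1, seed=rep))
        ki = a == "intervention"
        freq_dc = c[ki].mean() - c[~ki].mean()
        freq_dq = q[ki].mean() - q[~ki].mean()
        devs_c.append((post.delta_cost.mean() - freq_dc) / post.delta_cost.std())
        devs_q.append((post.delta_qaly.mean() - freq_dq) / post.delta_qaly.std())
    # standardized deviations should average near 0
    assert abs(np.mean(devs_c)) < 2 / np.sqrt(20) * np.std(devs_c, ddof=1) + 0.5
    assert abs(np.mean(devs_q)) < 2 / np.sqrt(20) * np.std(devs_q, ddof=1) + 0.5


def test_fit_zero_cost_offset():
    rng = np.random.default_rng(11)
    c, q, a, bc, bu = _gamma_trial(rng, 50, {"intervention": 100.0, "control": 100.0},
                                   {"intervention": 0.7, "control": 0.7})
    c[0] = 0.0
    post = fit_cea(c, q, a, bc, bu, _quick_config(burn_in=100, kept=100))
    assert np.all(np.isfinite(post.delta_cost))


def test_ceac_matches_bootstrap_oracle():
    """Bayesian CEAC within +/-0.05 of a nonparametric bootstrap CEAC."""
    rng = np.random.default_rng(13)
    c, q, a, bc, bu = _gamma_trial(rng, 500, {"intervention": 1900.0, "control": 2000.0},
                                   {"intervention": 0.67, "control": 0.70})
    post = fit_cea(c, q, a, bc, bu, _quick_config(burn_in=1000, kept=1000, seed=5))
    ki = a == "intervention"
    n_boot = 2000
    idx_i = rng.integers(0, ki.sum(), (n_boot, ki.sum()))
    idx_c = rng.integers(0, (~ki).sum(), (n_boot, (~ki).sum()))
    dc_boot = c[ki][idx_i].mean(axis=1) - c[~ki][idx_c].mean(axis=1)
    dq_boot = q[ki][idx_i].mean(axis=1) - q[~ki][idx_c].mean(axis=1)
    boot = CeaPosterior.from_deltas(dc_boot, dq_boot)
    for wtp in (0.0, 10000.0, 20000.0, 30000.0, 50000.0):
        p_bayes = ceac(post, [wtp]).points[0][1]
        p_boot = ceac(boot, [wtp]).points[0][1]
        assert abs(p_bayes - p_boot) <= 0.05, (wtp, p_bayes, p_boot)


# ---------------------------------------------------------------------------
# ICER


def test_icer_base_case_value():
    res = icer(-93.03, 0.027)
    assert round(res.value, 2) == 3445.56
    assert res.dominant
    assert res.label == "dominant"


def test_icer_complete_case_value():
    assert round(icer(-273.60, 0.026).value, 2) == 10523.08


def test_icer_zero_numerator():
    assert icer(0.0, 0.01).value == 0.0


def test_icer_zero_delta_qaly_rejected():
    with pytest.raises(ZeroDivisionError):
        icer(100.0, 0.0)


def test_icer_labels():
    assert icer(100.0, 0.02).label == "tradeoff"
    assert icer(100.0, -0.02).label == "dominated"


# ---------------------------------------------------------------------------
# CEAC / net benefit


def test_ceac_dominant_draws():
    post = CeaPosterior.from_deltas(np.full(100, -50.0), np.full(100, 0.01))
    curve = ceac(post, [0.0, 20000.0, 30000.0])
    assert all(p == 1.0 for _, p in curve.points)


def test_ceac_at_zero_wtp_is_cost_saving_fraction():
    rng = np.random.default_rng(3)
    dc = rng.normal(0, 100, 10000)
    post = CeaPosterior.from_deltas(dc, np.zeros_like(dc) + 0.01)
    p0 = ceac(post, [0.0]).points[0][1]
    assert p0 == pytest.approx(np.mean(dc < 0))


def test_ceac_gaussian_closed_form_oracle():
    rng = np.random.default_rng(4)
    n = 400_000
    dq = rng.normal(0.027, 0.0069, n)
    dc = rng.normal(-93.0, 248.0, n)
    post = CeaPosterior.from_deltas(dc, dq)
    lam = 20000.0
    expected = st.norm.cdf((lam * 0.027 + 93.0) / np.hypot(lam * 0.0069, 248.0))
    p = ceac(post, [lam]).points[0][1]
    assert p == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / n) + 1e-4)


def test_ceac_monotone_when_all_gains_positive():
    rng = np.random.default_rng(5)
    post = CeaPosterior.from_deltas(rng.normal(0, 100, 5000), np.abs(rng.normal(0.02, 0.01, 5000)))
    probs = [p for _, p in ceac(post, [0, 5000, 10000, 20000, 50000, 1e7]).points]
    assert probs == sorted(probs)
    assert probs[-1] == pytest.approx(np.mean(post.delta_qaly > 0))


def test_net_benefit_at_zero_equals_cost_saving():
    rng = np.random.default_rng(6)
    dc = rng.normal(-93, 50, 2000)
    post = CeaPosterior.from_deltas(dc, rng.normal(0.03, 0.01, 2000))
    nb = net_benefit(post, 0.0)
    assert nb.mean == pytest.approx(-dc.mean())


def test_net_benefit_zero_effect_line():
    dc = np.array([10.0, -20.0, 30.0] * 50)
    post = CeaPosterior.from_deltas(dc, np.zeros_like(dc))
    for wtp in (0.0, 20000.0):
        nb = net_benefit(post, wtp)
        assert nb.mean == pytest.approx(-dc.mean())


def test_net_benefit_gaussian_oracle():
    rng = np.random.default_rng(8)
    n = 200_000
    dq = rng.normal(0.027, 0.0069, n)
    dc = rng.normal(-93.0, 248.0, n)
    post = CeaPosterior.from_deltas(dc, dq)
    lam = 20000.0
    nb = net_benefit(post, lam)
    mean_exp = lam * 0.027 + 93.0
    sd_exp = np.hypot(lam * 0.0069, 248.0)
    assert nb.mean == pytest.approx(mean_exp, abs=4 * sd_exp / np.sqrt(n))
    assert nb.sd == pytest.approx(sd_exp, rel=0.02)


# ---------------------------------------------------------------------------
# CE plane


def test_ce_plane_degenerate_cloud():
    post = CeaPosterior.from_deltas(np.full(200, -50.0), np.full(200, 0.02))
    plane = ce_plane(post)
    assert plane.center == (pytest.approx(0.02), pytest.approx(-50.0))
    assert plane.quadrant_proportions["SE_cost_saving_more_effective"] == 1.0


def test_ce_plane_gaussian_coverage():
    rng = np.random.default_rng(9)
    n = 100_000
    dq = rng.standard_normal(n)
    dc = rng.standard_normal(n)
    post = CeaPosterior.from_deltas(dc, dq)
    plane = ce_plane(post)
    evals = np.linalg.eigvalsh(plane.covariance)
    assert evals[0] == pytest.approx(evals[1], rel=0.05)  # isotropic
    inv = np.linalg.inv(plane.covariance)
    pts = np.stack([dq - plane.center[0], dc - plane.center[1]])
    d2 = np.einsum("in,ij,jn->n", pts, inv, pts)
    inside = np.mean(d2 <= st.chi2.ppf(0.95, 2))
    assert inside == pytest.approx(0.95, abs=0.005)


def test_ce_plane_needs_enough_draws():
    post = CeaPosterior.from_deltas(np.zeros(10), np.zeros(10))
    with pytest.raises(ValidationError):
        ce_plane(post)


def test_summarize_icer_consistency():
    rng = np.random.default_rng(10)
    post = CeaPosterior.from_deltas(rng.normal(-93, 100, 5000), rng.normal(0.03, 0.005, 5000))
    s = summarize(post)
    expected = icer(float(post.delta_cost.mean()), float(post.delta_qaly.mean()))
    assert s.icer.value == expected.value
    assert s.mean_cost_saving == pytest.approx(-post.delta_cost.mean())
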