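"""OLS/2SLS primitives and instrument-strength diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import mrmediate as mm
from mrmediate.estimators import DegenerateFitError, UnderIdentifiedError


def test_ols_exact_line():
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 2.0, 4.0]})
    fit = mm.ols(df, "y", ["x"])
    assert fit.params["x"] == pytest.approx(2.0, abs=1e-12)
    assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)


def test_ols_rank_deficiency():
    df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
    with pytest.raises(DegenerateFitError):
        mm.ols(df, "y", ["x"])  # constant column duplicates the intercept


def test_tsls_just_identified_ratio_identity(confounded_ds):
    """Just-identified 2SLS equals cov(Y,G)/cov(X,G) to machine precision."""
    d = confounded_ds.data
    ratio = np.cov(d["y"], d["iv_x"])[0, 1] / np.cov(d["x"], d["iv_x"])[0, 1]
    fit = mm.tsls(confounded_ds, "y", ["x"], ["iv_x"], diagnostics=False)
    assert fit.params["x"] == pytest.approx(ratio, abs=1e-12)


def test_tsls_equals_ols_when_exposure_is_instrument():
    cfg = mm.ScenarioConfig(n=1000, gamma_x=1.0, noise_sds=mm.NoiseSDs(x=0.0), seed=6)
    ds = mm.simulate(cfg)
    assert np.allclose(ds.data["x"], ds.data["iv_x"])
    iv = mm.tsls(ds, "y", ["x"], ["iv_x"], diagnostics=False)
    ls = mm.ols(ds, "y", ["x"])
    assert iv.params["x"] == pytest.approx(ls.params["x"], abs=1e-10)


def test_tsls_matches_statsmodels_iv2sls(confounded_config):
    """Cross-check coefficients and SEs against the statsmodels IV oracle."""
    from statsmodels.sandbox.regression.gmm import IV2SLS

    cfg = dataclasses.replace(confounded_config, n=1500, instrument_mode="snps", n_snps=4)
    ds = mm.simulate(cfg, seed=9)
    inst = ds.roles.instruments["x"] + ds.roles.instruments["m1"]
    ours = mm.tsls(ds, "y", ["x", "m1"], inst, diagnostics=False)
    n = ds.n
    exog = np.column_stack([np.ones(n), ds.data[["x", "m1"]]])
    instr = np.column_stack([np.ones(n), ds.data[inst]])
    ref = IV2SLS(ds.data["y"].to_numpy(), exog, instrument=instr).fit()
    assert ours.params["x"] == pytest.approx(ref.params[1], rel=1e-8)
    assert ours.params["m1"] == pytest.approx(ref.params[2], rel=1e-8)
    assert ours.bse["x"] == pytest.approx(ref.bse[1], rel=1e-6)
    assert ours.bse["m1"] == pytest.approx(ref.bse[2], rel=1e-6)


def test_tsls_invariant_to_instrument_recoding(confounded_config):
    """Estimates are unchanged under invertible linear recoding of instruments."""
    cfg = dataclasses.replace(confounded_config, n=800, instrument_mode="snps", n_snps=5)
    ds = mm.simulate(cfg, seed=11)
    inst = ds.roles.instruments["x"] + ds.roles.instruments["m1"]
    base = mm.tsls(ds, "y", ["x", "m1"], inst, diagnostics=False)
    rng = np.random.default_rng(0)
    amat = rng.standard_normal((len(inst), len(inst))) + 3 * np.eye(len(inst))
    recoded = ds.data.copy()
    recoded[inst] = recoded[inst].to_numpy() @ amat + rng.standard_normal(len(inst))
    ds2 = mm.IndividualDataset(recoded, ds.roles)
    other = mm.tsls(ds2, "y", ["x", "m1"], inst, diagnostics=False)
    assert other.params["x"] == pytest.approx(base.params["x"], abs=1e-8)
    assert other.params["m1"] == pytest.approx(base.params["m1"], abs=1e-8)


def test_tsls_underidentified(confounded_ds):
    with pytest.raises(UnderIdentifiedError):
        mm.tsls(confounded_ds, "y", ["x", "m1"], ["iv_x"])


def test_duplicated_instrument_rank_error(confounded_ds):
    with pytest.raises(DegenerateFitError):
        mm.tsls(confounded_ds, "y", ["x"], ["iv_x", "iv_x"], diagnostics=False)


def test_first_stage_f_null_expectation():
    """Irrelevant instrument: F fluctuates around its null expectation of 1."""
    cfg = mm.ScenarioConfig(n=2000, gamma_x=0.0)
    fs = [
        mm.first_stage_F(mm.simulate(cfg, seed=(201, rep)), "x", ["iv_x"])
        for rep in range(300)
    ]
    assert np.mean(fs) == pytest.approx(1.0, abs=0.35)


def test_first_stage_f_calibration():
    """gamma chosen for E[F] = 30 gives mean simulated F within 10% of 30."""
    n = 2000
    gamma = mm.gamma_for_target_f(30.0, n, residual_var=1.0)
    cfg = mm.ScenarioConfig(n=n, gamma_x=gamma, noise_sds=mm.NoiseSDs(x=1.0))
    fs = [
        mm.first_stage_F(mm.simulate(cfg, seed=(202, rep)), "x", ["iv_x"])
        for rep in range(500)
    ]
    assert abs(np.mean(fs) - 30.0) < 3.0


def test_conditional_f_orthogonal_case():
    """Independent exposures with disjoint instruments: conditional F ~ marginal F."""
    cfg = mm.ScenarioConfig(n=20_000, a_paths=[0.0], b_paths=[0.5], seed=13)
    ds = mm.simulate(cfg)
    marginal = mm.first_stage_F(ds, "x", ["iv_x"])
    conditional = mm.conditional_F_sw(ds, ["x", "m1"], ["iv_x", "iv_m1"], "x")
    assert conditional == pytest.approx(marginal, rel=0.10)


def test_conditional_f_collapses_with_shared_scores(confounded_ds):
    """Near-identical instrument scores leave no conditional strength."""
    df = confounded_ds.data.copy()
    rng = np.random.default_rng(1)
    df["iv_m1"] = df["iv_x"] + 0.05 * rng.standard_normal(len(df))
    ds = mm.IndividualDataset(df, confounded_ds.roles)
    marginal = mm.first_stage_F(ds, "x", ["iv_x", "iv_m1"])
    conditional = mm.conditional_F_sw(ds, ["x", "m1"], ["iv_x", "iv_m1"], "x")
    assert marginal > 100
    assert conditional < 10


def test_conditional_f_requires_two_exposures(confounded_ds):
    with pytest.raises(ValueError, match="two"):
        mm.conditional_F_sw(confounded_ds, ["x"], ["iv_x"], "x")


def test_logistic_no_variation():
    df = pd.DataFrame({"x": np.arange(50.0), "y": np.zeros(50)})
    with pytest.raises(DegenerateFitError, match="variation"):
        mm.logistic_fit(df, "y", ["x"])


def test_logistic_consistency():
    """Direct ML logistic fit recovers the generating log-odds coefficients."""
    cfg = mm.ScenarioConfig(
        n=100_000, outcome_type="binary", prevalence=0.25, seed=14,
        noise_sds=mm.NoiseSDs(y=0.0),  # pure logistic model, no extra latent noise
    )
    ds = mm.simulate(cfg)
    fit = mm.logistic_fit(ds, "y", ["x", "m1"])
    assert abs(fit.params["x"] - cfg.c_prime) < 4 * fit.bse["x"]
    assert abs(fit.params["m1"] - cfg.b_paths[0]) < 4 * fit.bse["m1"]


def test_tsls_se_matches_empirical_sd(confounded_config):
    """Reported IV SEs track the sampling SD in a strong-instrument scenario."""
    cfg = dataclasses.replace(confounded_config, n=2000)
    est, ses = [], []
    for rep in range(1000):
        ds = mm.simulate(cfg, seed=(203, rep))
        fit = mm.tsls(ds, "y", ["x"], ["iv_x"], diagnostics=False)
        est.append(fit.params["x"])
        ses.append(fit.bse["x"])
    assert np.mean(ses) == pytest.approx(np.std(est, ddof=1), rel=0.15)


def test_risk_difference_equals_linear_tsls():
    """2SLS on a binary outcome IS linear 2SLS treating Y as numeric."""
    cfg = mm.ScenarioConfig(n=3000, outcome_type="binary", prevalence=0.25, seed=15)
    ds = mm.simulate(cfg)
    rd = mm.tsls(ds, "y", ["x"], ["iv_x"], diagnostics=False)
    numeric = ds.data.assign(y=ds.data["y"].astype(float))
    lin = mm.tsls(numeric, "y", ["x"], ["iv_x"], diagnostics=False)
    assert rd.params["x"] == lin.params["x"]
    assert rd.scale == "risk-difference"


def test_estimator_consistency_with_sample_size(confounded_config):
    """Bias shrinks with n: MR toward the truth, OLS toward its probability limit."""
    gamma = mm.gamma_for_target_f(5.0, 2000, residual_var=1.25, n_instruments=10)
    weak = dataclasses.replace(
        confounded_config, instrument_mode="snps", gamma_x=gamma
    )
    truth = mm.true_effects(weak)
    plim_w = mm.plim_noniv_oracle(weak, "y", ["x"])["x"]

    def run(cfg, n, reps, seed0):
        cfg = dataclasses.replace(cfg, n=n)
        iv, ls = [], []
        for rep in range(reps):
            ds = mm.simulate(cfg, seed=(seed0, rep))
            inst = ds.roles.instruments["x"]
            iv.append(mm.tsls(ds, "y", ["x"], inst, diagnostics=False).params["x"])
            ls.append(mm.ols(ds, "y", ["x"]).params["x"])
        return np.asarray(iv), np.asarray(ls)

    iv_small, ls_small = run(weak, 2000, 500, 204)
    iv_big, ls_big = run(weak, 50_000, 200, 205)
    # over-identified weak-instrument bias shrinks as instruments strengthen with n
    assert abs(iv_big.mean() - truth.total) < abs(iv_small.mean() - truth.total)
    assert abs(iv_small.mean() - truth.total) > 3 * iv_small.std(ddof=1) / np.sqrt(500)
    # OLS converges to its (confounded) plim, with shrinking spread
    # (the weak first stage leaves OLS bias essentially unchanged)
    for ls_est, reps in ((ls_small, 500), (ls_big, 200)):
        assert abs(ls_est.mean() - plim_w) < 3 * ls_est.std(ddof=1) / np.sqrt(reps)
    assert ls_big.std(ddof=1) < ls_small.std(ddof=1) / 3
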