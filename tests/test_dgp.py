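"""Simulator, path-traced truths and the covariance-algebra plim oracle."""

import dataclasses

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import mrmediate as mm
from mrmediate.dgp import OUTCOME_BINARY


def test_simulate_recovers_unconfounded_coefficients():
    """Without any bias mechanism, OLS of Y on X and M recovers (c', b)."""
    cfg = mm.ScenarioConfig(n=200_000, a_paths=[0.4], b_paths=[0.5], c_prime=0.3, seed=10)
    ds = mm.simulate(cfg)
    fit = mm.ols(ds, "y", ["x", "m1"])
    assert abs(fit.params["x"] - 0.3) < 3 * fit.bse["x"]
    assert abs(fit.params["m1"] - 0.5) < 3 * fit.bse["m1"]


@pytest.mark.parametrize("prevalence", [0.05, 0.25])
def test_binary_prevalence_calibration(prevalence):
    cfg = mm.ScenarioConfig(
        n=100_000, outcome_type="binary", prevalence=prevalence, seed=5,
        confounder=mm.ConfounderLoadings(0.5, 0.5, 0.5),
    )
    ds = mm.simulate(cfg)
    assert abs(ds.data["y"].mean() - prevalence) < 0.005
    assert set(np.unique(ds.data["y"])) <= {0.0, 1.0}


def test_seeded_determinism(confounded_config):
    cfg = dataclasses.replace(confounded_config, n=500)
    assert mm.simulate(cfg, seed=42).to_csv() == mm.simulate(cfg, seed=42).to_csv()
    assert mm.simulate(cfg, seed=42).to_csv() != mm.simulate(cfg, seed=43).to_csv()


def _path_enumeration_oracle(cfg):
    """Independent truth: enumerate every directed X->...->Y path in the DAG."""
    g = nx.DiGraph()
    names = cfg.mediator_names()
    for name, a in zip(names, cfg.a_paths):
        g.add_edge("x", name, w=a)
    for name, b in zip(names, cfg.b_paths):
        g.add_edge(name, "y", w=b)
    for src, dst, eff in cfg.mediator_chain:
        g.add_edge(src, dst, w=eff)
    g.add_edge("x", "y", w=cfg.c_prime)
    total = 0.0
    for path in nx.all_simple_paths(g, "x", "y"):
        prod = 1.0
        for u, v in zip(path, path[1:]):
            prod *= g.edges[u, v]["w"]
        total += prod
    return total


def test_true_effects_single_mediator():
    te = mm.true_effects(mm.ScenarioConfig(a_paths=[0.4], b_paths=[0.5], c_prime=0.3))
    assert te.total == pytest.approx(0.5)
    assert te.indirect == pytest.approx(0.2)
    assert te.proportion_mediated == pytest.approx(0.4)


def test_true_effects_broken_path():
    te = mm.true_effects(mm.ScenarioConfig(a_paths=[0.0], b_paths=[0.7], c_prime=0.2))
    assert te.indirect == 0.0
    assert te.proportion_mediated == 0.0


def test_true_effects_chain(chain_config):
    te = mm.true_effects(chain_config)
    assert te.total == pytest.approx(0.5)
    assert te.indirect == pytest.approx(0.205)  # frozen from path enumeration
    assert te.total == pytest.approx(_path_enumeration_oracle(chain_config))
    # M3's indirect effect includes the M2 -> M3 route
    assert te.indirect_per_mediator["m3"] == pytest.approx((0.1 + 0.3 * 0.2) * 0.5)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    a=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    b=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    c_prime=st.floats(-1, 1),
    e12=st.floats(-1, 1),
    e13=st.floats(-1, 1),
    e23=st.floats(-1, 1),
)
def test_true_effects_matches_path_enumeration(a, b, c_prime, e12, e13, e23):
    """Path tracing equals brute-force path enumeration on any mediator DAG."""
    cfg = mm.ScenarioConfig(
        a_paths=a, b_paths=b, c_prime=c_prime,
        mediator_chain=[("m1", "m2", e12), ("m1", "m3", e13), ("m2", "m3", e23)],
    )
    te = mm.true_effects(cfg)
    assert te.total == pytest.approx(_path_enumeration_oracle(cfg), rel=1e-9, abs=1e-12)
    assert te.total == te.direct + te.indirect  # additivity, exact by construction
    assert te.indirect == sum(te.indirect_per_mediator.values())


def test_true_effects_rejects_interaction():
    cfg = mm.ScenarioConfig(interaction_theta=0.5)
    with pytest.raises(ValueError, match="interaction"):
        mm.true_effects(cfg)


def test_plim_oracle_closed_form():
    """X = G + U + eps, Y = 0.5X + U + eps: plim slope = 2.5/3."""
    cfg = mm.ScenarioConfig(
        gamma_x=1.0, a_paths=[0.0], b_paths=[0.0], c_prime=0.5,
        confounder=mm.ConfounderLoadings(x=1.0, m=0.0, y=1.0),
    )
    plim = mm.plim_noniv_oracle(cfg, "y", ["x"])
    assert plim["x"] == pytest.approx(2.5 / 3)


def test_plim_oracle_unconfounded_equals_structural():
    cfg = mm.ScenarioConfig(a_paths=[0.4], b_paths=[0.5], c_prime=0.3)
    plim = mm.plim_noniv_oracle(cfg, "y", ["x", "m1"])
    assert plim["x"] == pytest.approx(0.3)
    assert plim["m1"] == pytest.approx(0.5)


def test_plim_oracle_matches_monte_carlo(confounded_config):
    reps = 200
    coefs = []
    for rep in range(reps):
        ds = mm.simulate(confounded_config, seed=(101, rep))
        fit = mm.ols(ds, "y", ["x", "m1"])
        coefs.append([fit.params["x"], fit.params["m1"]])
    coefs = np.asarray(coefs)
    plim = mm.plim_noniv_oracle(confounded_config, "y", ["x", "m1"])
    for i, name in enumerate(["x", "m1"]):
        se = coefs[:, i].std(ddof=1) / np.sqrt(reps)
        assert abs(coefs[:, i].mean() - plim[name]) < 3 * se


def test_plim_oracle_singular_regressors(confounded_config):
    with pytest.raises(np.linalg.LinAlgError):
        mm.plim_noniv_oracle(confounded_config, "y", ["x", "x"])


def test_instrument_uncorrelated_with_confounder(confounded_config):
    """Without pleiotropy the instrument is a valid IV by construction."""
    cfg = dataclasses.replace(confounded_config, n=20_000)
    ds = mm.simulate(cfg, seed=8, keep_latent_confounders=True)
    r = np.corrcoef(ds.data["iv_x"], ds.data["_u"])[0, 1]
    assert abs(r) < 4 / np.sqrt(cfg.n)


def test_rd_scale_factor_matches_sample_derivative():
    """k = E[p(1-p)] from quadrature agrees with its sample analogue."""
    cfg = mm.ScenarioConfig(
        n=200_000, outcome_type="binary", prevalence=0.25, seed=12,
        confounder=mm.ConfounderLoadings(0.5, 0.5, 0.5),
    )
    from scipy.special import expit

    b0, k = mm.binary_link_stats(cfg)
    assert 0 < k < 0.25
    # prevalence implied by (b0, population eta variance) matches the target
    cov = mm.model_covariance(cfg)
    z = np.random.default_rng(0).standard_normal(400_000) * np.sqrt(cov.loc["y", "y"])
    assert abs(expit(b0 + z).mean() - cfg.prevalence) < 0.002


# --- configuration validation ------------------------------------------------

@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(a_paths=[0.4, 0.2], b_paths=[0.5]), "equal length"),
        (dict(n=1), "n must be"),
        (dict(outcome_type="binary", prevalence=1.5), "prevalence"),
        (dict(outcome_type="count"), "outcome_type"),
        (dict(noise_sds=mm.NoiseSDs(x=-1.0)), "noise SDs"),
        (dict(me_exposure_sd=-0.1), "me_exposure_sd"),
        (
            dict(
                a_paths=[0.1, 0.1], b_paths=[0.1, 0.1],
                mediator_chain=[("m1", "m2", 0.2), ("m2", "m1", 0.2)],
            ),
            "cyclic",
        ),
        (dict(mediator_chain=[("m1", "m7", 0.2)]), "undeclared"),
    ],
)
def test_config_validation(kwargs, match):
    with pytest.raises(ValueError, match=match):
        mm.ScenarioConfig(**kwargs)


def test_config_yaml_roundtrip(chain_config):
    cfg = dataclasses.replace(
        chain_config, me_mediator_sd=[0.1, 0.0, 0.2], gamma_m=[1.0, 0.5, 0.8],
        instrument_mode="snps", x_mean=0.3,
    )
    again = mm.ScenarioConfig.from_yaml(cfg.to_yaml())
    assert again == cfg


def test_snp_mode_instruments():
    cfg = mm.ScenarioConfig(n=3000, instrument_mode="snps", n_snps=6, maf=0.3, seed=4)
    ds = mm.simulate(cfg)
    assert ds.roles.instruments["x"] == [f"iv_x_{i}" for i in range(1, 7)]
    dos = ds.data[ds.roles.instruments["x"]].to_numpy()
    assert set(np.unique(dos)) <= {0.0, 1.0, 2.0}
    # estimators run unchanged on dosage panels
    fit = mm.tsls(ds, "y", ["x"], ds.roles.instruments["x"], diagnostics=False)
    assert np.isfinite(fit.params["x"])


def test_dataset_csv_roundtrip(tmp_path, confounded_config):
    cfg = dataclasses.replace(confounded_config, n=300, me_mediator_sd=0.5)
    ds = mm.simulate(cfg, seed=2)
    path = tmp_path / "data.csv"
    ds.to_csv(path)
    back = mm.IndividualDataset.from_csv(path)
    assert back.roles == ds.roles
    assert back.latent == {"m1": "m1_latent"}
    assert np.allclose(back.data.to_numpy(), ds.data.to_numpy())


def test_dataset_validation_errors(confounded_ds):
    # dropping the mediator column leaves its instrument set orphaned
    df = confounded_ds.data.drop(columns=["m1"])
    with pytest.raises(ValueError, match="no role"):
        mm.IndividualDataset.from_dataframe(df)
    bad = mm.IndividualDataset(
        confounded_ds.data,
        dataclasses.replace(confounded_ds.roles, outcome_type=OUTCOME_BINARY),
    )
    with pytest.raises(ValueError, match="binary outcome"):
        bad.validate()
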