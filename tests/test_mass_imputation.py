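"""Latent-class mixture fitting and the mass-imputation identities."""

import numpy as np
import pytest

from volecmr.mass_imputation import (
    LatentClassModel,
    bic_weights,
    class_session_means,
    fit_latent_classes,
    impute_mass,
)
from volecmr.capture_data import SEXES
from volecmr.experiments import class_recovery_accuracy
from volecmr.synthetic import default_config, simulate


@pytest.fixture(scope="module")
def sim_data():
    cfg = default_config(n0_treatment=30, n0_control=30, recruits_per_interval=10)
    data, _ = simulate(cfg, seed=11)
    return data


def test_single_class_reduces_to_sample_means(sim_data):
    m = fit_latent_classes(sim_data, 1, n_restarts=1, seed=0)
    assert np.allclose(m.posterior, 1.0)
    assert m.mixing[0] == pytest.approx(1.0)
    obs = np.isfinite(sim_data.observed_mass)
    for s, sex in enumerate(SEXES):
        sel = sim_data.sex == sex
        for t in range(sim_data.design.n_sessions):
            col = sim_data.observed_mass[sel, t]
            col = col[np.isfinite(col)]
            if col.size:
                assert m.means[0, s, t] == pytest.approx(col.mean(), abs=1e-8)


def test_more_classes_never_fit_worse(sim_data):
    m1 = fit_latent_classes(sim_data, 1, n_restarts=1, seed=0)
    m3 = fit_latent_classes(sim_data, 3, n_restarts=3, seed=0)
    assert m3.loglik >= m1.loglik - 1e-6


def test_posterior_rows_sum_to_one(sim_data):
    m = fit_latent_classes(sim_data, 3, n_restarts=2, seed=1)
    np.testing.assert_allclose(m.posterior.sum(axis=1), 1.0, atol=1e-9)
    assert np.isfinite(m.bic)


def test_well_separated_classes_recovered():
    res = class_recovery_accuracy(seed=4)
    assert res["accuracy"] >= 0.95


def test_bic_weights_formula():
    def mk(bic):
        return LatentClassModel(
            n_classes=1, mixing=np.ones(1), means=np.zeros((1, 2, 1)),
            resid_sd=np.ones(1), posterior=np.ones((1, 1)), loglik=0.0,
            bic=bic, n_parameters=1, n_restarts=1, seed=0, converged=True, n_iter=1,
        )

    assert bic_weights([mk(10.0)])[0] == pytest.approx(1.0)
    np.testing.assert_allclose(bic_weights([mk(5.0), mk(5.0)]), [0.5, 0.5])
    w = bic_weights([mk(0.0), mk(2.0)])
    assert w[0] == pytest.approx(0.731, abs=5e-4)
    assert w[1] == pytest.approx(0.269, abs=5e-4)
    assert w.sum() == pytest.approx(1.0)


def test_class_means_hand_example(tiny_design):
    """Three voles, masses (20, 24, 30), class-1 probs (0.5, 0.25, 0.25):
    weighted mean = (10 + 6 + 7.5) / 1 = 23.5."""
    from volecmr.capture_data import EncounterData

    data = EncounterData(
        design=tiny_design,
        ids=["a", "b", "c"],
        sex=np.array(["F", "F", "F"]),
        location=np.array(["Barwik"] * 3, dtype="U32"),
        plot_role=np.array(["control"] * 3, dtype="U16"),
        cohort=np.array([""] * 3, dtype="U32"),
        encounters=np.array([[1, 0, 0, 0]] * 3, dtype=np.int8),
        observed_mass=np.array([[20.0, np.nan], [24.0, np.nan], [30.0, np.nan]]),
    )
    post = np.array([[0.5, 0.5], [0.25, 0.75], [0.25, 0.75]])
    model = LatentClassModel(
        n_classes=2, mixing=post.mean(axis=0), means=np.zeros((2, 2, 2)),
        resid_sd=np.ones(2), posterior=post, loglik=0.0, bic=0.0,
        n_parameters=1, n_restarts=1, seed=0, converged=True, n_iter=1,
    )
    mbar = class_session_means(model, data)
    assert mbar[0, 0, 0] == pytest.approx(23.5)
    # equal weights reduce to the unweighted mean
    post_eq = np.full((3, 2), 0.5)
    model_eq = LatentClassModel(
        n_classes=2, mixing=np.array([0.5, 0.5]), means=np.zeros((2, 2, 2)),
        resid_sd=np.ones(2), posterior=post_eq, loglik=0.0, bic=0.0,
        n_parameters=1, n_restarts=1, seed=0, converged=True, n_iter=1,
    )
    mbar_eq = class_session_means(model_eq, data)
    assert mbar_eq[0, 0, 0] == pytest.approx(np.mean([20, 24, 30]))
    assert mbar_eq[1, 0, 0] == pytest.approx(np.mean([20, 24, 30]))


def test_imputation_zero_mean_residual_and_single_capture_passthrough(sim_data):
    models = [fit_latent_classes(sim_data, k, n_restarts=2, seed=3) for k in (2, 3)]
    w = bic_weights(models)
    imputed = impute_mass(models, w, sim_data)
    assert np.isfinite(imputed).all()
    obs = np.isfinite(sim_data.observed_mass)
    resid = np.where(obs, sim_data.observed_mass - imputed, 0.0)
    np.testing.assert_allclose(resid.sum(axis=1) / obs.sum(axis=1), 0.0, atol=1e-9)
    # individuals captured exactly once: imputed equals observed there
    single = obs.sum(axis=1) == 1
    t_idx = np.argmax(obs[single], axis=1)
    rows = np.flatnonzero(single)
    for i, t in zip(rows, t_idx):
        assert imputed[i, t] == pytest.approx(sim_data.observed_mass[i, t], abs=1e-9)


def test_duplicate_model_splits_weight_leaves_imputation_unchanged(sim_data):
    m = fit_latent_classes(sim_data, 2, n_restarts=2, seed=5)
    one = impute_mass([m], np.array([1.0]), sim_data)
    two = impute_mass([m, m], np.array([0.5, 0.5]), sim_data)
    np.testing.assert_allclose(one, two, atol=1e-12)
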