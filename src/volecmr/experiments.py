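"""Simulation studies: oracles, recovery checks, and calibrations.

Everything here evaluates the estimators against generators with known
truth.  The likelihood oracles are written independently of the model
module's forward recursion: one enumerates every latent state sequence
outright, the other derives the temporary-emigration-free case from the
classic survival/recapture recursion, so agreement is evidence, not
tautology.  The study designs used here are scaled to desk-size runs
(tens of seconds per study) while keeping the generating rates at the
field study's magnitudes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import expit, logit
from scipy.stats import pearsonr

from .capture_data import EncounterData
from .cmr_model import DesignMatrices, ModelSpec, build_design, fit, negloglik, population_size
from .gof import parametric_bootstrap
from .mass_imputation import bic_weights, fit_latent_classes, impute_mass
from .model_selection import model_average, rank_models, relative_survival
from .synthetic import default_config, default_design, simulate

__all__ = [
    "brute_force_negloglik",
    "cjs_negloglik",
    "likelihood_oracle_max_error",
    "survival_recovery",
    "abundance_recovery",
    "imputation_check",
    "class_recovery_accuracy",
    "gof_calibration",
    "relative_survival_recovery",
    "null_relative_survival_pvalues",
]


# ---------------------------------------------------------------------------
# independent likelihood oracles


def brute_force_negloglik(beta, dm: DesignMatrices) -> float:
    """Exhaustive enumeration over {available, unavailable, dead} paths.

    Tractable only for tiny instances; serves as the ground-truth value
    of the conditional likelihood.
    """
    S, p, gamma = dm.real_params(beta)
    design = dm.design
    T = design.n_sessions
    phi = S ** dm.interval_exponent[None, :] if T > 1 else np.empty((S.shape[0], 0))
    x = dm.encounters
    total = 0.0
    for i in range(x.shape[0]):
        f = int(dm.first_session[i])
        lik_first = 1.0
        for o in np.flatnonzero(dm.after_first_mask[i]):
            lik_first *= p[i, o] if x[i, o] else 1.0 - p[i, o]

        def emission(state, t):
            sl = design.session_slice(t)
            seen = x[i, sl].any()
            if state == "A":
                e = 1.0
                for o in range(sl.start, sl.stop):
                    e *= p[i, o] if x[i, o] else 1.0 - p[i, o]
                return e
            return 0.0 if seen else 1.0

        def transition(a, b, j):
            ph = phi[i, j]
            if a == "D":
                return 1.0 if b == "D" else 0.0
            if b == "A":
                return ph * (1.0 - gamma)
            if b == "U":
                return ph * gamma
            return 1.0 - ph

        later = list(range(f + 1, T))
        lik = 0.0
        if not later:
            lik = 1.0
        else:
            for states in itertools.product("AUD", repeat=len(later)):
                prob = 1.0
                prev = "A"
                for t, st in zip(later, states):
                    prob *= transition(prev, st, t - 1) * emission(st, t)
                    prev = st
                    if prob == 0.0:
                        break
                lik += prob
        total += -math.log(max(lik_first * lik, 1e-300))
    return total


def cjs_negloglik(beta, dm: DesignMatrices) -> float:
    """Two-state (alive/dead) conditional likelihood, no emigration.

    Uses the classic closed form: the product of survival and detection
    terms up to the last capture, times the probability of never being
    seen again ('chi'), computed by backward recursion.  Valid as an
    oracle for the full model when gamma = 0.
    """
    S, p, _ = dm.real_params(beta)
    design = dm.design
    T = design.n_sessions
    phi = S ** dm.interval_exponent[None, :] if T > 1 else np.empty((S.shape[0], 0))
    x = dm.encounters
    total = 0.0
    for i in range(x.shape[0]):
        f = int(dm.first_session[i])
        lik = 1.0
        for o in np.flatnonzero(dm.after_first_mask[i]):
            lik *= p[i, o] if x[i, o] else 1.0 - p[i, o]

        def detect(t):
            sl = design.session_slice(t)
            e = 1.0
            for o in range(sl.start, sl.stop):
                e *= p[i, o] if x[i, o] else 1.0 - p[i, o]
            return e

        def nodetect(t):
            sl = design.session_slice(t)
            e = 1.0
            for o in range(sl.start, sl.stop):
                e *= 1.0 - p[i, o]
            return e

        seen = [t for t in range(T) if x[i, design.session_slice(t)].any()]
        last = max(seen)
        for t in range(f + 1, last + 1):
            lik *= phi[i, t - 1] * detect(t)
        chi = 1.0
        for t in range(T - 1, last, -1):
            chi = (1.0 - phi[i, t - 1]) + phi[i, t - 1] * nodetect(t) * chi
        lik *= chi
        total += -math.log(max(lik, 1e-300))
    return total


def _single_history_data(hist: np.ndarray, design) -> EncounterData:
    n = hist.shape[0] if hist.ndim == 2 else 1
    hist = np.atleast_2d(hist)
    mass = np.full((n, design.n_sessions), np.nan)
    cap = np.zeros((n, design.n_sessions), dtype=bool)
    for t in range(design.n_sessions):
        cap[:, t] = hist[:, design.session_slice(t)].any(axis=1)
    mass[cap] = 25.0
    return EncounterData(
        design=design,
        ids=[f"i{j}" for j in range(n)],
        sex=np.array(["F", "M"] * n)[:n],
        location=np.array(["Barwik"] * n, dtype="U32"),
        plot_role=np.array(["control"] * n, dtype="U16"),
        cohort=np.array([""] * n, dtype="U32"),
        encounters=hist,
        observed_mass=mass,
    )


def likelihood_oracle_max_error(seed: int = 0) -> dict:
    """Max |forward recursion - enumeration| over all tiny instances.

    Covers every non-empty individual history for 2-3 sessions of 2-3
    occasions, at several random coefficient vectors (the likelihood is a
    sum over individuals, so single-history instances are exhaustive),
    plus multi-individual spot instances with a sex effect on capture.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for T, K in [(2, 2), (2, 3), (3, 2), (3, 3)]:
        design = default_design(n_sessions=T, n_occasions=K, interval_days=45)
        n_occ = T * K
        betas = [rng.uniform(-1.5, 1.5, 3) for _ in range(3)]
        hists = [
            np.array(bits, dtype=np.int8)
            for bits in itertools.product((0, 1), repeat=n_occ)
            if any(bits)
        ]
        for hist in hists:
            data = _single_history_data(hist, design)
            dm = build_design(ModelSpec(), data, None, design)
            for beta in betas:
                a = negloglik(beta, dm)
                b = brute_force_negloglik(beta, dm)
                worst = max(worst, abs(a - b))
                n_checked += 1
        # 4-individual instances with a sex effect on p
        for _ in range(5):
            take = rng.choice(len(hists), size=4, replace=False)
            data = _single_history_data(np.stack([hists[j] for j in take]), design)
            spec = ModelSpec(capture_terms=("sex",))
            dm = build_design(spec, data, None, design)
            beta = rng.uniform(-1.0, 1.0, dm.n_params)
            a = negloglik(beta, dm)
            b = brute_force_negloglik(beta, dm)
            worst = max(worst, abs(a - b))
            n_checked += 1
    return {"max_abs_error": worst, "n_instances": n_checked}


# ---------------------------------------------------------------------------
# generating configurations


def flat_config(
    s_monthly: float = 0.8,
    p_occasion: float = 0.4,
    gamma: float = 0.1,
    treatment_ratio: float = 1.0,
    **overrides,
):
    """A homogeneous-rate scenario: no location, time, mass or day effects.

    ``treatment_ratio`` is the generating ratio of treatment to control
    monthly survival; the control plots run at ``s_monthly``.
    """
    s_treat = min(s_monthly * treatment_ratio, 0.995)
    return default_config(
        survival_intercept=float(logit(s_monthly)),
        treatment_effect=float(logit(s_treat) - logit(s_monthly)),
        location_effects={},
        time_effects=(),
        mass_slope=0.0,
        capture_intercept=float(logit(p_occasion)),
        capture_location_effects={},
        capture_day_slope=0.0,
        gamma=gamma,
        **overrides,
    )


# ---------------------------------------------------------------------------
# recovery and calibration studies


def survival_recovery(n_datasets: int = 50, seed: int = 1) -> dict:
    """Wald-CI coverage and bias for monthly survival at study scale.

    Simulates homogeneous datasets (S_monthly = 0.8, p = 0.4,
    gamma = 0.1; 3 locations x 2 plots, 7 sessions of 5 days, ~70
    animals per plot) and fits the matching intercept-only model.
    """
    truth = 0.8
    cfg = flat_config(n0_treatment=70, n0_control=70)
    covered, est = [], []
    for r in range(n_datasets):
        data, _ = simulate(cfg, seed=seed * 100003 + r)
        m = fit(ModelSpec(), data, None, cfg.design)
        b0, se = m.beta[0], np.sqrt(max(m.vcov[0, 0], 0.0))
        lo, hi = expit(b0 - 1.96 * se), expit(b0 + 1.96 * se)
        covered.append(lo <= truth <= hi)
        est.append(float(expit(b0)))
    est = np.asarray(est)
    return {
        "coverage": float(np.mean(covered)),
        "median_abs_bias": float(np.median(np.abs(est - truth))),
        "estimates": est,
        "truth": truth,
        "n_datasets": n_datasets,
    }


def abundance_recovery(n_replicates: int = 50, seed: int = 2) -> dict:
    """Relative bias of Horvitz-Thompson abundance at p* ~ 0.8.

    Per-occasion p = 0.275 over 5 days gives per-session detection
    ~0.80.  Truth is the number of animals alive and available per
    session; the estimate uses fitted capture probabilities.
    """
    cfg = flat_config(p_occasion=0.275, n0_treatment=70, n0_control=70)
    design = cfg.design
    rel = []
    min_margin = np.inf
    for r in range(n_replicates):
        data, truth = simulate(cfg, seed=seed * 200003 + r)
        m = fit(ModelSpec(), data, None, design, compute_vcov=False)
        dm = build_design(ModelSpec(), data, None, design)
        _, p, _ = dm.real_params(m.beta)
        ab = truth.abundance()
        for t in range(design.n_sessions):
            n_hat = float(population_size(p, data, t))
            n_true = int(ab.loc[ab["session"] == t + 1, "n_true"].sum())
            n_obs = int(data.captured_by_session()[:, t].sum())
            rel.append((n_hat - n_true) / n_true)
            min_margin = min(min_margin, n_hat - n_obs)
    return {
        "relative_bias": float(np.mean(rel)),
        "min_estimate_minus_count": float(min_margin),
        "n_replicates": n_replicates,
    }


def imputation_check(seed: int = 3, n_restarts: int = 3) -> dict:
    """Observed-vs-imputed mass correlation on the default scenario.

    Fits 3- and 4-class trajectory mixtures, BIC-averages, imputes, and
    correlates imputed with observed mass at captured sessions.
    """
    cfg = default_config()
    data, _ = simulate(cfg, seed=seed)
    models = [
        fit_latent_classes(data, k, n_restarts=n_restarts, seed=seed + k)
        for k in (3, 4)
    ]
    w = bic_weights(models)
    imputed = impute_mass(models, w, data)
    obs = np.isfinite(data.observed_mass)
    r, _ = pearsonr(data.observed_mass[obs], imputed[obs])
    return {"pearson_r": float(r), "n_observations": int(obs.sum()), "weights": w}


def class_recovery_accuracy(seed: int = 4) -> dict:
    """Modal-class accuracy for two well-separated trajectory classes.

    Class labels are arbitrary, and with sex-specific mean cells the
    likelihood is invariant to permuting labels within each sex, so
    accuracy is scored under the best label permutation per sex -- the
    alignment the imputation step actually consumes.
    """
    cfg = default_config(
        class_proportions=(0.5, 0.5),
        class_curves=((18.0,) * 7, (35.0,) * 7),
        sex_mass_effect=0.0,
        individual_mass_sd=0.5,
        residual_mass_sd=1.0,
    )
    data, truth = simulate(cfg, seed=seed)
    model = fit_latent_classes(data, 2, n_restarts=3, seed=seed)
    modal = model.modal_class()
    true_cls = truth.true_class[truth.captured_mask]
    n_correct = 0
    for s in ("F", "M"):
        sel = data.sex == s
        n_correct += max(
            int(np.sum(modal[sel] == true_cls[sel])),
            int(np.sum(modal[sel] == 1 - true_cls[sel])),
        )
    return {"accuracy": n_correct / data.n_individuals, "n_individuals": data.n_individuals}


def _small_gof_config(**overrides):
    design = default_design(n_sessions=5, n_occasions=3, interval_days=61)
    return flat_config(
        design=design,
        n0_treatment=35,
        n0_control=35,
        recruits_per_interval=15,
        **overrides,
    )


def gof_calibration(n_runs: int = 10, n_boot: int = 50, seed: int = 5) -> dict:
    """c-hat calibration of the bootstrap GOF under a well-specified model."""
    cfg = _small_gof_config()
    chats, pvals = [], []
    for r in range(n_runs):
        data, _ = simulate(cfg, seed=seed * 300007 + r)
        m = fit(ModelSpec(), data, None, cfg.design, compute_vcov=False)
        res = parametric_bootstrap(
            m, data, None, cfg.design, n_boot=n_boot, seed=seed * 17 + r
        )
        chats.append(res.c_hat)
        pvals.append(res.p)
    chats = np.asarray(chats)
    return {
        "c_hats": chats,
        "p_values": np.asarray(pvals),
        "frac_in_band": float(np.mean((chats >= 0.85) & (chats <= 1.15))),
        "n_runs": n_runs,
        "n_boot": n_boot,
    }


def gof_misspecification(n_runs: int = 5, n_boot: int = 40, seed: int = 6) -> dict:
    """c-hat under strong unmodelled two-point heterogeneity in capture."""
    design = default_design(n_sessions=4, n_occasions=5, interval_days=61)
    cfg = flat_config(
        design=design,
        n0_treatment=50,
        n0_control=50,
        recruits_per_interval=20,
        capture_mixture_delta=2.0,
    )
    chats = []
    for r in range(n_runs):
        data, _ = simulate(cfg, seed=seed * 400009 + r)
        m = fit(ModelSpec(), data, None, cfg.design, compute_vcov=False)
        res = parametric_bootstrap(
            m, data, None, cfg.design, n_boot=n_boot, seed=seed * 19 + r
        )
        chats.append(res.c_hat)
    return {"c_hats": np.asarray(chats), "mean_c_hat": float(np.mean(chats))}


def _treatment_ratio_draws(model, betas, dm):
    """Paired (treatment, control) monthly-survival draws at interval 1."""
    row_c = dm.survival_row("Barwik", False, min(1, dm.Xs.shape[1] - 1), 25.0)
    row_t = dm.survival_row("Barwik", True, min(1, dm.Xs.shape[1] - 1), 25.0)
    s_c = expit(betas[:, : dm.ks] @ row_c)
    s_t = expit(betas[:, : dm.ks] @ row_t)
    return s_t, s_c


def relative_survival_recovery(
    n_replicates: int = 50, seed: int = 7, treatment_ratio: float = 1.25, n_draws: int = 1000
) -> dict:
    """CI coverage for the treatment/control survival ratio.

    The generator sets control monthly survival ``treatment_ratio`` times
    below treatment (default: control 20% below, ratio 1.25); two
    candidate models containing the treatment effect are averaged.
    """
    cfg = flat_config(
        s_monthly=0.72,
        treatment_ratio=treatment_ratio,
        n0_treatment=70,
        n0_control=70,
        design=default_design(n_sessions=5, n_occasions=5, interval_days=61),
    )
    specs = [
        ModelSpec(survival_terms=("treatment",)),
        ModelSpec(survival_terms=("treatment", "sex")),
    ]
    covered, points, pvals = [], [], []
    for r in range(n_replicates):
        data, _ = simulate(cfg, seed=seed * 500009 + r)
        fits = [fit(s, data, None, cfg.design) for s in specs]
        ranked = rank_models(fits, screen=False)
        dms = {
            id(m): build_design(m.spec, data, None, cfg.design) for m in ranked.models
        }

        def q(model, betas):
            s_t, s_c = _treatment_ratio_draws(model, betas, dms[id(model)])
            return np.stack([s_t, s_c], axis=1)

        pred = model_average(ranked, q, n_draws=n_draws, seed=seed + r)
        ratio = relative_survival(pred.draws[:, 0], pred.draws[:, 1])
        covered.append(ratio.ci_low <= treatment_ratio <= ratio.ci_high)
        points.append(float(ratio.point))
        pvals.append(float(ratio.p))
    return {
        "coverage": float(np.mean(covered)),
        "mean_ratio": float(np.mean(points)),
        "p_values": np.asarray(pvals),
        "true_ratio": treatment_ratio,
        "n_replicates": n_replicates,
    }


def null_relative_survival_pvalues(n_replicates: int = 20, seed: int = 8) -> np.ndarray:
    """p-values for the survival ratio when the true treatment effect is 0."""
    out = relative_survival_recovery(
        n_replicates=n_replicates, seed=seed, treatment_ratio=1.0
    )
    return out["p_values"]
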