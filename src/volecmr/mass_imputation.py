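"""Latent-class body-mass trajectories and covariate imputation.

The capture-recapture model needs a body mass for every individual at
every session, but mass is only observed when an animal is caught.  Field
trajectories follow a small number of temporal patterns (e.g. stable
small animals, heavy overwintering adults, fast spring growers), so we
fit a finite Gaussian mixture over sex x session mean trajectories by EM:
each class g has a mean mass per sex and session and a residual standard
deviation, and each individual carries a posterior probability
P(c_i = g) of membership in each class.

Imputation then proceeds in two steps.  First the class-and-sex mean mass
per session is computed as a posterior-probability-weighted mean over the
individuals caught in that session,

    mbar_{g,s,t} = sum_i m_{i,t} P(c_i = g) / sum_i P(c_i = g),

and BIC-averaged across candidate models (3- and 4-class fits by
default).  Second, each individual's expected curve
sum_g mbar_{g,s_i,t} P(c_i = g) is shifted by the mean difference between
its observed masses and that curve at the sessions where it was caught,
so the imputed series passes through a single observation exactly and has
zero mean residual at captured sessions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capture_data import SEXES, EncounterData

__all__ = [
    "LatentClassModel",
    "fit_latent_classes",
    "bic_weights",
    "class_session_means",
    "impute_mass",
    "load_imputed_mass",
]


def load_imputed_mass(path, data: EncounterData) -> np.ndarray:
    """Read an imputed-mass CSV (id-indexed, one column per session),
    aligned to the row order of ``data``."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.loc[data.ids].to_numpy(dtype=float)


@dataclass
class LatentClassModel:
    """A fitted finite mixture of sex x session mass trajectories."""

    n_classes: int
    mixing: np.ndarray            # (K,)
    means: np.ndarray             # (K, n_sex, T); NaN where no data
    resid_sd: np.ndarray          # (K,)
    posterior: np.ndarray         # (n_individuals, K): P(c_i = g)
    loglik: float
    bic: float
    n_parameters: int
    n_restarts: int
    seed: int
    converged: bool
    n_iter: int

    def modal_class(self) -> np.ndarray:
        return self.posterior.argmax(axis=1)


def _observed_arrays(data: EncounterData):
    """Masses, observation mask, and sex index (0=F, 1=M)."""
    mass = data.observed_mass
    obs = np.isfinite(mass)
    if not obs.any(axis=1).all():
        raise ValueError("every individual needs at least one mass observation")
    sex_idx = (data.sex == "M").astype(int)
    return mass, obs, sex_idx


def _loglik_by_class(mass, obs, sex_idx, means, resid_sd):
    """(n, K) log-likelihood of each individual's observed masses per class."""
    n, T = mass.shape
    K = means.shape[0]
    out = np.zeros((n, K))
    m = np.where(obs, mass, 0.0)
    for g in range(K):
        mu = means[g, sex_idx, :]          # (n, T)
        mu = np.where(np.isfinite(mu), mu, 0.0)
        resid2 = np.where(obs, (m - mu) ** 2, 0.0).sum(axis=1)
        k = obs.sum(axis=1)
        s2 = resid_sd[g] ** 2
        out[:, g] = -0.5 * (k * np.log(2.0 * np.pi * s2) + resid2 / s2)
    return out


def _m_step(mass, obs, sex_idx, post, min_sd=0.05):
    n, T = mass.shape
    K = post.shape[1]
    n_sex = len(SEXES)
    means = np.full((K, n_sex, T), np.nan)
    resid_sd = np.empty(K)
    m = np.where(obs, mass, 0.0)
    for g in range(K):
        w = post[:, g]
        sse, cnt = 0.0, 0.0
        for s in range(n_sex):
            sel = sex_idx == s
            wobs = (w[sel, None] * obs[sel])    # (n_s, T)
            denom = wobs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                mu = (wobs * m[sel]).sum(axis=0) / denom
            means[g, s] = np.where(denom > 1e-12, mu, np.nan)
            mu0 = np.where(np.isfinite(mu), mu, 0.0)
            sse += (wobs * (m[sel] - mu0) ** 2).sum()
            cnt += wobs.sum()
        resid_sd[g] = max(np.sqrt(sse / max(cnt, 1e-12)), min_sd)
    mixing = post.mean(axis=0)
    return mixing, means, resid_sd


def fit_latent_classes(
    data: EncounterData,
    n_classes: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LatentClassModel:
    """Fit a K-class Gaussian mixture of mass trajectories by EM.

    The best of ``n_restarts`` random initializations (by log-likelihood)
    is returned.  The EM log-likelihood is non-decreasing across
    iterations; convergence is declared when its relative change drops
    below ``tol``.  BIC is ``-2 lnL + k ln(n_individuals)`` where k counts
    mixing proportions, residual sds, and the estimated mean cells.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    mass, obs, sex_idx = _observed_arrays(data)
    n, T = mass.shape
    K = n_classes
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(n_restarts, 1)):
        # initialize posteriors from a random soft assignment
        post = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
        loglik_prev = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            mixing, means, resid_sd = _m_step(mass, obs, sex_idx, post)
            if K > 1 and (mixing < 1e-10).any():
                # empty class: reseed its posteriors and continue
                gdead = np.flatnonzero(mixing < 1e-10)
                for g in gdead:
                    take = rng.choice(n, size=max(n // (K * 4), 2), replace=False)
                    post[take] = 0.0
                    post[take, g] = 1.0
                post /= post.sum(axis=1, keepdims=True)
                mixing, means, resid_sd = _m_step(mass, obs, sex_idx, post)
            ll_ic = _loglik_by_class(mass, obs, sex_idx, means, resid_sd)
            logw = ll_ic + np.log(np.maximum(mixing, 1e-300))
            mx = logw.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logw - mx).sum(axis=1))
            loglik = float(lse.sum())
            post = np.exp(logw - lse[:, None])
            if loglik - loglik_prev < tol * (abs(loglik_prev) + 1.0) and it > 1:
                converged = True
                break
            loglik_prev = loglik
        mixing, means, resid_sd = _m_step(mass, obs, sex_idx, post)
        if best is None or loglik > best[0]:
            best = (loglik, mixing, means, resid_sd, post, converged, it)

    loglik, mixing, means, resid_sd, post, converged, n_iter = best
    k_par = (K - 1) + K + int(np.isfinite(means).sum())
    bic = -2.0 * loglik + k_par * np.log(n)
    return LatentClassModel(
        n_classes=K,
        mixing=mixing,
        means=means,
        resid_sd=resid_sd,
        posterior=post,
        loglik=loglik,
        bic=bic,
        n_parameters=k_par,
        n_restarts=n_restarts,
        seed=seed,
        converged=converged,
        n_iter=n_iter,
    )


def bic_weights(models: list[LatentClassModel]) -> np.ndarray:
    """Evidence weights exp(-dBIC/2), normalized to sum to 1."""
    if not models:
        raise ValueError("need at least one model")
    bic = np.array([m.bic for m in models], dtype=float)
    d = bic - bic.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def class_session_means(model: LatentClassModel, data: EncounterData) -> np.ndarray:
    """Posterior-weighted mean mass per (class, sex, session).

    A cell with no captured individual of that sex in that session is
    filled by linear interpolation (edge extension) across sessions within
    the (class, sex) series.
    """
    mass, obs, sex_idx = _observed_arrays(data)
    n, T = mass.shape
    K = model.n_classes
    out = np.full((K, len(SEXES), T), np.nan)
    m = np.where(obs, mass, 0.0)
    for g in range(K):
        pg = model.posterior[:, g]
        for s in range(len(SEXES)):
            sel = sex_idx == s
            wobs = pg[sel, None] * obs[sel]
            denom = wobs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                mu = (wobs * m[sel]).sum(axis=0) / denom
            series = np.where(denom > 1e-12, mu, np.nan)
            out[g, s] = _interpolate_nan(series)
    return out


def _interpolate_nan(series: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN gaps, constant extension at the ends."""
    series = series.astype(float).copy()
    good = np.isfinite(series)
    if not good.any():
        return series
    x = np.arange(series.size)
    series[~good] = np.interp(x[~good], x[good], series[good])
    return series


def impute_mass(
    models: list[LatentClassModel],
    weights: np.ndarray,
    data: EncounterData,
) -> np.ndarray:
    """Complete mass matrix (n_individuals, n_sessions), in grams.

    The baseline is the class-probability-weighted mean curve, averaged
    over models by their BIC weights; each individual's curve is then
    offset by the mean difference (observed - baseline) at its captured
    sessions, so the mean residual at captured sessions is exactly zero.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("model weights must sum to 1")
    mass, obs, sex_idx = _observed_arrays(data)
    n, T = mass.shape

    base = np.zeros((n, T))
    for model, w in zip(models, weights):
        mbar = class_session_means(model, data)       # (K, n_sex, T)
        curves = mbar[:, sex_idx, :]                  # (K, n, T)
        base += w * np.einsum("nk,knt->nt", model.posterior, curves)

    m = np.where(obs, mass, 0.0)
    cnt = obs.sum(axis=1)
    offset = np.where(obs, m - base, 0.0).sum(axis=1) / cnt
    return base + offset[:, None]
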