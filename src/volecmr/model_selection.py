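"""Candidate sets, AICc ranking, and simulation-based model averaging.

Candidate models are all marginality-respecting subsets of a term pool
(an interaction never appears without its lower-order margins), expanded
over the allowed time forms and capped at 11 terms per component.
Models are ranked by the small-sample Akaike criterion

    AICc = -2 lnL + 2k + 2k(k+1) / (n_eff - k - 1),

with the number of individuals as effective sample size (the individual
is the exchangeable unit under per-individual conditioning).  Models
whose parameters are inestimable or at a boundary are screened out
before ranking; models with Akaike weight > 0.001 are retained.

Averaged predictions are built by simulation: each retained model
contributes multivariate-Gaussian draws of beta (at the MLE and its
covariance) in proportion to its weight; a derived quantity is evaluated
per draw and the pooled draws give the point estimate (mean), 95%
percentile interval, and a p-value against a null value (twice the
fraction of draws on the null's side of the mean at least as far from
the mean as the null is).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .cmr_model import (
    CAPTURE_POOL,
    MANDATORY_CAPTURE,
    MANDATORY_SURVIVAL,
    MAX_TERMS,
    SURVIVAL_POOL,
    FittedModel,
    ModelSpec,
)

__all__ = [
    "generate_candidates",
    "aicc",
    "akaike_weights",
    "RankedModelSet",
    "rank_models",
    "AveragedPrediction",
    "model_average",
    "pvalue",
    "relative_survival",
]

# desk-scale defaults: the treatment structure that the study's question
# turns on, over a compact time-form grid
REDUCED_SURVIVAL_OPTIONAL = ("treatment", "treatment:time", "treatment:mass")
REDUCED_CAPTURE_OPTIONAL = ("day",)
REDUCED_SURVIVAL_FORMS = ("categorical", "spline-3")
REDUCED_CAPTURE_FORMS = ("spline-3",)


def _marginality_closure(terms: frozenset[str]) -> frozenset[str]:
    """Add every lower-order margin of every interaction."""
    out = set(terms)
    for t in terms:
        parts = t.split(":")
        for r in range(1, len(parts)):
            for sub in itertools.combinations(parts, r):
                out.add(":".join(sub))
    return frozenset(out)


def _order_terms(terms: frozenset[str], pool: tuple[str, ...]) -> tuple[str, ...]:
    rank = {t: i for i, t in enumerate(pool)}
    return tuple(sorted(terms, key=lambda t: (rank.get(t, len(rank)), t)))


def generate_candidates(
    survival_optional: tuple[str, ...] = REDUCED_SURVIVAL_OPTIONAL,
    capture_optional: tuple[str, ...] = REDUCED_CAPTURE_OPTIONAL,
    survival_mandatory: tuple[str, ...] = MANDATORY_SURVIVAL,
    capture_mandatory: tuple[str, ...] = MANDATORY_CAPTURE,
    survival_time_forms: tuple[str, ...] = REDUCED_SURVIVAL_FORMS,
    capture_time_forms: tuple[str, ...] = REDUCED_CAPTURE_FORMS,
    max_terms: int = MAX_TERMS,
    full_pools: bool = False,
) -> list[ModelSpec]:
    """Enumerate candidate :class:`ModelSpec` objects, deterministically.

    With ``full_pools=True`` the optional pools are the entire term pools
    of the model module (minus mandatory terms) over all four time forms
    -- the study-scale candidate set; the defaults are a reduced pool for
    desk-scale runs.
    """
    if full_pools:
        survival_optional = tuple(t for t in SURVIVAL_POOL if t not in survival_mandatory)
        capture_optional = tuple(t for t in CAPTURE_POOL if t not in capture_mandatory)
        from .cmr_model import TIME_FORMS

        survival_time_forms = TIME_FORMS
        capture_time_forms = ("categorical", "spline-3", "spline-4")
    if not (survival_mandatory or survival_optional) or not (
        capture_mandatory or capture_optional
    ):
        raise ValueError("empty term pool")

    def component_sets(mandatory, optional):
        seen = set()
        out = []
        for r in range(len(optional) + 1):
            for combo in itertools.combinations(optional, r):
                s = _marginality_closure(frozenset(mandatory) | frozenset(combo))
                if len(s) > max_terms or s in seen:
                    continue
                seen.add(s)
                out.append(s)
        return out

    s_sets = component_sets(survival_mandatory, survival_optional)
    p_sets = component_sets(capture_mandatory, capture_optional)

    specs = []
    for s in s_sets:
        s_terms = _order_terms(s, SURVIVAL_POOL)
        s_forms = survival_time_forms if any("time" in t.split(":") for t in s) else ("categorical",)
        for p in p_sets:
            p_terms = _order_terms(p, CAPTURE_POOL)
            p_forms = capture_time_forms if any("time" in t.split(":") for t in p) else ("categorical",)
            for sf in s_forms:
                for pf in p_forms:
                    specs.append(
                        ModelSpec(
                            survival_terms=s_terms,
                            capture_terms=p_terms,
                            survival_time_form=sf,
                            capture_time_form=pf,
                        )
                    )
    specs.sort(key=lambda m: m.label())
    return specs


def aicc(loglik: float, k: int, n_eff: int) -> float:
    """Small-sample Akaike information criterion."""
    if n_eff <= k + 1:
        raise ValueError(f"n_eff={n_eff} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n_eff - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized evidence weights exp(-delta/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.isfinite(a).any():
        raise ValueError("need at least one finite criterion value")
    d = a - np.nanmin(a[np.isfinite(a)])
    w = np.where(np.isfinite(d), np.exp(-d / 2.0), 0.0)
    return w / w.sum()


@dataclass
class RankedModelSet:
    """AICc-ranked candidate models after estimability screening."""

    models: list[FittedModel]         # sorted by AICc
    delta: np.ndarray
    weights: np.ndarray               # sums to 1 over `models`
    retained: np.ndarray              # bool mask, weight > threshold
    retain_threshold: float
    n_screened_out: int

    @property
    def retained_models(self) -> list[FittedModel]:
        return [m for m, r in zip(self.models, self.retained) if r]

    @property
    def retained_weights(self) -> np.ndarray:
        w = self.weights[self.retained]
        return w / w.sum()

    @property
    def cumulative_retained_weight(self) -> float:
        return float(self.weights[self.retained].sum())

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": [m.spec.label() for m in self.models],
                "k": [m.k for m in self.models],
                "loglik": [m.loglik for m in self.models],
                "delta_aicc": self.delta,
                "weight": self.weights,
                "retained": self.retained,
            }
        )


def rank_models(
    fitted: list[FittedModel],
    retain_threshold: float = 0.001,
    screen: bool = True,
) -> RankedModelSet:
    """Screen out inestimable/boundary fits, rank the rest by AICc."""
    usable = [m for m in fitted if m.usable()] if screen else list(fitted)
    n_out = len(fitted) - len(usable)
    if not usable:
        raise ValueError("no estimable candidate model survived screening")
    usable.sort(key=lambda m: m.aicc)
    a = np.array([m.aicc for m in usable])
    w = akaike_weights(a)
    return RankedModelSet(
        models=usable,
        delta=a - a.min(),
        weights=w,
        retained=w > retain_threshold,
        retain_threshold=retain_threshold,
        n_screened_out=n_out,
    )


@dataclass
class AveragedPrediction:
    """Pooled simulation draws of a derived quantity (possibly vector)."""

    draws: np.ndarray            # (n_draws,) or (n_draws, m)
    point: np.ndarray            # mean of draws, per column
    ci_low: np.ndarray           # 2.5th percentile
    ci_high: np.ndarray          # 97.5th percentile
    p: np.ndarray | None         # vs null_value, per column
    null_value: float | None
    n_excluded: int = 0


def pvalue(draws, null_value: float, alternative: str = "from_mean") -> float:
    """Two-sided simulation p-value of ``draws`` against a null value.

    ``from_mean`` (default): twice the fraction of draws lying on the
    null's side of the sample mean at least as far from the mean as the
    null is.  ``from_null``: the distance is measured from the null value
    instead.  Capped at 1; with < 1 tail draw out of n the result is the
    resolution floor rather than exactly 0.
    """
    y = np.asarray(draws, dtype=float)
    if y.size < 2:
        raise ValueError("need draws to compute a p-value")
    mu = y.mean()
    d = abs(mu - null_value)
    if alternative == "from_mean":
        if null_value <= mu:
            tail = np.count_nonzero(y <= mu - d)
        else:
            tail = np.count_nonzero(y >= mu + d)
    elif alternative == "from_null":
        if null_value <= mu:
            tail = np.count_nonzero(y <= null_value - d)
        else:
            tail = np.count_nonzero(y >= null_value + d)
    else:
        raise ValueError("alternative must be 'from_mean' or 'from_null'")
    return float(min(1.0, 2.0 * max(tail, 0.5) / y.size)) if d > 0 else 1.0


def _summarize_draws(draws, null_value) -> AveragedPrediction:
    y = np.atleast_2d(np.asarray(draws, dtype=float).T).T  # (n, m)
    point = y.mean(axis=0)
    lo = np.percentile(y, 2.5, axis=0)
    hi = np.percentile(y, 97.5, axis=0)
    p = None
    if null_value is not None:
        p = np.array([pvalue(y[:, j], null_value) for j in range(y.shape[1])])
    squeeze = np.asarray(draws).ndim == 1
    return AveragedPrediction(
        draws=np.asarray(draws, dtype=float),
        point=point[0] if squeeze else point,
        ci_low=lo[0] if squeeze else lo,
        ci_high=hi[0] if squeeze else hi,
        p=(p[0] if squeeze else p) if p is not None else None,
        null_value=null_value,
    )


def draw_betas(model: FittedModel, n: int, rng: np.random.Generator) -> np.ndarray | None:
    """Multivariate-Gaussian draws at the MLE; None if the vcov is unusable."""
    if not np.isfinite(model.vcov).all():
        return None
    cov = (model.vcov + model.vcov.T) / 2.0
    try:
        return rng.multivariate_normal(
            model.beta, cov, size=n, check_valid="ignore", method="svd"
        )
    except (np.linalg.LinAlgError, ValueError):
        return None


def model_average(
    ranked: RankedModelSet,
    quantity,
    n_draws: int = 10000,
    seed: int = 0,
    null_value: float | None = None,
) -> AveragedPrediction:
    """Weight-proportional pooled simulation of a derived quantity.

    ``quantity(fitted_model, beta_draws)`` maps (nd, k) coefficient draws
    to (nd,) or (nd, m) values of the estimand.  Each retained model
    contributes ``round(weight * n_draws)`` draws; a model whose
    covariance cannot be sampled is skipped with a warning and the
    weights renormalized.
    """
    rng = np.random.default_rng(seed)
    models = ranked.retained_models
    w = ranked.retained_weights
    pieces = []
    skipped = 0
    for m, wm in zip(models, w):
        nd = int(round(wm * n_draws))
        if nd == 0:
            continue
        betas = draw_betas(m, nd, rng)
        if betas is None:
            warnings.warn(f"skipping model with unusable covariance: {m.spec.label()}")
            skipped += 1
            continue
        pieces.append(np.asarray(quantity(m, betas), dtype=float))
    if not pieces:
        raise ValueError("no model could be sampled")
    pooled = np.concatenate(pieces, axis=0)
    out = _summarize_draws(pooled, null_value)
    out.n_excluded = skipped
    return out


def relative_survival(
    treatment_draws, control_draws, null_value: float = 1.0
) -> AveragedPrediction:
    """Ratio of treatment to control survival draws, summarized vs null 1.

    Draws where the control survival is 0 are excluded; their count is
    reported on the result.
    """
    t = np.asarray(treatment_draws, dtype=float)
    c = np.asarray(control_draws, dtype=float)
    if t.shape != c.shape:
        raise ValueError("treatment and control draws must be paired")
    ok = c > 0
    if t.ndim == 1:
        ratio = t[ok] / c[ok]
        excluded = int((~ok).sum())
    else:
        keep = ok.all(axis=1)
        ratio = t[keep] / c[keep]
        excluded = int((~keep).sum())
    out = _summarize_draws(ratio, null_value)
    out.n_excluded = excluded
    return out
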