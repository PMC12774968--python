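"""Robust-design Huggins model with random temporary emigration.

The likelihood conditions on each individual's first capture (Huggins
conditional likelihood), so capture probability parameters are estimated
without modelling abundance; abundance is recovered afterwards by
Horvitz-Thompson summation of 1 / p* over the individuals caught in a
session, where p* = 1 - prod(1 - p) is the probability of being caught at
least once in the session.

Within a primary session the population is closed and occasions are
independent Bernoulli(p) captures (capture and recapture probabilities
equal, p = c).  Between sessions three latent states are marginalized by
a forward recursion: alive-and-available, alive-but-off-plot (temporary
emigrant), and dead.  Survival acts on a 30-day (monthly) scale and is
powered by L/30 for an interval of L days; temporary emigration is
random (gamma' = gamma''): availability at each session is
Bernoulli(1 - gamma) independent of previous availability.

Model structure is declared as term lists on the logit of monthly
survival and of per-occasion capture probability; terms are colon-joined
products of the base factors location, treatment, time, mass, sex,
cohort and (for capture) the ordinal day within session.  Time enters
either categorically (optionally merging the last two levels, used when
the final session leaves parameters inestimable) or through a cubic
B-spline basis with 3 or 4 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.special import expit

from .capture_data import EncounterData, StudyDesign

__all__ = [
    "ModelSpec",
    "FittedModel",
    "DesignMatrices",
    "spline_basis",
    "build_design",
    "negloglik",
    "fit",
    "population_size",
    "monthly_survival",
]

TIME_FORMS = ("categorical", "categorical-last-two-merged", "spline-3", "spline-4")
MASS_CENTER = 25.0
MASS_SCALE = 10.0

SURVIVAL_POOL = (
    "location", "treatment", "time", "mass", "sex", "cohort",
    "location:treatment", "location:time", "treatment:time",
    "treatment:mass", "time:mass",
)
CAPTURE_POOL = (
    "location", "sex", "time", "day",
    "location:time", "location:day", "location:time:day",
)
MANDATORY_SURVIVAL = ("location", "time", "mass")
MANDATORY_CAPTURE = ("location", "time", "location:time")
MAX_TERMS = 11


@dataclass(frozen=True)
class ModelSpec:
    """Term structure of one candidate model.

    ``survival_terms`` and ``capture_terms`` are tuples of colon-joined
    factor products; the intercept is always present and not listed.
    ``p = c`` and random emigration (``gamma' = gamma''``) always hold.
    """

    survival_terms: tuple[str, ...] = ()
    capture_terms: tuple[str, ...] = ()
    survival_time_form: str = "categorical"
    capture_time_form: str = "categorical"

    def __post_init__(self) -> None:
        for tf in (self.survival_time_form, self.capture_time_form):
            if tf not in TIME_FORMS:
                raise ValueError(f"unknown time form {tf!r}")
        if len(self.survival_terms) > MAX_TERMS or len(self.capture_terms) > MAX_TERMS:
            raise ValueError(f"more than {MAX_TERMS} terms in a model component")

    def label(self) -> str:
        s = "+".join(self.survival_terms) or "1"
        p = "+".join(self.capture_terms) or "1"
        return f"S({s};{self.survival_time_form}) p({p};{self.capture_time_form})"

    def check_mandatory(self) -> bool:
        return all(t in self.survival_terms for t in MANDATORY_SURVIVAL) and all(
            t in self.capture_terms for t in MANDATORY_CAPTURE
        )


def spline_basis(x, df: int) -> np.ndarray:
    """Cubic B-spline basis with ``df`` columns, no intercept column.

    Interior knots (``df - 3`` of them) sit at quantiles of ``x``; the
    intercept-spanning first basis function is dropped, as the model
    carries its own intercept.
    """
    if df not in (3, 4):
        raise ValueError("df must be 3 or 4")
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < df + 1:
        raise ValueError(f"need at least {df + 1} distinct points for df={df}")
    k = 3
    n_interior = df - k
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), qs)
    else:
        interior = np.array([])
    t = np.r_[[x.min()] * (k + 1), interior, [x.max()] * (k + 1)]
    B = BSpline.design_matrix(x, t, k).toarray()
    return B[:, 1:]


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _FactorContext:
    locations: tuple[str, ...]
    cohorts: tuple[str, ...]
    n_time_levels: int
    time_form: str
    time_basis: np.ndarray | None  # (n_levels, df) for spline forms


def _time_columns(time_idx: np.ndarray, ctx: _FactorContext):
    """Columns for the time factor at integer level indices."""
    L = ctx.n_time_levels
    if ctx.time_form.startswith("spline"):
        B = ctx.time_basis
        return B[time_idx], [f"time.b{j + 1}" for j in range(B.shape[1])]
    merged = ctx.time_form == "categorical-last-two-merged"
    levels = np.arange(L)
    if merged and L >= 2:
        levels = np.minimum(levels, L - 2)
    lev = np.minimum(time_idx, L - 2) if merged and L >= 2 else time_idx
    uniq = np.unique(levels)[1:]  # reference = first level
    cols = np.stack([(lev == u).astype(float) for u in uniq], axis=1) if uniq.size else np.empty((len(time_idx), 0))
    return cols, [f"time.{u + 1}" for u in uniq]


def _base_factor(name: str, cov: dict, ctx: _FactorContext):
    if name == "location":
        uniq = ctx.locations[1:]
        cols = np.stack([(cov["location"] == u).astype(float) for u in uniq], axis=1) \
            if uniq else np.empty((len(cov["location"]), 0))
        return cols, [f"loc.{u}" for u in uniq]
    if name == "treatment":
        return cov["treated"].astype(float)[:, None], ["treatment"]
    if name == "time":
        return _time_columns(cov["time"], ctx)
    if name == "mass":
        return ((cov["mass"] - MASS_CENTER) / MASS_SCALE)[:, None], ["mass"]
    if name == "sex":
        return (cov["sex"] == "M").astype(float)[:, None], ["sex.M"]
    if name == "cohort":
        uniq = ctx.cohorts[1:]
        cols = np.stack([(cov["cohort"] == u).astype(float) for u in uniq], axis=1) \
            if uniq else np.empty((len(cov["cohort"]), 0))
        return cols, [f"cohort.{u}" for u in uniq]
    if name == "day":
        return cov["day"].astype(float)[:, None], ["day"]
    raise ValueError(f"unknown term {name!r}")


def _term_columns(term: str, cov: dict, ctx: _FactorContext):
    parts = term.split(":")
    cols, names = _base_factor(parts[0], cov, ctx)
    for part in parts[1:]:
        c2, n2 = _base_factor(part, cov, ctx)
        cols = np.einsum("ni,nj->nij", cols, c2).reshape(len(cols), -1)
        names = [f"{a}:{b}" for a in names for b in n2]
    return cols, names


def _design_matrix(terms, cov, ctx):
    n = len(next(iter(cov.values())))
    blocks = [np.ones((n, 1))]
    names = ["(intercept)"]
    for term in terms:
        cols, nm = _term_columns(term, cov, ctx)
        blocks.append(cols)
        names += nm
    return np.concatenate(blocks, axis=1), names


@dataclass
class DesignMatrices:
    """Per-row design matrices plus everything the likelihood needs."""

    spec: ModelSpec
    design: StudyDesign
    Xs: np.ndarray               # (n, n_intervals, ks)
    Xp: np.ndarray               # (n, n_occasions, kp)
    names_s: list[str]
    names_p: list[str]
    estimate_gamma: bool
    interval_exponent: np.ndarray  # (n_intervals,) = L / 30
    # data-dependent pieces
    encounters: np.ndarray
    captured_session: np.ndarray  # (n, T) bool
    first_session: np.ndarray     # (n,)
    first_occasion: np.ndarray    # (n,)
    after_first_mask: np.ndarray  # (n, n_occ): occasions after first capture
    # contexts for profile prediction
    ctx_s: _FactorContext = None
    ctx_p: _FactorContext = None

    @property
    def ks(self) -> int:
        return self.Xs.shape[2]

    @property
    def kp(self) -> int:
        return self.Xp.shape[2]

    @property
    def n_params(self) -> int:
        return self.ks + self.kp + (1 if self.estimate_gamma else 0)

    def split(self, beta):
        beta = np.asarray(beta, dtype=float)
        bs = beta[: self.ks]
        bp = beta[self.ks : self.ks + self.kp]
        bg = beta[-1] if self.estimate_gamma else -np.inf
        return bs, bp, bg

    def real_params(self, beta):
        """(S_monthly (n, n_int), p (n, n_occ), gamma scalar)."""
        bs, bp, bg = self.split(beta)
        S = expit(self.Xs @ bs)
        p = expit(self.Xp @ bp)
        gamma = expit(bg) if self.estimate_gamma else 0.0
        return S, p, gamma

    def survival_row(self, location, treated, interval, mass, sex_frac_m=0.0, cohort=None):
        """Design row for a survival covariate profile.

        ``sex_frac_m`` enters the sex dummy fractionally (a sex-ratio
        profile), matching prediction at the observed sex composition.
        """
        cov = {
            "location": np.array([location]),
            "treated": np.array([float(treated)]),
            "time": np.array([interval]),
            "mass": np.array([float(mass)]),
            "sex": np.array(["F"]),
            "cohort": np.array([cohort if cohort is not None else self.ctx_s.cohorts[0]]),
            "day": np.array([0.0]),
        }
        row, _ = _design_matrix(self.spec.survival_terms, cov, self.ctx_s)
        if sex_frac_m:
            cov["sex"] = np.array(["M"])
            row_m, _ = _design_matrix(self.spec.survival_terms, cov, self.ctx_s)
            row = (1.0 - sex_frac_m) * row + sex_frac_m * row_m
        return row[0]


def build_design(
    spec: ModelSpec,
    data: EncounterData,
    mass: np.ndarray | None,
    design: StudyDesign,
    estimate_gamma: bool = True,
) -> DesignMatrices:
    """Expand a :class:`ModelSpec` into survival and capture design matrices.

    ``mass`` is the complete imputed matrix (n, n_sessions) in grams; it
    may be None only if no term involves mass.  Survival rows use the mass
    at the interval's origin session.  The treatment flag is 0 for every
    row whose interval originates in a pre-netting session, so all plots
    share 'control' parameters before the exclusion starts.
    """
    T = design.n_sessions
    n = data.n_individuals
    n_int = T - 1
    uses_mass = any("mass" in t.split(":") for t in spec.survival_terms + spec.capture_terms)
    if uses_mass and mass is None:
        raise ValueError("model includes mass but no imputed mass matrix given")
    if mass is None:
        mass = np.full((n, T), MASS_CENTER)
    mass = np.asarray(mass, dtype=float)
    if not np.isfinite(mass).all():
        raise ValueError("imputed mass must be finite for every individual x session")

    locations = tuple(sorted(np.unique(data.location)))
    cohorts = tuple(sorted(np.unique(data.cohort)))

    def make_ctx(form, n_levels):
        basis = None
        if form.startswith("spline"):
            df = int(form.split("-")[1])
            basis = spline_basis(np.arange(n_levels), df)
        return _FactorContext(locations, cohorts, n_levels, form, basis)

    ctx_s = make_ctx(spec.survival_time_form, max(n_int, 1))
    ctx_p = make_ctx(spec.capture_time_form, T)

    # survival rows: individual x interval
    treated_plot = data.plot_role == "treatment"
    iv = np.arange(n_int)
    cov_s = {
        "location": np.repeat(data.location, n_int),
        "treated": (treated_plot[:, None] & ((iv + 1)[None, :] >= design.treatment_start_session)).ravel().astype(float),
        "time": np.tile(iv, n),
        "mass": mass[:, :n_int].ravel(),
        "sex": np.repeat(data.sex, n_int),
        "cohort": np.repeat(data.cohort, n_int),
        "day": np.zeros(n * n_int),
    }
    if n_int > 0:
        Xs_flat, names_s = _design_matrix(spec.survival_terms, cov_s, ctx_s)
        Xs = Xs_flat.reshape(n, n_int, -1)
    else:
        # single-session study: no survival (or emigration) parameters
        Xs, names_s = np.empty((n, 0, 0)), []

    # capture rows: individual x occasion
    occ_sess = design.occasion_session
    occ_day = design.occasion_day
    n_occ = design.total_occasions
    cov_p = {
        "location": np.repeat(data.location, n_occ),
        "treated": (treated_plot[:, None] & ((occ_sess + 1)[None, :] >= design.treatment_start_session)).ravel().astype(float),
        "time": np.tile(occ_sess, n),
        "mass": mass[:, occ_sess].ravel(),
        "sex": np.repeat(data.sex, n_occ),
        "cohort": np.repeat(data.cohort, n_occ),
        "day": np.tile(occ_day.astype(float), n),
    }
    Xp_flat, names_p = _design_matrix(spec.capture_terms, cov_p, ctx_p)
    Xp = Xp_flat.reshape(n, n_occ, -1)

    first_session, first_occ = data.first_capture()
    occ_idx = np.arange(n_occ)
    after_first = (occ_idx[None, :] > first_occ[:, None]) & (
        occ_sess[None, :] == first_session[:, None]
    )

    return DesignMatrices(
        spec=spec,
        design=design,
        Xs=Xs,
        Xp=Xp,
        names_s=names_s,
        names_p=names_p,
        estimate_gamma=estimate_gamma and n_int > 0,
        interval_exponent=np.asarray(design.interval_days, dtype=float) / 30.0,
        encounters=data.encounters,
        captured_session=data.captured_by_session(),
        first_session=first_session,
        first_occasion=first_occ,
        after_first_mask=after_first,
        ctx_s=ctx_s,
        ctx_p=ctx_p,
    )


# ---------------------------------------------------------------------------
# likelihood

_TINY = 1e-300


def negloglik(beta, dm: DesignMatrices) -> float:
    """Negative log conditional likelihood of the observed histories.

    Each individual contributes the probability of its history strictly
    after its first capture, given that first capture: independent
    Bernoulli(p) occasions through the rest of the first-capture session,
    then a forward recursion over {available, unavailable, dead} with
    survival ``S_monthly^(L/30)`` and availability ``Bernoulli(1-gamma)``
    between sessions.  An unavailable or dead animal cannot be seen.
    """
    S, p, gamma = dm.real_params(beta)
    if not (np.isfinite(S).all() and np.isfinite(p).all()):
        return np.inf
    design = dm.design
    T = design.n_sessions
    n = dm.encounters.shape[0]
    x = dm.encounters

    # per-session available-state emission: prod over occasions of p^x (1-p)^(1-x)
    like_obs = np.where(x == 1, p, 1.0 - p)
    emis = np.empty((n, T))
    first_term = np.ones(n)
    for t in range(T):
        sl = design.session_slice(t)
        emis[:, t] = like_obs[:, sl].prod(axis=1)
    ft = np.where(dm.after_first_mask, like_obs, 1.0)
    first_term = ft.prod(axis=1)

    phi = S ** dm.interval_exponent[None, :] if T > 1 else np.empty((n, 0))

    aA = np.zeros(n)
    aU = np.zeros(n)
    aD = np.zeros(n)
    f = dm.first_session
    cap = dm.captured_session
    for t in range(T):
        if t > 0:
            prev = f < t
            alive = aA + aU
            ph = phi[:, t - 1]
            nA = alive * ph * (1.0 - gamma)
            nU = alive * ph * gamma
            nD = aD + alive * (1.0 - ph)
            seen = cap[:, t]
            e = emis[:, t]
            tA = nA * e
            tU = np.where(seen, 0.0, nU)
            tD = np.where(seen, 0.0, nD)
            aA = np.where(prev, tA, aA)
            aU = np.where(prev, tU, aU)
            aD = np.where(prev, tD, aD)
        just = f == t
        if just.any():
            aA = np.where(just, first_term, aA)
            aU = np.where(just, 0.0, aU)
            aD = np.where(just, 0.0, aD)
    lik = aA + aU + aD
    return float(-np.log(np.maximum(lik, _TINY)).sum())


@dataclass
class FittedModel:
    """Maximum-likelihood fit of one :class:`ModelSpec`."""

    spec: ModelSpec
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    k: int
    n_eff: int
    aicc: float
    converged: bool
    boundary: bool
    boundary_notes: list[str] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def usable(self) -> bool:
        """Estimable, converged, off-boundary -- eligible for ranking."""
        return self.converged and not self.boundary

    def to_dict(self) -> dict:
        return {
            "spec": {
                "survival_terms": list(self.spec.survival_terms),
                "capture_terms": list(self.spec.capture_terms),
                "survival_time_form": self.spec.survival_time_form,
                "capture_time_form": self.spec.capture_time_form,
            },
            "beta": self.beta.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "n_eff": self.n_eff,
            "aicc": self.aicc,
            "converged": self.converged,
            "boundary": self.boundary,
            "boundary_notes": list(self.boundary_notes),
            "names": list(self.names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = ModelSpec(
            survival_terms=tuple(d["spec"]["survival_terms"]),
            capture_terms=tuple(d["spec"]["capture_terms"]),
            survival_time_form=d["spec"]["survival_time_form"],
            capture_time_form=d["spec"]["capture_time_form"],
        )
        return cls(
            spec=spec,
            beta=np.asarray(d["beta"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float),
            loglik=d["loglik"],
            k=d["k"],
            n_eff=d["n_eff"],
            aicc=d["aicc"],
            converged=d["converged"],
            boundary=d["boundary"],
            boundary_notes=list(d["boundary_notes"]),
            names=list(d["names"]),
        )


def _numerical_hessian(fun, beta, rel_step=1e-5):
    k = len(beta)
    h = rel_step * np.maximum(np.abs(beta), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            bpp = beta.copy(); bpp[i] += h[i]; bpp[j] += h[j]
            bpm = beta.copy(); bpm[i] += h[i]; bpm[j] -= h[j]
            bmp = beta.copy(); bmp[i] -= h[i]; bmp[j] += h[j]
            bmm = beta.copy(); bmm[i] -= h[i]; bmm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(bpp) - fun(bpm) - fun(bmp) + fun(bmm)) / (
                4.0 * h[i] * h[j]
            )
    return H


def fit(
    spec: ModelSpec,
    data: EncounterData,
    mass: np.ndarray | None,
    design: StudyDesign,
    estimate_gamma: bool = True,
    n_eff: int | None = None,
    compute_vcov: bool = True,
    maxiter: int = 500,
) -> FittedModel:
    """Maximize the conditional likelihood by quasi-Newton from zero.

    The covariance of beta comes from the inverse numerical Hessian
    (central differences, relative step 1e-5).  A fit is flagged as
    boundary when any fitted real-scale probability leaves
    [1e-6, 1 - 1e-6] or a coefficient variance is degenerate (< 1e-10 or
    > 1e6); non-convergence is flagged, not raised.
    """
    dm = build_design(spec, data, mass, design, estimate_gamma=estimate_gamma)
    x0 = np.zeros(dm.n_params)
    res = optimize.minimize(
        negloglik, x0, args=(dm,), method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 200000},
    )
    beta = res.x
    loglik = -float(res.fun)
    k = dm.n_params
    n_eff = data.n_individuals if n_eff is None else n_eff

    from .model_selection import aicc as _aicc  # late import; no cycle at import time

    aicc_val = _aicc(loglik, k, n_eff) if n_eff > k + 1 else np.inf

    notes: list[str] = []
    S, p, gamma = dm.real_params(beta)
    eps = 1e-6
    if ((S < eps) | (S > 1 - eps)).any():
        notes.append("survival at boundary")
    if ((p < eps) | (p > 1 - eps)).any():
        notes.append("capture probability at boundary")
    if dm.estimate_gamma and (gamma < eps or gamma > 1 - eps):
        notes.append("gamma at boundary")

    vcov = np.full((k, k), np.nan)
    if compute_vcov:
        H = _numerical_hessian(lambda b: negloglik(b, dm), beta)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
            notes.append("singular Hessian")
        var = np.diag(vcov)
        if (var < 1e-10).any() or (var > 1e6).any() or (var < 0).any():
            notes.append("degenerate coefficient variance")

    names = dm.names_s + dm.names_p + (["gamma"] if dm.estimate_gamma else [])
    return FittedModel(
        spec=spec,
        beta=beta,
        vcov=vcov,
        loglik=loglik,
        k=k,
        n_eff=n_eff,
        aicc=aicc_val,
        converged=bool(res.success),
        boundary=bool(notes),
        boundary_notes=notes,
        names=names,
    )


# ---------------------------------------------------------------------------
# derived estimands


def p_star(p: np.ndarray, design: StudyDesign, session: int) -> np.ndarray:
    """Per-individual probability of >= 1 capture in a session.

    ``p`` has occasion capture probabilities on its last axis; leading
    axes (e.g. simulation draws) pass through.
    """
    sl = design.session_slice(session)
    return 1.0 - np.prod(1.0 - p[..., sl], axis=-1)


def population_size(
    p: np.ndarray,
    data: EncounterData,
    session: int,
    location: str | None = None,
    plot: str | None = None,
) -> np.ndarray:
    """Horvitz-Thompson abundance: sum of 1/p* over captured individuals.

    ``p`` is (n, n_occasions) or (n_draws, n, n_occasions); returns a
    scalar array per draw.  Always >= the observed count.
    """
    mask = data.captured_by_session()[:, session]
    if location is not None:
        mask = mask & (data.location == location)
    if plot is not None:
        mask = mask & (data.plot_role == plot)
    ps = p_star(p, data.design, session)
    ps = np.maximum(ps[..., mask], 1e-12)
    return (1.0 / ps).sum(axis=-1)


def monthly_survival(
    dm: DesignMatrices,
    beta: np.ndarray,
    location: str,
    treated: bool,
    interval: int,
    mass: float,
    sex_frac_m: float = 0.0,
) -> np.ndarray:
    """Monthly survival at a covariate profile, for one beta or many draws.

    ``beta`` is (k,) or (n_draws, k); the profile plugs in the supplied
    mean body mass and sex ratio, as predictions are made at the observed
    composition of the captured animals at that point.
    """
    row = dm.survival_row(location, treated, interval, mass, sex_frac_m)
    single = np.asarray(beta).ndim == 1
    beta = np.atleast_2d(beta)
    out = expit(beta[:, : dm.ks] @ row)
    return float(out[0]) if single else out
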