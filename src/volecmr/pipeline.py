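"""End-to-end orchestration: simulate/load -> impute -> fit -> average -> GOF.

The stages follow the analysis order of the exclusion study: build (or
read) robust-design capture histories, complete the body-mass covariate
with latent-class imputation, fit the candidate Huggins models, rank by
AICc with estimability screening, produce simulation-averaged estimates
of monthly survival, relative survival (treatment/control), and
Horvitz-Thompson abundance, and close with a parametric-bootstrap
goodness-of-fit on the top model.

Every stochastic stage draws its seed from the master seed by a fixed
offset, so stages are independently reproducible and the whole run is
deterministic: two runs with the same master seed write byte-identical
tables.  Outputs are plain CSV/JSON plus a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import __version__
from .capture_data import EncounterData, StudyDesign, read_long_csv, summarize
from .cmr_model import ModelSpec, build_design, fit
from .gof import parametric_bootstrap
from .mass_imputation import bic_weights, fit_latent_classes, impute_mass
from .model_selection import (
    generate_candidates,
    model_average,
    rank_models,
    relative_survival,
)
from .synthetic import SimulationConfig, simulate

log = logging.getLogger("volecmr")

# fixed stage-seed offsets from the master seed
SEED_SIMULATE = 11
SEED_IMPUTE = 23
SEED_AVERAGE = 37
SEED_GOF = 51


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    scenario: SimulationConfig | None = None   # simulate when set
    data_path: str | None = None               # else read this long CSV
    design: StudyDesign | None = None          # required with data_path
    pool: str = "reduced"                      # minimal | reduced | full
    k_classes: tuple[int, ...] = (3, 4)
    n_restarts: int = 3
    n_draws: int = 2000
    n_boot: int = 50
    master_seed: int = 1
    out_dir: str = "results/pipeline"
    retain_threshold: float = 0.001

    def resolved_design(self) -> StudyDesign:
        if self.scenario is not None:
            return self.scenario.design
        if self.design is None:
            raise ValueError("need either a scenario or a data path with a design")
        return self.design


def candidate_specs(pool: str) -> list[ModelSpec]:
    if pool == "minimal":
        return generate_candidates(
            survival_optional=("treatment",),
            capture_optional=(),
            survival_time_forms=("categorical",),
            capture_time_forms=("spline-3",),
        )
    if pool == "reduced":
        return generate_candidates()
    if pool == "full":
        return generate_candidates(full_pools=True)
    raise ValueError(f"unknown candidate pool {pool!r}")


def derive_estimates(
    ranked,
    data: EncounterData,
    mass: np.ndarray | None,
    design: StudyDesign,
    n_draws: int,
    seed: int,
    out: Path | None = None,
) -> dict:
    """Model-averaged survival, relative survival and abundance tables.

    Survival is predicted at the mean observed mass and sex ratio of the
    captures at each prediction point; relative survival uses paired
    draws so treatment and control share each simulated beta; abundance
    is the Horvitz-Thompson sum per draw.  Writes CSVs when ``out`` is
    given and returns the tables.
    """
    dms = {id(m): build_design(m.spec, data, mass, design) for m in ranked.models}
    locations = sorted(np.unique(data.location))
    T = design.n_sessions
    captured = data.captured_by_session()

    combos = [
        (loc, plot, j)
        for loc in locations
        for plot in ("treatment", "control")
        for j in range(T - 1)
    ]

    def q_survival(model, betas):
        dm = dms[id(model)]
        cols = []
        for loc, plot, j in combos:
            mass_j, frac_m = _profile_at(data, loc, j)
            treated = plot == "treatment" and (j + 1) >= design.treatment_start_session
            row = dm.survival_row(loc, treated, j, mass_j, frac_m)
            cols.append(expit(betas[:, : dm.ks] @ row))
        return np.stack(cols, axis=1)

    pred = model_average(ranked, q_survival, n_draws=n_draws, seed=seed)
    surv = pd.DataFrame(
        [
            {"location": loc, "plot": plot, "interval": j + 1,
             "monthly_survival": pred.point[c],
             "ci_low": pred.ci_low[c], "ci_high": pred.ci_high[c]}
            for c, (loc, plot, j) in enumerate(combos)
        ]
    )

    rel_rows = []
    for loc in locations:
        for j in range(T - 1):
            it = combos.index((loc, "treatment", j))
            ic = combos.index((loc, "control", j))
            rel = relative_survival(pred.draws[:, it], pred.draws[:, ic])
            rel_rows.append(
                {"location": loc, "interval": j + 1,
                 "relative_survival": float(rel.point),
                 "ci_low": float(rel.ci_low), "ci_high": float(rel.ci_high),
                 "p_vs_1": float(rel.p)}
            )
    rel_df = pd.DataFrame(rel_rows)

    ab_combos = [
        (loc, plot, t)
        for loc in locations
        for plot in ("treatment", "control")
        for t in range(T)
    ]

    def q_abundance(model, betas):
        dm = dms[id(model)]
        cols = []
        for loc, plot, t in ab_combos:
            sl = design.session_slice(t)
            mask = captured[:, t] & (data.location == loc) & (data.plot_role == plot)
            if not mask.any():
                cols.append(np.zeros(len(betas)))
                continue
            X = dm.Xp[mask][:, sl, :]
            eta = np.einsum("dk,iok->dio", betas[:, dm.ks : dm.ks + dm.kp], X)
            p = expit(eta)
            ps = np.maximum(1.0 - np.prod(1.0 - p, axis=2), 1e-12)
            cols.append((1.0 / ps).sum(axis=1))
        return np.stack(cols, axis=1)

    ab = model_average(ranked, q_abundance, n_draws=n_draws, seed=seed + 1)
    ab_df = pd.DataFrame(
        [
            {"location": loc, "plot": plot, "session": t + 1,
             "n_hat": ab.point[c], "ci_low": ab.ci_low[c], "ci_high": ab.ci_high[c]}
            for c, (loc, plot, t) in enumerate(ab_combos)
        ]
    )

    diff_rows = []
    for loc in locations:
        for t in range(T):
            it = ab_combos.index((loc, "treatment", t))
            ic = ab_combos.index((loc, "control", t))
            d = ab.draws[:, it] - ab.draws[:, ic]
            diff_rows.append(
                {"location": loc, "session": t + 1,
                 "diff_treatment_minus_control": float(d.mean()),
                 "ci_low": float(np.percentile(d, 2.5)),
                 "ci_high": float(np.percentile(d, 97.5))}
            )
    diff_df = pd.DataFrame(diff_rows)

    if out is not None:
        surv.to_csv(out / "survival.csv", index=False)
        rel_df.to_csv(out / "relative_survival.csv", index=False)
        ab_df.to_csv(out / "abundance.csv", index=False)
        diff_df.to_csv(out / "abundance_diff.csv", index=False)
    return {
        "survival": surv,
        "relative_survival": rel_df,
        "abundance": ab_df,
        "abundance_diff": diff_df,
    }


def _profile_at(data: EncounterData, location: str, session: int) -> tuple[float, float]:
    """Mean observed mass and male fraction of captures at a prediction point."""
    cap = data.captured_by_session()[:, session] & (data.location == location)
    if not cap.any():
        return 25.0, 0.5
    masses = data.observed_mass[cap, session]
    masses = masses[np.isfinite(masses)]
    mean_mass = float(masses.mean()) if masses.size else 25.0
    frac_m = float((data.sex[cap] == "M").mean())
    return mean_mass, frac_m


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of output paths and key objects.

    Any stage failure raises with the stage named; outputs written by
    earlier stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "master_seed": config.master_seed,
        "stage_seeds": {
            "simulate": config.master_seed + SEED_SIMULATE,
            "impute": config.master_seed + SEED_IMPUTE,
            "average": config.master_seed + SEED_AVERAGE,
            "gof": config.master_seed + SEED_GOF,
        },
        "pool": config.pool,
        "stages": {},
    }
    result: dict = {"out_dir": str(out)}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                value = fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return value

        return deco

    design = config.resolved_design()

    @stage("data")
    def _data():
        if config.scenario is not None:
            data, truth = simulate(config.scenario, seed=config.master_seed + SEED_SIMULATE)
            truth.abundance().to_csv(out / "true_abundance.csv", index=False)
            return data
        return read_long_csv(config.data_path, design)

    data = _data

    @stage("summary")
    def _summary():
        stats = summarize(data, design)
        stats.to_frame().to_csv(out / "summary.csv", index=False)
        return stats

    _summary

    @stage("impute")
    def _impute():
        models = [
            fit_latent_classes(
                data, k, n_restarts=config.n_restarts,
                seed=config.master_seed + SEED_IMPUTE + k,
            )
            for k in config.k_classes
        ]
        w = bic_weights(models)
        imputed = impute_mass(models, w, data)
        pd.DataFrame(
            imputed, index=pd.Index(data.ids, name="id"),
            columns=[f"session_{t + 1}" for t in range(design.n_sessions)],
        ).to_csv(out / "imputed_mass.csv")
        rows = []
        for m, wt in zip(models, w):
            rows.append(
                {
                    "n_classes": m.n_classes,
                    "loglik": m.loglik,
                    "bic": m.bic,
                    "weight": wt,
                    "converged": m.converged,
                    "mixing": json.dumps([round(float(x), 4) for x in m.mixing]),
                }
            )
        pd.DataFrame(rows).to_csv(out / "class_summary.csv", index=False)
        return imputed

    mass = _impute

    @stage("fit")
    def _fit():
        specs = candidate_specs(config.pool)
        fits = []
        for i, spec in enumerate(specs):
            m = fit(spec, data, mass, design)
            log.info(
                "candidate %d/%d %s: loglik=%.2f k=%d AICc=%.2f%s",
                i + 1, len(specs), spec.label(), m.loglik, m.k, m.aicc,
                "" if m.usable() else " [screened out]",
            )
            fits.append(m)
        ranked = rank_models(fits, retain_threshold=config.retain_threshold)
        ranked.table().to_csv(out / "selection_table.csv", index=False)
        return ranked

    ranked = _fit

    @stage("derive")
    def _derive():
        return derive_estimates(
            ranked, data, mass, design,
            n_draws=config.n_draws,
            seed=config.master_seed + SEED_AVERAGE,
            out=out,
        )

    derived = _derive

    @stage("gof")
    def _gof():
        best = ranked.models[0]
        res = parametric_bootstrap(
            best, data, mass, design,
            n_boot=config.n_boot, seed=config.master_seed + SEED_GOF,
        )
        with open(out / "gof.json", "w") as fh2:
            json.dump(res.to_dict(), fh2, indent=2)
        return res

    gof_res = _gof

    with open(out / "manifest.json", "w") as fh2:
        json.dump(manifest, fh2, indent=2)
    log.removeHandler(fh)
    fh.close()

    result.update(
        {
            "data": data,
            "mass": mass,
            "ranked": ranked,
            "derived": derived,
            "gof": gof_res,
            "manifest": manifest,
        }
    )
    return result
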