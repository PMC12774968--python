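# volecmr

Robust-design capture–mark–recapture analysis of an avian-predation
exclusion experiment on root voles (*Microtus oeconomus*).

Field setting: three paired trapping grids in a sedge wetland, each
pair with one plot netted against birds of prey and one open control,
surveyed by five-day live-trapping sessions at two-month intervals
across a year (the first session pre-experimental, before netting).
The scientific questions: did excluding avian predators raise vole
survival, when, and did it change population size?

The package provides the full analysis stack to answer them:

- **capture histories** — a validated data model for robust-design
  encounter matrices with plot/sex/cohort covariates and sparse body
  masses; long-CSV and MARK-style `.inp` I/O; descriptive summaries;
- **synthetic data** — a truth-tracking simulator of the whole study
  (survival, random temporary emigration, recruitment, latent body-mass
  trajectory classes), so every estimator is testable without any field
  data;
- **mass imputation** — latent-class Gaussian-mixture trajectories fit
  by EM, BIC-weighted, giving every vole a mass at every session via a
  posterior-weighted class mean plus a per-animal offset;
- **the CMR model** — Huggins conditional likelihood for the robust
  design with random temporary emigration (`p = c`, `γ′ = γ″`),
  survival on a 30-day scale powered by interval length, B-spline or
  categorical time, maximum-likelihood fitting with estimability
  screening, and Horvitz–Thompson abundance `N̂ = Σ 1/p*`;
- **model selection & averaging** — marginality-respecting candidate
  sets, AICc ranking, Akaike weights, and simulation-based averaged
  predictions (survival, treatment/control relative survival with
  p-values against 1, abundance) with 95% percentile intervals;
- **goodness of fit** — parametric-bootstrap p and overdispersion
  `ĉ` = observed deviance / mean bootstrap deviance, with deviance
  measured against the saturated multinomial over histories.

The model, in the field's notation: within a session an available
animal is caught each day with probability `p`; between sessions it
survives with `S^(L/30)` (`S` = apparent monthly survival, `L` =
interval days) and is available with probability `1 − γ` independent of
past availability; the likelihood conditions on each animal's first
capture, so abundance drops out and is recovered afterwards from
`p* = 1 − Π(1 − p)`.  See `docs/methods.md` for the full account.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic scenario and write their tables under
`results/analysis/`:

```sh
python analysis/01_simulate.py          # capture histories + summary
python analysis/02_impute_mass.py       # latent-class mass imputation
python analysis/03_fit_and_rank_models.py
python analysis/04_average_estimates.py
python analysis/05_bootstrap_gof.py
python analysis/06_recovery_checks.py   # estimator calibration vs truth
```

Actual output (abridged):

```
$ python analysis/01_simulate.py
simulated 1497 voles, 1386 ever captured
6325 captures; 86.7% recaptured; 69.2 (+/- 17.8 sd) caught per session and plot

$ python analysis/02_impute_mass.py
K=3: lnL=-6806.7 BIC=13953.3 weight=0.000 mixing=[0.247 0.462 0.291]
K=4: lnL=-6649.4 BIC=13754.6 weight=1.000 mixing=[0.267 0.263 0.262 0.207]
observed vs imputed mass at captured sessions: r = 0.992

$ python analysis/03_fit_and_rank_models.py
fitting 20 candidate models
best model: S(location+treatment+time+mass;spline-3)
            p(location+time+location:time;spline-3) (k=21, weight=0.42)
12 retained models carry 0.999 of the weight; 2 screened out

$ python analysis/04_average_estimates.py
relative survival (treatment/control) across active intervals: 1.17-1.26
largest effect at Losiowka, interval 6: ratio 1.26 [1.18, 1.34], p = 0.0002
mean treatment-control abundance difference over sessions: 26.3 voles

$ python analysis/05_bootstrap_gof.py
observed deviance 10749.2; bootstrap mean 10677.7
p = 0.35, c-hat = 1.007 (0 failed refits)
no lack of fit detected
```

Reading this: the selection table concentrates weight on structures
containing the treatment effect; the averaged treatment/control
survival ratio sits at 1.17–1.26 across post-netting intervals —
control survival 15–21% below the netted plots, consistent with the
scenario's generating effect — with intervals excluding 1 and p-values
far below 0.05; and the netted plots carry more voles on average.  The
pre-netting interval reports a ratio of exactly 1 because all plots
share control parameters there.  `05_bootstrap_gof.py` then shows the
well-specified model passes its own bootstrap (`ĉ` near 1, p not
extreme), and `06_recovery_checks.py` reports coverage and bias of the
estimators against the simulator's truth.

The same stack runs from the shell on any long-format capture CSV:

```sh
volecmr run-all --data captures.csv --design design.yaml --out-dir results/run
```

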