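"""Data model and I/O for robust-design capture histories.

A robust-design study consists of widely spaced *primary sessions* (the
population is open between them) each containing consecutive *secondary
occasions* (trapping days; the population is treated as closed within a
session).  This module holds the study design, the individual encounter
matrix with covariates and sparse body-mass observations, long-CSV
readers/writers, a MARK-style ``.inp`` encounter-history writer, and
descriptive summaries.

Conventions
-----------
Sessions and occasions are 1-based in files and 0-based internally.
Occasion dates are ``session start + occasion index`` days (one occasion
per trapping day).  If an individual is weighed more than once within a
session, the first record of that session supplies the session mass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StudyDesign",
    "EncounterData",
    "SummaryStats",
    "read_long_csv",
    "write_long_csv",
    "write_encounter_histories",
    "read_encounter_histories",
    "summarize",
]

SEXES = ("F", "M")


@dataclass(frozen=True)
class StudyDesign:
    """Primary/secondary structure of a robust-design trapping study.

    Parameters
    ----------
    session_labels
        Ordered labels of the primary sessions.
    session_start_dates
        Calendar start date of each session.
    occasions_per_session
        Number of trapping days in each session (>= 1).
    treatment_start_session
        1-based index of the first session with the exclusion netting
        active.  In the pre-experimental session(s) before it, all plots
        are coded as controls.
    """

    session_labels: tuple[str, ...]
    session_start_dates: tuple[date, ...]
    occasions_per_session: tuple[int, ...]
    treatment_start_session: int = 2

    def __post_init__(self) -> None:
        n = self.n_sessions
        if not (len(self.session_start_dates) == len(self.occasions_per_session) == n):
            raise ValueError("design fields must have one entry per session")
        if any(k < 1 for k in self.occasions_per_session):
            raise ValueError("occasions_per_session must be >= 1")
        if any(d <= 0 for d in self.interval_days):
            raise ValueError("session start dates must be strictly increasing")
        if not 1 <= self.treatment_start_session <= n + 1:
            raise ValueError("treatment_start_session out of range")

    @property
    def n_sessions(self) -> int:
        return len(self.session_labels)

    @property
    def interval_days(self) -> tuple[int, ...]:
        """Days between consecutive session starts (length ``n_sessions - 1``)."""
        d = self.session_start_dates
        return tuple((d[i + 1] - d[i]).days for i in range(len(d) - 1))

    @property
    def total_occasions(self) -> int:
        return int(sum(self.occasions_per_session))

    @property
    def occasion_session(self) -> np.ndarray:
        """0-based session index of each occasion column."""
        return np.repeat(np.arange(self.n_sessions), self.occasions_per_session)

    @property
    def occasion_day(self) -> np.ndarray:
        """0-based day-within-session of each occasion column."""
        return np.concatenate([np.arange(k) for k in self.occasions_per_session])

    def session_slice(self, t: int) -> slice:
        """Column slice of session ``t`` (0-based) in the encounter matrix."""
        starts = np.concatenate([[0], np.cumsum(self.occasions_per_session)])
        return slice(int(starts[t]), int(starts[t + 1]))

    def occasion_date(self, occasion: int) -> date:
        """Calendar date of a 0-based global occasion index."""
        t = int(self.occasion_session[occasion])
        return self.session_start_dates[t] + timedelta(int(self.occasion_day[occasion]))

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sessions = raw["sessions"]
        return cls(
            session_labels=tuple(str(s["label"]) for s in sessions),
            session_start_dates=tuple(
                s["start"] if isinstance(s["start"], date) else date.fromisoformat(s["start"])
                for s in sessions
            ),
            occasions_per_session=tuple(int(s["occasions"]) for s in sessions),
            treatment_start_session=int(raw.get("treatment_start_session", 2)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "sessions": [
                {"label": lab, "start": d.isoformat(), "occasions": k}
                for lab, d, k in zip(
                    self.session_labels, self.session_start_dates, self.occasions_per_session
                )
            ],
            "treatment_start_session": self.treatment_start_session,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class EncounterData:
    """Individual capture histories with covariates and sparse masses.

    ``encounters`` is a binary matrix of shape ``(n_individuals,
    total_occasions)`` whose columns are grouped by session.
    ``observed_mass`` has shape ``(n_individuals, n_sessions)`` in grams,
    NaN where the individual was not weighed in that session.
    """

    design: StudyDesign
    ids: list[str]
    sex: np.ndarray          # unicode, "F"/"M"
    location: np.ndarray     # unicode, e.g. "Barwik"
    plot_role: np.ndarray    # "treatment"/"control"
    cohort: np.ndarray       # unicode label
    encounters: np.ndarray   # (n, total_occasions) int8
    observed_mass: np.ndarray  # (n, n_sessions) float, NaN = unobserved

    def __post_init__(self) -> None:
        self.encounters = np.asarray(self.encounters, dtype=np.int8)
        self.observed_mass = np.asarray(self.observed_mass, dtype=float)
        n = len(self.ids)
        if self.encounters.shape != (n, self.design.total_occasions):
            raise ValueError("encounter matrix shape mismatch")
        if self.observed_mass.shape != (n, self.design.n_sessions):
            raise ValueError("observed_mass shape mismatch")
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if not np.isin(self.encounters, (0, 1)).all():
            raise ValueError("encounter matrix must be binary")
        never = np.flatnonzero(self.encounters.sum(axis=1) == 0)
        if never.size:
            raise ValueError(
                f"individual(s) with no capture: {[self.ids[i] for i in never[:5]]}"
            )
        # a mass may only exist in sessions with >= 1 capture
        cap = self.captured_by_session()
        bad = np.argwhere(~np.isnan(self.observed_mass) & ~cap)
        if bad.size:
            i, t = bad[0]
            raise ValueError(
                f"mass observed without capture: individual {self.ids[i]}, session {t + 1}"
            )

    # -- derived views -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def captured_by_session(self) -> np.ndarray:
        """Boolean (n, n_sessions): captured at least once in session."""
        T = self.design.n_sessions
        out = np.zeros((self.n_individuals, T), dtype=bool)
        for t in range(T):
            out[:, t] = self.encounters[:, self.design.session_slice(t)].any(axis=1)
        return out

    def first_capture(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based (session, global occasion) of each individual's first capture."""
        occ = self.encounters.argmax(axis=1)
        return self.design.occasion_session[occ], occ

    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": self.sex,
                "location": self.location,
                "plot": self.plot_role,
                "cohort": self.cohort,
            }
        )

    def subset(self, idx: np.ndarray) -> "EncounterData":
        idx = np.asarray(idx)
        return dataclasses.replace(
            self,
            ids=[self.ids[i] for i in idx],
            sex=self.sex[idx],
            location=self.location[idx],
            plot_role=self.plot_role[idx],
            cohort=self.cohort[idx],
            encounters=self.encounters[idx],
            observed_mass=self.observed_mass[idx],
        )


@dataclass(frozen=True)
class SummaryStats:
    total_captures: int
    n_individuals: int
    n_recaptured: int
    frac_recaptured: float
    session_plot_counts_mean: float
    session_plot_counts_sd: float
    session_plot_counts_min: int
    session_plot_counts_max: int
    mean_sessions_per_individual: float
    mean_occasions_per_individual: float
    n_single_session: int
    frac_single_session: float
    mean_span_days: float
    max_span_days: int

    def to_frame(self) -> pd.DataFrame:
        d = dataclasses.asdict(self)
        return pd.DataFrame({"statistic": list(d), "value": list(d.values())})


REQUIRED_COLUMNS = ("id", "location", "plot", "session", "occasion", "sex", "mass_g")


def read_long_csv(path, design: StudyDesign) -> EncounterData:
    """Read one-row-per-capture long CSV into an :class:`EncounterData`.

    Duplicate ``(id, occasion)`` rows collapse to a single capture; the
    session's mass is taken from the first record of that session.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if "cohort" not in df.columns:
        df["cohort"] = ""
    df["cohort"] = df["cohort"].fillna("").astype(str)

    T = design.n_sessions
    bad = df[(df["session"] < 1) | (df["session"] > T)]
    if len(bad):
        raise ValueError(f"unknown session at row {bad.index[0]}: {bad.iloc[0]['session']}")
    kmax = np.asarray(design.occasions_per_session)[df["session"].to_numpy() - 1]
    bad = df[(df["occasion"] < 1) | (df["occasion"].to_numpy() > kmax)]
    if len(bad):
        raise ValueError(f"unknown occasion at row {bad.index[0]}: {bad.iloc[0]['occasion']}")

    plots = df.groupby("id")["plot"].nunique()
    multi = plots[plots > 1]
    if len(multi):
        raise ValueError(f"individual in two plots: {multi.index[0]}")

    ids = sorted(df["id"].unique())
    idx = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    starts = np.concatenate([[0], np.cumsum(design.occasions_per_session)])

    enc = np.zeros((n, design.total_occasions), dtype=np.int8)
    mass = np.full((n, T), np.nan)
    rows = df.set_index("id", drop=False)
    for _, r in df.iterrows():
        i = idx[r["id"]]
        t = int(r["session"]) - 1
        o = starts[t] + int(r["occasion"]) - 1
        enc[i, o] = 1
        if np.isnan(mass[i, t]) and pd.notna(r["mass_g"]):
            mass[i, t] = float(r["mass_g"])

    first = df.drop_duplicates("id").set_index("id")
    meta = first.loc[ids]
    return EncounterData(
        design=design,
        ids=list(ids),
        sex=meta["sex"].to_numpy(dtype="U1"),
        location=meta["location"].to_numpy(dtype="U32"),
        plot_role=meta["plot"].to_numpy(dtype="U16"),
        cohort=meta["cohort"].to_numpy(dtype="U32"),
        encounters=enc,
        observed_mass=mass,
    )


def write_long_csv(data: EncounterData, path) -> None:
    """Write the long-format inverse of :func:`read_long_csv`."""
    design = data.design
    recs = []
    occ_sess = design.occasion_session
    occ_day = design.occasion_day
    for i, ident in enumerate(data.ids):
        for o in np.flatnonzero(data.encounters[i]):
            t = int(occ_sess[o])
            first_occ_of_sess = data.encounters[i, design.session_slice(t)].argmax()
            m = data.observed_mass[i, t]
            recs.append(
                {
                    "id": ident,
                    "location": data.location[i],
                    "plot": data.plot_role[i],
                    "session": t + 1,
                    "occasion": int(occ_day[o]) + 1,
                    "sex": data.sex[i],
                    "mass_g": m if (occ_day[o] == first_occ_of_sess and np.isfinite(m)) else np.nan,
                    "cohort": data.cohort[i],
                }
            )
    pd.DataFrame.from_records(recs).to_csv(path, index=False)


def write_encounter_histories(data: EncounterData, path) -> None:
    """Write MARK-style encounter histories: one ``0/1`` string per line,
    followed by covariate columns (id, location, plot, sex, cohort)."""
    with open(path, "w") as fh:
        for i, ident in enumerate(data.ids):
            hist = "".join(map(str, data.encounters[i]))
            fh.write(
                f"{hist} {ident} {data.location[i]} {data.plot_role[i]} "
                f"{data.sex[i]} {data.cohort[i]};\n"
            )


def read_encounter_histories(path, design: StudyDesign) -> EncounterData:
    """Read back the output of :func:`write_encounter_histories`.

    Masses are not representable in the ``.inp`` format and come back NaN.
    """
    ids, sexes, locs, plots, cohorts, rows = [], [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip().rstrip(";")
            if not line:
                continue
            parts = line.split()
            hist, ident, loc, plot, sex = parts[:5]
            cohort = parts[5] if len(parts) > 5 else ""
            rows.append([int(c) for c in hist])
            ids.append(ident)
            locs.append(loc)
            plots.append(plot)
            sexes.append(sex)
            cohorts.append(cohort)
    n = len(ids)
    return EncounterData(
        design=design,
        ids=ids,
        sex=np.array(sexes, dtype="U1"),
        location=np.array(locs, dtype="U32"),
        plot_role=np.array(plots, dtype="U16"),
        cohort=np.array(cohorts, dtype="U32"),
        encounters=np.array(rows, dtype=np.int8),
        observed_mass=np.full((n, design.n_sessions), np.nan),
    )


def summarize(data: EncounterData, design: StudyDesign) -> SummaryStats:
    """Descriptive counts over the capture histories.

    The capture span is in calendar days from the date of the first to the
    date of the last capture, with occasion dates derived from the design.
    """
    enc = data.encounters
    total_captures = int(enc.sum())
    n = data.n_individuals
    cap_sess = data.captured_by_session()
    sessions_per_ind = cap_sess.sum(axis=1)
    n_recaptured = int((enc.sum(axis=1) > 1).sum())

    counts = []
    plot_key = [f"{l}|{p}" for l, p in zip(data.location, data.plot_role)]
    plot_key = np.asarray(plot_key)
    for pk in np.unique(plot_key):
        mask = plot_key == pk
        for t in range(design.n_sessions):
            c = int(cap_sess[mask, t].sum())
            if c > 0:
                counts.append(c)
    counts = np.asarray(counts)

    dates = np.array([design.occasion_date(o).toordinal() for o in range(design.total_occasions)])
    spans = np.empty(n)
    for i in range(n):
        occ = np.flatnonzero(enc[i])
        spans[i] = dates[occ[-1]] - dates[occ[0]]

    n_single = int((sessions_per_ind == 1).sum())
    return SummaryStats(
        total_captures=total_captures,
        n_individuals=n,
        n_recaptured=n_recaptured,
        frac_recaptured=n_recaptured / n,
        session_plot_counts_mean=float(counts.mean()),
        session_plot_counts_sd=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        session_plot_counts_min=int(counts.min()),
        session_plot_counts_max=int(counts.max()),
        mean_sessions_per_individual=float(sessions_per_ind.mean()),
        mean_occasions_per_individual=float(enc.sum(axis=1).mean()),
        n_single_session=n_single,
        frac_single_session=n_single / n,
        mean_span_days=float(spans.mean()),
        max_span_days=int(spans.max()),
    )
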