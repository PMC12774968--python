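"""Data model, I/O round trips, and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from volecmr.capture_data import (
    EncounterData,
    read_encounter_histories,
    read_long_csv,
    summarize,
    write_encounter_histories,
    write_long_csv,
)
from volecmr.synthetic import default_config, simulate


def test_triple_capture_collapses_to_one_individual(tiny_design, tmp_path):
    df = pd.DataFrame(
        {
            "id": ["v1", "v1", "v1"],
            "location": ["Barwik"] * 3,
            "plot": ["control"] * 3,
            "session": [1, 1, 2],
            "occasion": [1, 2, 1],
            "sex": ["F"] * 3,
            "mass_g": [20.0, 21.0, 22.5],
        }
    )
    path = tmp_path / "d.csv"
    df.to_csv(path, index=False)
    data = read_long_csv(path, tiny_design)
    assert data.n_individuals == 1
    assert data.encounters.sum() == 3
    # session mass from the first record of the session
    assert data.observed_mass[0, 0] == 20.0
    assert data.observed_mass[0, 1] == 22.5


def test_duplicate_rows_collapse_to_single_capture(tiny_design, tmp_path):
    df = pd.DataFrame(
        {
            "id": ["v1", "v1"],
            "location": ["Barwik"] * 2,
            "plot": ["control"] * 2,
            "session": [1, 1],
            "occasion": [1, 1],
            "sex": ["F"] * 2,
            "mass_g": [20.0, 24.0],
        }
    )
    path = tmp_path / "d.csv"
    df.to_csv(path, index=False)
    data = read_long_csv(path, tiny_design)
    assert data.encounters.sum() == 1
    assert data.observed_mass[0, 0] == 20.0


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda df: df.drop(columns=["sex"]), "missing required column"),
        (lambda df: df.assign(session=[5]), "unknown session"),
        (lambda df: df.assign(occasion=[3]), "unknown occasion"),
    ],
)
def test_reader_rejects_malformed_files(tiny_design, tmp_path, mutate, message):
    df = pd.DataFrame(
        {
            "id": ["v1"], "location": ["Barwik"], "plot": ["control"],
            "session": [1], "occasion": [1], "sex": ["F"], "mass_g": [20.0],
        }
    )
    path = tmp_path / "d.csv"
    mutate(df).to_csv(path, index=False)
    with pytest.raises(ValueError, match=message):
        read_long_csv(path, tiny_design)


def test_reader_rejects_individual_in_two_plots(tiny_design, tmp_path):
    df = pd.DataFrame(
        {
            "id": ["v1", "v1"], "location": ["Barwik"] * 2,
            "plot": ["control", "treatment"], "session": [1, 2],
            "occasion": [1, 1], "sex": ["F"] * 2, "mass_g": [20.0, 21.0],
        }
    )
    path = tmp_path / "d.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="two plots"):
        read_long_csv(path, tiny_design)


def test_long_csv_round_trip_on_synthetic_data(tmp_path):
    cfg = default_config(n0_treatment=3, n0_control=3, recruits_per_interval=1)
    data, _ = simulate(cfg, seed=42)
    data = data.subset(np.arange(min(10, data.n_individuals)))
    path = tmp_path / "long.csv"
    write_long_csv(data, path)
    back = read_long_csv(path, cfg.design)
    order = [back.ids.index(i) for i in data.ids]
    back = back.subset(np.array(order))
    np.testing.assert_array_equal(back.encounters, data.encounters)
    np.testing.assert_array_equal(back.sex, data.sex)
    np.testing.assert_array_equal(back.plot_role, data.plot_role)
    np.testing.assert_allclose(back.observed_mass, data.observed_mass)


def test_encounter_history_file_round_trip(four_vole_data, tmp_path):
    path = tmp_path / "hist.inp"
    write_encounter_histories(four_vole_data, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 4
    assert lines[0].startswith("1110 ")  # A captured occasions 1,2,3 of 4
    back = read_encounter_histories(path, four_vole_data.design)
    np.testing.assert_array_equal(back.encounters, four_vole_data.encounters)
    np.testing.assert_array_equal(back.location, four_vole_data.location)


def test_all_zero_history_rejected(tiny_design):
    with pytest.raises(ValueError, match="no capture"):
        EncounterData(
            design=tiny_design,
            ids=["x"],
            sex=np.array(["F"]),
            location=np.array(["Barwik"], dtype="U32"),
            plot_role=np.array(["control"], dtype="U16"),
            cohort=np.array([""], dtype="U32"),
            encounters=np.zeros((1, 4), dtype=np.int8),
            observed_mass=np.full((1, 2), np.nan),
        )


def test_mass_without_capture_rejected(tiny_design):
    with pytest.raises(ValueError, match="mass observed without capture"):
        EncounterData(
            design=tiny_design,
            ids=["x"],
            sex=np.array(["F"]),
            location=np.array(["Barwik"], dtype="U32"),
            plot_role=np.array(["control"], dtype="U16"),
            cohort=np.array([""], dtype="U32"),
            encounters=np.array([[1, 0, 0, 0]], dtype=np.int8),
            observed_mass=np.array([[20.0, 21.0]]),
        )


def test_summary_matches_hand_enumeration(four_vole_data, tiny_design):
    s = summarize(four_vole_data, tiny_design)
    assert s.total_captures == 7
    assert s.n_individuals == 4
    assert s.n_recaptured == 2 and s.frac_recaptured == 0.5
    # session-plot cells with captures: control s1 = {A,B}, control s2 = {A,C},
    # treatment s1 = {D}
    assert s.session_plot_counts_min == 1 and s.session_plot_counts_max == 2
    assert s.session_plot_counts_mean == pytest.approx(5 / 3)
    assert s.mean_sessions_per_individual == pytest.approx(1.25)
    assert s.mean_occasions_per_individual == pytest.approx(1.75)
    assert s.n_single_session == 3 and s.frac_single_session == 0.75
    # spans: A = 61 days, B = 0, C = 1, D = 0
    assert s.max_span_days == 61
    assert s.mean_span_days == pytest.approx(62 / 4)


def test_single_capture_summary(tiny_design):
    data = EncounterData(
        design=tiny_design,
        ids=["x"],
        sex=np.array(["F"]),
        location=np.array(["Barwik"], dtype="U32"),
        plot_role=np.array(["control"], dtype="U16"),
        cohort=np.array([""], dtype="U32"),
        encounters=np.array([[0, 1, 0, 0]], dtype=np.int8),
        observed_mass=np.array([[21.0, np.nan]]),
    )
    s = summarize(data, tiny_design)
    assert s.total_captures == 1
    assert s.frac_recaptured == 0.0
    assert s.max_span_days == 0


def test_summary_invariants_and_permutation_invariance(four_vole_data, tiny_design):
    s = summarize(four_vole_data, tiny_design)
    assert s.n_recaptured <= s.n_individuals
    assert s.total_captures >= s.n_individuals
    perm = four_vole_data.subset(np.array([2, 0, 3, 1]))
    assert summarize(perm, tiny_design) == s
    # singletons + multi-session individuals partition the population
    n_multi = s.n_individuals - s.n_single_session
    assert n_multi + s.n_single_session == s.n_individuals
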