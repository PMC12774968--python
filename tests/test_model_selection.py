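"""Candidate enumeration, information criteria, and averaging machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from volecmr.cmr_model import FittedModel, ModelSpec
from volecmr.model_selection import (
    aicc,
    akaike_weights,
    generate_candidates,
    model_average,
    pvalue,
    rank_models,
    relative_survival,
)


# ------------------------------------------------------------ candidate sets


def test_mandatory_only_pool_yields_time_form_variants():
    specs = generate_candidates(
        survival_optional=(), capture_optional=(),
        survival_time_forms=("categorical", "spline-3"),
        capture_time_forms=("categorical",),
    )
    assert len(specs) == 2
    assert all(s.check_mandatory() for s in specs)


def test_one_optional_term_doubles_candidates():
    specs = generate_candidates(
        survival_optional=("treatment",), capture_optional=(),
        survival_time_forms=("categorical",), capture_time_forms=("categorical",),
    )
    assert len(specs) == 2


def test_candidate_count_matches_independent_enumeration():
    """Independent combinatorial count: closed subsets of the optional
    survival pool {treatment, treatment:time, treatment:mass} under
    marginality (each interaction forces 'treatment'; 'time' and 'mass'
    are already mandatory) times time-form expansion."""
    s_opt = ("treatment", "treatment:time", "treatment:mass")
    closed = set()
    for r in range(len(s_opt) + 1):
        for combo in itertools.combinations(s_opt, r):
            s = set(combo)
            if s & {"treatment:time", "treatment:mass"}:
                s.add("treatment")
            closed.add(frozenset(s))
    expected = len(closed) * 2 * 1  # 2 survival time forms x 1 capture form
    specs = generate_candidates(
        survival_optional=s_opt, capture_optional=(),
        survival_time_forms=("categorical", "spline-3"),
        capture_time_forms=("categorical",),
    )
    assert len(specs) == expected == 10
    # deterministic order
    again = generate_candidates(
        survival_optional=s_opt, capture_optional=(),
        survival_time_forms=("categorical", "spline-3"),
        capture_time_forms=("categorical",),
    )
    assert [s.label() for s in specs] == [s.label() for s in again]


def test_interactions_imply_their_margins():
    specs = generate_candidates(
        survival_optional=("treatment", "treatment:time"),
        capture_optional=("day", "location:day"),
    )
    for s in specs:
        for term in s.survival_terms + s.capture_terms:
            parts = term.split(":")
            if len(parts) > 1:
                component = s.survival_terms if term in s.survival_terms else s.capture_terms
                for part in parts:
                    assert part in component


def test_term_cap_enforced():
    with pytest.raises(ValueError, match="terms"):
        ModelSpec(survival_terms=tuple(f"t{i}" for i in range(12)))


# -------------------------------------------------------------------- criteria


def test_aicc_values():
    assert aicc(-100.0, 0, 50) == pytest.approx(200.0)
    assert aicc(-100.0, 5, 100) == pytest.approx(210 + 60 / 94)
    for k in range(1, 6):
        assert aicc(-10.0, k, 40) > 20 + 2 * k  # AICc > AIC
    with pytest.raises(ValueError):
        aicc(-10.0, 10, 11)


def test_akaike_weights_formula_and_invariance():
    np.testing.assert_allclose(akaike_weights([3.0, 3.0]), [0.5, 0.5])
    w = akaike_weights([100.0, 102.0])
    assert w[0] == pytest.approx(0.731, abs=5e-4)
    assert w[1] == pytest.approx(0.269, abs=5e-4)
    np.testing.assert_allclose(akaike_weights([0.0, 2.0]), w, atol=1e-12)


@given(st.lists(st.floats(0, 500), min_size=1, max_size=8))
def test_akaike_weights_sum_to_one(values):
    assert akaike_weights(values).sum() == pytest.approx(1.0)


# ----------------------------------------------------------------- averaging


def _fake_model(beta, vcov, aicc_val=100.0, spec=None):
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return FittedModel(
        spec=spec or ModelSpec(),
        beta=beta,
        vcov=np.atleast_2d(np.asarray(vcov, dtype=float)),
        loglik=-50.0,
        k=len(beta),
        n_eff=100,
        aicc=aicc_val,
        converged=True,
        boundary=False,
        names=["b0"] * len(beta),
    )


def test_ranked_set_screens_boundary_models():
    good = _fake_model([0.0], [[1.0]], aicc_val=100.0)
    bad = _fake_model([0.0], [[1.0]], aicc_val=90.0)
    bad.boundary = True
    ranked = rank_models([good, bad])
    assert ranked.n_screened_out == 1
    assert ranked.models == [good]
    assert ranked.weights.sum() == pytest.approx(1.0)


def test_single_model_draw_mean_near_point_estimate():
    m = _fake_model([2.0], [[0.25]])
    ranked = rank_models([m])
    pred = model_average(ranked, lambda mod, b: b[:, 0], n_draws=4000, seed=0)
    assert pred.point == pytest.approx(2.0, abs=3 * 0.5 / np.sqrt(4000))


def test_two_identical_models_match_single_model_distribution():
    m1 = _fake_model([1.0], [[0.04]])
    m2 = _fake_model([1.0], [[0.04]])
    both = model_average(
        rank_models([m1, m2]), lambda mod, b: b[:, 0], n_draws=4000, seed=1
    )
    one = model_average(rank_models([m1]), lambda mod, b: b[:, 0], n_draws=4000, seed=2)
    assert both.point == pytest.approx(one.point, abs=0.02)
    assert both.ci_high - both.ci_low == pytest.approx(one.ci_high - one.ci_low, abs=0.05)


def test_degenerate_covariance_gives_zero_width_interval():
    m = _fake_model([1.5], [[0.0]])
    pred = model_average(rank_models([m]), lambda mod, b: b[:, 0], n_draws=500, seed=3)
    assert pred.ci_low == pred.ci_high == pytest.approx(1.5)


# ------------------------------------------------------------------- p-values


def test_pvalue_all_draws_at_null_is_one():
    assert pvalue(np.full(200, 3.0), 3.0) == 1.0


def test_pvalue_gaussian_quantile():
    rng = np.random.default_rng(0)
    y = rng.normal(0.0, 1.0, 200000)
    null = np.percentile(y, 2.5)
    assert pvalue(y, null) == pytest.approx(0.05, abs=0.01)


def test_pvalue_far_null_reports_resolution_floor():
    y = np.linspace(0, 1, 1000)
    p = pvalue(y, 50.0)
    assert 0 < p < 2 / 1000


def test_pvalue_in_unit_interval_and_alternative_reading():
    rng = np.random.default_rng(1)
    y = rng.normal(0, 1, 500)
    for null in (-3.0, 0.0, 0.5, 4.0):
        for alt in ("from_mean", "from_null"):
            p = pvalue(y, null, alternative=alt)
            assert 0 < p <= 1


# ----------------------------------------------------------- relative survival


def test_relative_survival_identical_draws():
    y = np.random.default_rng(2).uniform(0.5, 0.9, 1000)
    rel = relative_survival(y, y)
    assert rel.point == pytest.approx(1.0)
    assert rel.p == 1.0


def test_relative_survival_deterministic_ratio():
    t = np.full(100, 0.9)
    c = np.full(100, 0.75)
    rel = relative_survival(t, c)
    assert rel.point == pytest.approx(1.2)


def test_relative_survival_excludes_zero_control():
    t = np.array([0.9, 0.9, 0.9])
    c = np.array([0.0, 0.45, 0.45])
    rel = relative_survival(t, c)
    assert rel.n_excluded == 1
    assert rel.point == pytest.approx(2.0)
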