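"""Scoring engine: stiffness index, band lookup, breakdown, categories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ease_score import (
    Band,
    ConfigError,
    DomainError,
    EchoMeasurements,
    MissingDataError,
    ThresholdConfig,
    categorize,
    compute_breakdown,
    default_config,
    fig6_config,
    score_parameter,
    stiffness_index,
    validate_config,
)
from ease_score.ease import _three_band, _two_band, replace

from conftest import random_measurements


# ---------------------------------------------------------------------------
# stiffness index
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ee, lasr, expected", [
    (10, 20, 0.5),    # exactly the normal/abnormal boundary
    (12, 30, 0.4),
    (14, 10, 1.4),
])
def test_stiffness_index_arithmetic(ee, lasr, expected):
    assert stiffness_index(ee, lasr) == pytest.approx(expected, abs=0)


@pytest.mark.parametrize("ee, lasr", [(0, 20), (-1, 20), (10, 0), (10, -5),
                                      (math.nan, 20), (10, math.inf)])
def test_stiffness_index_rejects_non_positive(ee, lasr):
    with pytest.raises(DomainError):
        stiffness_index(ee, lasr)


def test_stiffness_index_names_offending_field():
    with pytest.raises(DomainError, match="lasr_pct"):
        stiffness_index(10, -1)
    with pytest.raises(DomainError, match="e_over_eprime"):
        stiffness_index(-1, 20)


def test_stiffness_equals_direct_division_to_full_precision():
    rng = np.random.default_rng(0)
    for _ in range(200):
        ee = rng.uniform(1, 30)
        lasr = rng.uniform(2, 45)
        assert stiffness_index(ee, lasr) == ee / lasr


# ---------------------------------------------------------------------------
# per-parameter band lookup
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("param, value, expected", [
    ("lasr", 25.0, 0),       # normal: > 23 %
    ("lasr", 18.0, 1),       # borderline 15-23 %
    ("lasr", 12.0, 2),       # advanced remodeling < 15 %
    ("lasr", 23.0, 1),       # edge: "greater than 23" -> 23 is borderline
    ("lasr", 15.0, 1),       # edge: 15 belongs to the borderline band
    ("pa_tdi", 100.0, 0),
    ("pa_tdi", 135.0, 1),    # implicit intermediate band 120-150 ms
    ("pa_tdi", 120.0, 1),    # "below 120" normal -> 120 is intermediate
    ("pa_tdi", 150.0, 1),    # "above 150" abnormal -> 150 still intermediate
    ("pa_tdi", 151.0, 2),
    ("lavi", 30.0, 0),
    ("lavi", 40.0, 1),
    ("lavi", 50.0, 2),       # severe dilation > 48 mL/m2
    ("lavi", 48.0, 1),
    ("stiffness", 0.5, 0),   # "below or equal to 0.5" is normal
    ("stiffness", 0.51, 2),
    ("e_over_eprime", 14.0, 0),
    ("e_over_eprime", 14.5, 2),
    ("lasct", 8.0, 0),       # normal above 6 %
    ("lasct", 6.0, 2),
    ("lasct", 4.0, 2),
])
def test_score_parameter_default_bands(cfg, param, value, expected):
    assert score_parameter(value, cfg.bands[param]) == expected


def test_score_parameter_rejects_bad_values(cfg):
    for bad in (0.0, -3.0, math.nan, math.inf):
        with pytest.raises(DomainError):
            score_parameter(bad, cfg.bands["lasr"])


def test_score_parameter_uncovered_value_is_config_error():
    bands = (Band(0.0, 10.0, 0, hi_closed=False),)  # does not reach inf
    with pytest.raises(ConfigError):
        score_parameter(20.0, bands)


# ---------------------------------------------------------------------------
# full breakdown
# ---------------------------------------------------------------------------

def test_all_normal_patient_scores_zero(cfg):
    bd = compute_breakdown(
        EchoMeasurements(lasr_pct=28, pa_tdi_ms=100, lavi_ml_m2=30,
                         e_over_eprime=8, lasct_pct=10), cfg)
    assert bd.total == 0
    assert bd.category == "low"
    assert all(v == 0 for v in bd.points.values())


def test_all_worst_patient_scores_twelve(cfg):
    bd = compute_breakdown(
        EchoMeasurements(lasr_pct=12, pa_tdi_ms=160, lavi_ml_m2=52,
                         e_over_eprime=16, lasct_pct=4), cfg)
    assert bd.total == 12
    assert bd.category == "high"


def test_mixed_patient_band_by_band(cfg):
    # stiffness 10/18 ~ 0.556 > 0.5 -> 2; points 1+1+1+2+0+0 = 5
    bd = compute_breakdown(
        EchoMeasurements(lasr_pct=18, pa_tdi_ms=135, lavi_ml_m2=40,
                         e_over_eprime=10, lasct_pct=8), cfg)
    assert bd.points == {"lasr": 1, "pa_tdi": 1, "lavi": 1,
                         "stiffness": 2, "e_over_eprime": 0, "lasct": 0}
    assert bd.total == 5
    assert bd.category == "intermediate"


def test_breakdown_total_is_sum_of_parts(cfg):
    rng = np.random.default_rng(1)
    for _ in range(300):
        bd = compute_breakdown(random_measurements(rng), cfg)
        assert bd.total == sum(bd.points.values())
        assert 0 <= bd.total <= 12


def test_scoring_is_pure(cfg):
    m = EchoMeasurements(17.3, 141.2, 43.9, 11.7, 5.1)
    a, b = compute_breakdown(m, cfg), compute_breakdown(m, cfg)
    assert a == b


# missing-LASct policies -----------------------------------------------------

def _no_lasct():
    return EchoMeasurements(lasr_pct=18, pa_tdi_ms=135, lavi_ml_m2=40,
                            e_over_eprime=10, lasct_pct=None)


def test_missing_lasct_refused_by_default(cfg):
    with pytest.raises(MissingDataError, match="lasct"):
        compute_breakdown(_no_lasct(), cfg)


def test_missing_lasct_worst_case(cfg):
    bd = compute_breakdown(
        _no_lasct(), replace(cfg, missing_lasct_policy="worst_case"))
    assert bd.points["lasct"] == 2
    assert bd.total == 7
    assert "lasct_imputed_worst_case" in bd.flags


def test_missing_lasct_omit_rescale(cfg):
    # five available params score 5 of a possible 10 -> rescaled 6 of 12
    bd = compute_breakdown(
        _no_lasct(), replace(cfg, missing_lasct_policy="omit_rescale"))
    assert bd.points["lasct"] is None
    assert bd.total == 6
    assert "lasct_omitted_rescaled" in bd.flags


# ---------------------------------------------------------------------------
# categorisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("total, expected", [
    (0, "low"), (3, "low"), (4, "intermediate"), (8, "intermediate"),
    (9, "high"), (12, "high"),
])
def test_categorize_default_boundaries(total, expected):
    assert categorize(total) == expected


def test_categorize_is_total_monotone_step_function():
    order = {"low": 0, "intermediate": 1, "high": 2}
    cats = [categorize(t) for t in range(13)]
    ranks = [order[c] for c in cats]
    assert ranks == sorted(ranks)
    assert set(cats) == {"low", "intermediate", "high"}


def test_categorize_alternate_boundaries():
    # the survival-figure variant: 0-3 / 4-7 / 8-12
    assert categorize(8, (3, 7)) == "high"
    assert categorize(8, (3, 8)) == "intermediate"


@pytest.mark.parametrize("bad", [-1, 13])
def test_categorize_rejects_out_of_range(bad):
    with pytest.raises(DomainError):
        categorize(bad)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

def test_shipped_configs_validate(cfg):
    assert validate_config(cfg) == []
    assert validate_config(fig6_config()) == []


def test_config_with_band_gap_reports_one_coverage_violation(cfg):
    broken_bands = dict(cfg.bands)
    broken_bands["lasr"] = (
        Band(0.0, 15.0, 2, hi_closed=False),
        Band(16.0, 23.0, 1, lo_closed=True, hi_closed=True),  # gap 15-16
        Band(23.0, math.inf, 0, hi_closed=False),
    )
    violations = validate_config(replace(cfg, bands=broken_bands))
    assert sum("gap" in v for v in violations) == 1


def test_config_with_wrong_max_total_reports_violation(cfg):
    shrunk = dict(cfg.bands)
    shrunk["lasct"] = _two_band(6.0, higher_is_worse=False)
    shrunk["lasct"] = tuple(Band(b.lo, b.hi, min(b.points, 1),
                                 b.lo_closed, b.hi_closed)
                            for b in shrunk["lasct"])
    shrunk["stiffness"] = tuple(Band(b.lo, b.hi, 0, b.lo_closed, b.hi_closed)
                                for b in cfg.bands["stiffness"])
    violations = validate_config(replace(cfg, bands=shrunk))
    assert any("max attainable total is 9" in v for v in violations)


def test_config_with_double_covered_edge_flagged(cfg):
    bands = dict(cfg.bands)
    bands["lasct"] = (Band(0.0, 6.0, 2, hi_closed=True),
                      Band(6.0, math.inf, 0, lo_closed=True,
                           hi_closed=False))
    violations = validate_config(replace(cfg, bands=bands))
    assert any("twice" in v for v in violations)


def test_config_bad_category_boundaries_flagged(cfg):
    violations = validate_config(replace(cfg, category_boundaries=(8, 3)))
    assert any("category boundaries" in v for v in violations)


# ---------------------------------------------------------------------------
# monotonicity and oracle equivalence
# ---------------------------------------------------------------------------

_WORSEN = {
    # parameter -> (attribute, direction of worsening)
    "lasr_pct": -1.0,
    "pa_tdi_ms": +1.0,
    "lavi_ml_m2": +1.0,
    "e_over_eprime": +1.0,
    "lasct_pct": -1.0,
}


@settings(max_examples=300, deadline=None)
@given(
    lasr=st.floats(3, 45), patdi=st.floats(60, 220), lavi=st.floats(15, 75),
    ee=st.floats(3, 25), lasct=st.floats(1, 20),
    which=st.sampled_from(sorted(_WORSEN)),
    delta=st.floats(0.01, 15),
)
def test_worsening_any_parameter_never_lowers_score(
        lasr, patdi, lavi, ee, lasct, which, delta):
    cfg = default_config()
    base = dict(lasr_pct=lasr, pa_tdi_ms=patdi, lavi_ml_m2=lavi,
                e_over_eprime=ee, lasct_pct=lasct)
    worse = dict(base)
    worse[which] = base[which] + _WORSEN[which] * delta
    if worse[which] <= 0.5:  # keep strictly positive and physiologic
        worse[which] = 0.5
        if worse[which] >= base[which]:
            return
    t0 = compute_breakdown(EchoMeasurements(**base), cfg).total
    t1 = compute_breakdown(EchoMeasurements(**worse), cfg).total
    assert t1 >= t0
    order = {"low": 0, "intermediate": 1, "high": 2}
    c0 = compute_breakdown(EchoMeasurements(**base), cfg).category
    c1 = compute_breakdown(EchoMeasurements(**worse), cfg).category
    assert order[c1] >= order[c0]


def naive_score(m: EchoMeasurements) -> int:
    """Independent oracle: every default threshold inlined as a comparison."""
    stiff = m.e_over_eprime / m.lasr_pct
    pts = 0
    pts += 2 if m.lasr_pct < 15 else (1 if m.lasr_pct <= 23 else 0)
    pts += 2 if m.pa_tdi_ms > 150 else (1 if m.pa_tdi_ms >= 120 else 0)
    pts += 2 if m.lavi_ml_m2 > 48 else (1 if m.lavi_ml_m2 >= 34 else 0)
    pts += 2 if stiff > 0.5 else 0
    pts += 2 if m.e_over_eprime > 14 else 0
    pts += 2 if m.lasct_pct <= 6 else 0
    return pts


def test_breakdown_matches_naive_oracle_on_1000_random_patients(cfg):
    rng = np.random.default_rng(123)
    for _ in range(1000):
        m = random_measurements(rng)
        assert compute_breakdown(m, cfg).total == naive_score(m)
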