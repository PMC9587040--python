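"""Cohort construction: eBMI, exclusions, onset durations, drug grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srs_signal.cohort import (AnalysisCase, build_analysis_table,
                               build_tto_table, classify_ebmi, compute_ebmi,
                               drugs_of_interest, ebmi_outlier_bounds,
                               frequency_stratum, intermediate_value,
                               parse_band, quantile, tabulate_outcomes)
from srs_signal.synthetic_data import SimulationConfig, simulate


# -- band arithmetic -------------------------------------------------------

@pytest.mark.parametrize("band, expected", [
    ("160-169", 165), ("50-59", 55), ("40-49", 45), ("<10", 5),
    ("100-109", 105),
])
def test_intermediate_value_is_lower_bound_plus_five(band, expected):
    assert intermediate_value(band) == expected


@pytest.mark.parametrize("band", ["", "abc", "160-170", "169-160", "160"])
def test_unparseable_bands_rejected(band):
    with pytest.raises(ValueError):
        intermediate_value(band)


@given(st.integers(min_value=0, max_value=20))
@settings(deadline=None)
def test_band_roundtrip(decade):
    lo = decade * 10
    assert parse_band(f"{lo}-{lo + 9}") == (lo, lo + 9)


# -- eBMI ------------------------------------------------------------------

def test_ebmi_worked_example():
    assert compute_ebmi("160-169", "50-59") == 20.2


def test_ebmi_hand_arithmetic():
    # 45 kg / 1.55 m^2 = 18.73 -> 18.7
    assert compute_ebmi("150-159", "40-49") == 18.7


def test_ebmi_monotone_in_weight_at_fixed_height():
    weights = [f"{lo}-{lo + 9}" for lo in range(10, 100, 10)]
    values = [compute_ebmi("160-169", w) for w in weights]
    assert values == sorted(values)
    assert len(set(values)) == len(values)


@pytest.mark.parametrize("ebmi, expected", [
    (18.4, "underweight"), (18.5, "normal"), (24.9, "normal"),
    (25.0, "obese"), (20.2, "normal"),
])
def test_ebmi_class_boundaries_half_open(ebmi, expected):
    assert classify_ebmi(ebmi) == expected


# -- quantiles and outlier bounds ------------------------------------------

def _oracle_quantile(values, p):
    # independent (n+1)p order-statistic interpolation
    xs = sorted(values)
    n = len(xs)
    h = (n + 1) * p
    k = int(np.floor(h))
    if k < 1:
        return xs[0]
    if k >= n:
        return xs[-1]
    frac = h - k
    return xs[k - 1] + frac * (xs[k] - xs[k - 1])


def test_quantile_matches_order_statistic_oracle():
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 30.0, size=48)
    for p in (0.25, 0.5, 0.75, 0.1, 0.9):
        assert quantile(values, p) == pytest.approx(
            _oracle_quantile(values, p), rel=1e-12)


def test_outlier_bounds_exclude_extreme_value():
    values = list(range(1, 11)) + [100]
    low, high = ebmi_outlier_bounds(values)
    # type-6 quartiles of 11 values: Q1=3, Q3=9, IQR=6
    assert (low, high) == (3 - 9, 9 + 9)
    kept = [v for v in values if low <= v <= high]
    assert 100 not in kept and len(kept) == 10


def test_outlier_bounds_collapse_for_identical_values():
    low, high = ebmi_outlier_bounds([5.0] * 6)
    assert low == high == 5.0


def test_outlier_exclusion_idempotent_inside_bounds():
    values = [18.0, 20.0, 22.0, 24.0, 26.0]
    low, high = ebmi_outlier_bounds(values)
    assert [v for v in values if low <= v <= high] == values


def test_outlier_bounds_need_four_values():
    with pytest.raises(ValueError):
        ebmi_outlier_bounds([1.0, 2.0, 3.0])


# -- analysis table --------------------------------------------------------

@pytest.fixture
def ten_bundles(make_bundle):
    complete = [
        ("B1", "160-169", "50-59"),   # 20.2
        ("B2", "150-159", "50-59"),   # 22.9
        ("B3", "160-169", "60-69"),   # 23.9
        ("B4", "170-179", "60-69"),   # 21.2
        ("B5", "170-179", "70-79"),   # 24.5
        ("B6", "150-159", "40-49"),   # 18.7
        ("B7", "100-109", "90-99"),   # 86.2 -> boxplot outlier
    ]
    bundles = [make_bundle(cid, height_band=h, weight_band=w,
                           reactions=[{"outcome": "Recovered"}]
                           if cid == "B1" else ())
               for cid, h, w in complete]
    bundles.append(make_bundle("M1", sex=None))
    bundles.append(make_bundle("M2", weight_band=None))
    bundles.append(make_bundle("M3", age_band="unknown"))
    return bundles


def test_flowchart_counts_on_hand_fixture(ten_bundles):
    cases, flow = build_analysis_table(ten_bundles, "10056979")
    assert flow.n_input == 10
    assert flow.n_excluded_missing == 3
    assert flow.n_complete == 7
    assert flow.n_excluded_outlier == 1
    assert flow.n_analysis == 6
    assert flow.n_input == flow.n_excluded_missing + flow.n_complete
    assert flow.n_complete == flow.n_excluded_outlier + flow.n_analysis
    assert flow.n_event == 1
    assert {c.case_id for c in cases} == {f"B{i}" for i in range(1, 7)}
    b1 = next(c for c in cases if c.case_id == "B1")
    assert b1.event and b1.outcome == "Recovered"
    assert b1.ebmi == 20.2 and b1.ebmi_class == "normal"
    assert not b1.age_ge60 or b1.age_band == "60-69"


def test_no_missingness_retains_every_case():
    cfg = SimulationConfig(
        n_cases=300, seed=9,
        missing_rate={"sex": 0.0, "age_band": 0.0,
                      "height_band": 0.0, "weight_band": 0.0})
    tables, _ = simulate(cfg)
    from srs_signal.jader_io import bundles_from_frames
    bundles = bundles_from_frames(tables["demo"], tables["drug"],
                                  tables["reac"])
    _, flow = build_analysis_table(bundles, cfg.target_pt_code)
    assert flow.n_excluded_missing == 0
    assert flow.n_analysis + flow.n_excluded_outlier == 300


def test_age_ge60_from_band_lower_bound(make_bundle):
    young = make_bundle("Y", age_band="50-59")
    old = make_bundle("O", age_band="60-69")
    cases, _ = build_analysis_table([young, old], "none")
    by_id = {c.case_id: c for c in cases}
    assert not by_id["Y"].age_ge60
    assert by_id["O"].age_ge60


def test_banded_ebmi_class_tracks_latent_bmi():
    _, truth = simulate(SimulationConfig(n_cases=2000, seed=4))
    cases = truth.cases
    latent_bmi = (cases.latent_weight_kg
                  / (cases.latent_height_cm / 100.0) ** 2)
    latent_class = np.where(latent_bmi < 18.5, "underweight",
                            np.where(latent_bmi < 25.0, "normal", "obese"))
    agreement = (latent_class == cases.ebmi_class).mean()
    assert agreement > 0.8


# -- time-to-onset table ---------------------------------------------------

def test_duration_calendar_arithmetic(make_bundle):
    bundle = make_bundle(
        "T1",
        drugs=[{"drug_name": "aspirin", "start_date": "20200101"}],
        reactions=[{"onset_date": "20200313"}])
    records, n_neg = build_tto_table([bundle], ["T1"], "10056979")
    assert n_neg == 0
    assert len(records) == 1
    assert records[0].duration_days == 72.0


def test_shortest_duration_kept_per_case_drug(make_bundle):
    bundle = make_bundle(
        "T2",
        drugs=[{"drug_name": "aspirin", "start_date": "20200101"},
               {"drug_name": "aspirin", "start_date": "20200212"}],
        reactions=[{"onset_date": "20200313"}])
    records, _ = build_tto_table([bundle], ["T2"], "10056979")
    assert [r.duration_days for r in records] == [30.0]


def test_negative_durations_dropped_and_counted(make_bundle):
    bundle = make_bundle(
        "T3",
        drugs=[{"drug_name": "late", "start_date": "20200401"},
               {"drug_name": "ontime", "start_date": "20200301"}],
        reactions=[{"onset_date": "20200313"}])
    records, n_neg = build_tto_table([bundle], ["T3"], "10056979")
    assert n_neg == 1
    assert [r.drug_name for r in records] == ["ontime"]


def test_same_day_onset_maps_to_half_day(make_bundle):
    bundle = make_bundle(
        "T4",
        drugs=[{"drug_name": "a", "start_date": "20200313"}],
        reactions=[{"onset_date": "20200313"}])
    records, _ = build_tto_table([bundle], ["T4"], "10056979")
    assert records[0].duration_days == 0.5


def test_partial_dates_excluded_from_tto(make_bundle):
    bundle = make_bundle(
        "T5",
        drugs=[{"drug_name": "a", "start_date": "202001"}],
        reactions=[{"onset_date": "20200313"}])
    records, n_neg = build_tto_table([bundle], ["T5"], "10056979")
    assert records == [] and n_neg == 0


def test_all_durations_strictly_positive():
    cfg = SimulationConfig(n_cases=3000, seed=8)
    tables, _ = simulate(cfg)
    from srs_signal.jader_io import bundles_from_frames
    bundles = bundles_from_frames(tables["demo"], tables["drug"],
                                  tables["reac"])
    cases, _ = build_analysis_table(bundles, cfg.target_pt_code)
    records, _ = build_tto_table(
        bundles, [c.case_id for c in cases if c.event], cfg.target_pt_code)
    assert len(records) > 0
    assert all(r.duration_days > 0 for r in records)


# -- drugs of interest and outcomes ----------------------------------------

def _case(cid, drugs, event=True, outcome=None):
    return AnalysisCase(cid, "female", "60-69", True, 20.2, "normal",
                        frozenset(drugs), event, outcome)


def test_drug_frequency_threshold_and_strata():
    cases = []
    for i in range(4):
        cases.append(_case(f"a{i}", ["rare"]))
    for i in range(5):
        cases.append(_case(f"b{i}", ["five"]))
    for i in range(128):
        cases.append(_case(f"c{i}", ["common"]))
    for i in range(50):
        cases.append(_case(f"n{i}", ["nonevent_drug"], event=False))
    groups = drugs_of_interest(cases).set_index("drug")
    assert "rare" not in groups.index           # 4 event cases < 5
    assert "nonevent_drug" not in groups.index  # non-event exposure ignored
    assert groups.loc["five", "stratum"] == "5-9"
    assert groups.loc["common", "stratum"] == ">100"
    assert groups.loc["common", "n_cases"] == 128


@pytest.mark.parametrize("n, stratum", [
    (5, "5-9"), (9, "5-9"), (10, "10-19"), (19, "10-19"),
    (20, "20-100"), (100, "20-100"), (101, ">100"), (128, ">100"),
])
def test_frequency_bin_edges(n, stratum):
    assert frequency_stratum(n) == stratum


def test_outcome_tabulation():
    cases = [_case("o1", [], outcome="Recovered"),
             _case("o2", [], outcome="Recovered"),
             _case("o3", [], outcome="Death"),
             _case("o4", [], event=False, outcome="Improved")]
    counts = tabulate_outcomes(cases)
    assert list(counts.values()) == [0, 2, 0, 0, 0, 1]
    assert sum(counts.values()) == 3  # only event cases with outcomes


def test_outcomes_all_zero_without_events():
    counts = tabulate_outcomes([_case("x", [], event=False)])
    assert all(v == 0 for v in counts.values())
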