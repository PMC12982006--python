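"""Facility-year tallies, volume/MAD filters, profiles, and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import acsbalance as ab
from acsbalance import metrics as fm
from acsbalance.registry import LT34_DAYS, OPTIMAL_INTERVALS, TERM_DAYS

from test_registry import base_row, frame


# ---------------------------------------------------------------- tallies

def brute_force_tally(df):
    """Independent per-record tally oracle (pure-python loops)."""
    out = {}
    for _, r in df.iterrows():
        key = (r["facility_id"], r["year"])
        d = out.setdefault(
            key, dict.fromkeys(
                ["n_total", "n_lt34", "n_acs_lt34", "n_acs_optimal_lt34",
                 "n_acs_all", "n_acs_term", "n_tpl_lt34"], 0
            )
        )
        rec = (
            r["acs_checkbox"] == 1
            or not pd.isna(r["acs_dose_mg"])
            or not pd.isna(r["acs_interval"])
        )
        lt34 = r["gestational_age_days"] < LT34_DAYS
        term = r["gestational_age_days"] >= TERM_DAYS
        d["n_total"] += 1
        d["n_lt34"] += lt34
        d["n_acs_all"] += rec
        d["n_acs_lt34"] += rec and lt34
        d["n_acs_optimal_lt34"] += (
            rec and lt34 and r["acs_interval"] in OPTIMAL_INTERVALS
        )
        d["n_acs_term"] += rec and term
        d["n_tpl_lt34"] += lt34 and r["tpl"] == 1
    return out


def test_facility_year_tally_matches_brute_force(small_registry):
    df = small_registry.records.head(400)
    m = fm.compute_facility_year_metrics(df).set_index(["facility_id", "year"])
    oracle = brute_force_tally(df)
    assert set(m.index) == set(oracle)
    for key, d in oracle.items():
        for col, val in d.items():
            assert m.loc[key, col] == val, (key, col)


def test_direct_tally_rates():
    """7/10 covered, 5 optimally timed -> 70% and 50%."""
    rows = []
    for i in range(10):
        acs = i < 7
        rows.append(
            {
                "gestational_age_days": 225.0,
                "acs_checkbox": int(acs),
                "acs_interval": (
                    "<48h" if acs and i < 3 else "48h-7d" if acs and i < 5
                    else "7d-1mo" if acs else np.nan
                ),
            }
        )
    m = fm.compute_facility_year_metrics(frame(rows))
    assert m.loc[0, "acs34_rate"] == 70.0
    assert m.loc[0, "optimal34_rate"] == 50.0


def test_zero_denominator_rates_are_nan():
    m = fm.compute_facility_year_metrics(frame([{"gestational_age_days": 270.0}]))
    assert np.isnan(m.loc[0, "term_acs_prop"])   # no recipients at all
    assert np.isnan(m.loc[0, "acs34_rate"])      # no <34w deliveries
    assert m.loc[0, "acs_all_rate"] == 0.0       # defined: 0 of 1


def test_monotone_nesting_of_ga_counts(small_registry):
    retained, _ = ab.apply_exclusions(small_registry.records)
    m = fm.compute_facility_year_metrics(retained)
    assert (m["n_lt28"] <= m["n_lt32"]).all()
    assert (m["n_lt32"] <= m["n_lt34"]).all()
    assert (m["n_lt34"] <= m["n_lt37"]).all()
    assert (m["n_lt37"] <= m["n_total"]).all()
    assert (m["n_term"] == m["n_total"] - m["n_lt37"]).all()


# ---------------------------------------------------------------- filters

def test_min_preterm_threshold_boundary():
    m = pd.DataFrame(
        {"facility_id": ["a", "b"], "year": [2021, 2021], "n_lt34": [9, 10]}
    )
    kept, removed = fm.filter_min_preterm(m)
    assert list(kept["facility_id"]) == ["b"]
    assert list(removed["facility_id"]) == ["a"]
    kept0, removed0 = fm.filter_min_preterm(m, min_lt34=0)
    assert len(kept0) == 2 and len(removed0) == 0


def test_min_preterm_matches_brute_force(small_registry):
    m = fm.compute_facility_year_metrics(small_registry.records)
    kept, removed = fm.filter_min_preterm(m, min_lt34=5)
    expected = {i for i, v in m["n_lt34"].items() if v >= 5}
    assert set(kept.index) == expected
    assert set(removed.index) == set(m.index) - expected


def test_mad_filter_hand_enumeration():
    """(60, 62, 64, 66, 10): median 62, MAD 2, threshold 5 -> only 10 is out."""
    res = fm.mad_filter([60.0, 62.0, 64.0, 66.0, 10.0])
    assert res.median == 62.0 and res.mad == 2.0
    assert list(res.excluded) == [4]
    assert sorted(res.kept) == [0, 1, 2, 3]


def test_mad_filter_degenerate_cases():
    const = fm.mad_filter([5.0] * 6)
    assert const.mad == 0.0 and len(const.excluded) == 0
    zero_mad = fm.mad_filter([5.0, 5.0, 5.0, 9.0])  # MAD 0: off-median goes
    assert list(zero_mad.excluded) == [3]
    none = fm.mad_filter([60.0, 62.0, 10.0], k=np.inf)
    assert len(none.excluded) == 0
    with pytest.raises(ValueError):
        fm.mad_filter([])


def test_mad_filter_one_sided():
    res = fm.mad_filter([60.0, 62.0, 64.0, 66.0, 10.0, 95.0], two_sided=False)
    assert 4 in res.excluded            # anomalously low
    assert 5 not in res.excluded        # high tail kept in one-sided mode


@given(
    st.lists(st.integers(-100, 100), min_size=3, max_size=30),
    st.integers(-5, 5).filter(lambda a: a != 0),
    st.integers(-50, 50),
)
def test_mad_filter_affine_equivariance(xs, a, b):
    """Filtering a*x + b excludes exactly the same indices as filtering x.

    Integer inputs keep the arithmetic exact, so the check is about the
    filter's equivariance rather than floating-point tie-breaking.
    """
    base = fm.mad_filter([float(x) for x in xs])
    scaled = fm.mad_filter([float(a * x + b) for x in xs])
    assert list(base.excluded) == list(scaled.excluded)


# ---------------------------------------------------------------- profiles

def attrs(fids):
    return pd.DataFrame(
        {
            "facility_id": fids,
            "care_level": ["comprehensive"] * len(fids),
            "in_designated_city": [0] * len(fids),
        }
    )


def test_profile_annual_means_hand_case():
    m = pd.DataFrame(
        {
            "facility_id": ["a", "a"], "year": [2021, 2022],
            "n_total": [100, 200], "n_lt34": [10, 20],
            **{f"n_{c}_lt34": [0, 0] for c in fm.COMPLICATIONS},
            "n_transfer_lt34": [5, 10], "n_cs_lt34": [5, 10],
            "acs34_rate": [60.0, 70.0], "optimal34_rate": [40.0, 50.0],
            "term_acs_prop": [10.0, 14.0], "acs_all_rate": [5.0, 6.0],
        }
    )
    prof = fm.build_profiles(m, attrs(["a"]))
    assert prof.loc[0, "acs34_rate"] == 65.0         # unweighted mean
    assert prof.loc[0, "n_total"] == 150.0
    assert prof.loc[0, "n_years_retained"] == 2
    assert prof.loc[0, "is_comprehensive"] == 1

    single = fm.build_profiles(m.iloc[:1], attrs(["a"]))
    assert single.loc[0, "acs34_rate"] == 60.0       # one year: identity


def test_profiles_match_brute_force_means(small_registry):
    m = fm.compute_facility_year_metrics(small_registry.records)
    prof = fm.build_profiles(m, small_registry.attributes).set_index("facility_id")
    for fid, grp in m.groupby("facility_id"):
        for col in ("acs34_rate", "term_acs_prop", "n_total"):
            expect = grp[col].dropna().mean()
            got = prof.loc[fid, col]
            assert got == pytest.approx(expect, nan_ok=True)


def test_summarize_two_point_sd():
    prof = pd.DataFrame(
        {
            "facility_id": ["a", "b"],
            "n_total": [100.0, 100.0], "n_lt34": [10.0, 10.0],
            "acs34_rate": [50.0, 70.0],
            "optimal34_rate": [30.0, 40.0],
            "term_acs_prop": [np.nan, 12.0],
            "acs_all_rate": [5.0, 6.0],
        }
    )
    s = fm.summarize_cohort(prof)
    assert s.loc["acs34_rate", "mean"] == 60.0
    assert s.loc["acs34_rate", "sd"] == pytest.approx(14.142135, abs=1e-5)
    # undefined values drop from that metric's row, not counted as zero
    assert s.loc["term_acs_prop", "n"] == 1
    assert s.loc["term_acs_prop", "mean"] == 12.0


def test_facility_table_round_trip(tmp_path):
    from acsbalance.facility_table import synthetic_file_s1

    tab = synthetic_file_s1()
    p = tmp_path / "facilities.tsv"
    tab.to_csv(p, sep="\t", index=False)
    back = fm.read_facility_table(p)
    pd.testing.assert_frame_equal(back, tab)
    with pytest.raises(ValueError, match="missing columns"):
        fm.read_facility_table(p, sep=",")  # single mangled column
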