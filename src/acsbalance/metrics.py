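"""Facility-year ACS metrics, volume/outlier filters, and facility profiles.

Four balancing metrics are computed per facility-year, all as percentages:

* ``acs34_rate`` — ACS recipients among deliveries <34 weeks (coverage);
* ``optimal34_rate`` — recipients <34 weeks whose ACS fell within 7 days
  before delivery (timing);
* ``term_acs_prop`` — term deliveries among all ACS recipients
  (overtreatment);
* ``acs_all_rate`` — recipients among all deliveries.

Rates with a zero denominator are undefined (NaN), never 0-by-convention, and
are excluded from means. Facility-years with fewer than 10 deliveries before
34 weeks are removed (small-number instability), and facility-year ACS/34w
rates beyond k median absolute deviations from the median are removed as
reporting outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import (
    COMPLICATIONS,
    LT28_DAYS,
    LT32_DAYS,
    LT34_DAYS,
    LT37_DAYS,
    OPTIMAL_INTERVALS,
    TERM_DAYS,
    is_acs_recipient,
)

#: Facility-level factor columns of a profile (proportions in %, counts as annual means).
FACTOR_COLUMNS = [
    "n_total", "n_lt34",
    "tpl", "hdp", "pprom", "previa", "multiple", "fgr", "abruption",
    "transfer", "cesarean",
]
OUTCOME_COLUMNS = ["acs34_rate", "term_acs_prop", "optimal34_rate", "acs_all_rate"]


def _rate(num: pd.Series, den: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(den > 0, 100.0 * num / np.where(den > 0, den, 1), np.nan),
        index=num.index,
    )


def compute_facility_year_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Tally one row of counts and rates per facility-year.

    ``df`` must already have passed the exclusion cascade. Counts are exact
    tallies; ACS receipt follows :func:`~acsbalance.registry.is_acs_recipient`;
    "optimal" timing means an interval in the two shortest categories.
    """
    ga = df["gestational_age_days"].to_numpy(dtype=float)
    rec = is_acs_recipient(df).to_numpy()
    lt34 = ga < LT34_DAYS
    term = ga >= TERM_DAYS

    # group facility-years once; tally each flag with bincount over the codes
    fac_codes, fac_ids = pd.factorize(df["facility_id"], sort=True)
    years = df["year"].to_numpy(dtype=np.int64)
    yr_codes, yr_vals = pd.factorize(years, sort=True)
    combined = fac_codes.astype(np.int64) * len(yr_vals) + yr_codes
    codes, groups = pd.factorize(combined, sort=True)
    n_groups = len(groups)

    def tally(mask) -> np.ndarray:
        return np.bincount(codes[mask], minlength=n_groups)

    m = pd.DataFrame(
        {
            "facility_id": fac_ids[groups // len(yr_vals)],
            "year": yr_vals[groups % len(yr_vals)],
            "n_total": np.bincount(codes, minlength=n_groups),
            "n_lt37": tally(ga < LT37_DAYS),
            "n_lt34": tally(lt34),
            "n_lt32": tally(ga < LT32_DAYS),
            "n_lt28": tally(ga < LT28_DAYS),
            "n_term": tally(term),
            "n_acs_all": tally(rec),
            "n_acs_lt34": tally(rec & lt34),
            "n_acs_optimal_lt34": tally(
                rec & lt34 & df["acs_interval"].isin(OPTIMAL_INTERVALS).to_numpy()
            ),
            "n_acs_term": tally(rec & term),
            "n_transfer_lt34": tally((df["transfer_in"].to_numpy() == 1) & lt34),
            "n_cs_lt34": tally((df["cesarean"].to_numpy() == 1) & lt34),
            **{
                f"n_{c}_lt34": tally((df[c].to_numpy() == 1) & lt34)
                for c in COMPLICATIONS
            },
        }
    )

    m["acs34_rate"] = _rate(m["n_acs_lt34"], m["n_lt34"])
    m["optimal34_rate"] = _rate(m["n_acs_optimal_lt34"], m["n_lt34"])
    m["term_acs_prop"] = _rate(m["n_acs_term"], m["n_acs_all"])
    m["acs_all_rate"] = _rate(m["n_acs_all"], m["n_total"])
    return m


def filter_min_preterm(
    metrics: pd.DataFrame, min_lt34: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split facility-years into (retained, removed) by the <34w volume floor."""
    keep = metrics["n_lt34"] >= min_lt34
    return metrics.loc[keep], metrics.loc[~keep]


@dataclass
class MadFilterResult:
    kept: np.ndarray        # positional indices into the input
    excluded: np.ndarray
    median: float
    mad: float


def mad_filter(
    values,
    k: float = 2.5,
    consistency: float = 1.0,
    two_sided: bool = True,
) -> MadFilterResult:
    """Flag values more than ``k`` median absolute deviations from the median.

    The MAD is the raw median of absolute deviations (no Gaussian consistency
    constant unless ``consistency`` is set, e.g. to 1.4826). ``two_sided``
    excludes both tails, matching dashed +/- reference lines on a rate
    histogram; set it False to exclude only anomalously *low* values. When the
    MAD is zero, only values different from the median are excluded; an
    infinite ``k`` excludes nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad_filter requires a non-empty input")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * consistency
    thr = k * mad
    if np.isnan(thr):  # k = inf with mad = 0: no spread, nothing to exclude
        thr = np.inf
    dev = x - med
    if two_sided:
        out = np.abs(dev) > thr
    else:
        out = dev < -thr
    return MadFilterResult(
        kept=np.flatnonzero(~out),
        excluded=np.flatnonzero(out),
        median=med,
        mad=mad,
    )


def apply_mad_filter(
    metrics: pd.DataFrame,
    k: float = 2.5,
    column: str = "acs34_rate",
    consistency: float = 1.0,
    two_sided: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, MadFilterResult]:
    """MAD-filter facility-years on a rate column, pooled across all years.

    Each facility-year is one observation. Returns (retained, removed, result).
    """
    res = mad_filter(
        metrics[column].to_numpy(), k=k, consistency=consistency, two_sided=two_sided
    )
    keep_mask = np.zeros(len(metrics), dtype=bool)
    keep_mask[res.kept] = True
    return metrics.loc[keep_mask], metrics.loc[~keep_mask], res


def build_profiles(
    metrics: pd.DataFrame, attributes: pd.DataFrame
) -> pd.DataFrame:
    """Collapse retained facility-years into one profile row per facility.

    Every proportion-based factor is first formed per facility-year (e.g. TPL
    among <34w births, in %), then averaged *unweighted* across that
    facility's retained years; counts (total and <34w deliveries) become
    annual means. Undefined rates (zero denominators) are skipped in the
    averaging. ``attributes`` supplies ``care_level`` and
    ``in_designated_city`` per facility.
    """
    m = metrics.copy()
    for c in COMPLICATIONS:
        m[c] = _rate(m[f"n_{c}_lt34"], m["n_lt34"])
    m["transfer"] = _rate(m["n_transfer_lt34"], m["n_lt34"])
    m["cesarean"] = _rate(m["n_cs_lt34"], m["n_lt34"])

    value_cols = FACTOR_COLUMNS + OUTCOME_COLUMNS
    g = m.groupby("facility_id")
    prof = g[value_cols].mean()  # skips NaN per column
    prof["n_years_retained"] = g.size()
    prof = prof.reset_index()

    attrs = attributes.set_index("facility_id")
    missing = set(prof["facility_id"]) - set(attrs.index)
    if missing:
        raise KeyError(f"attributes table lacks facilities: {sorted(missing)[:5]}")
    prof["care_level"] = prof["facility_id"].map(attrs["care_level"])
    prof["in_designated_city"] = (
        prof["facility_id"].map(attrs["in_designated_city"]).astype(int)
    )
    prof["is_comprehensive"] = (prof["care_level"] == "comprehensive").astype(int)
    return prof


def summarize_cohort(profiles: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: mean, sample SD (n−1), and contributing-facility n.

    Facilities with an undefined value for a given metric (e.g. no ACS
    recipients at all, hence an undefined term/ACS proportion) are excluded
    from that metric's row rather than counted as zero.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for SDs")
    cols = [c for c in FACTOR_COLUMNS + OUTCOME_COLUMNS if c in profiles.columns]
    rows = []
    for c in cols:
        s = profiles[c].dropna()
        rows.append((c, s.mean(), s.std(ddof=1), int(s.size)))
    return pd.DataFrame(rows, columns=["metric", "mean", "sd", "n"]).set_index("metric")


FACILITY_TABLE_COLUMNS = [
    "facility_id", "n_total", "n_lt34",
    "acs34_rate", "optimal34_rate", "term_acs_prop", "acs_all_rate",
]


def read_facility_table(path, sep: str = "\t") -> pd.DataFrame:
    """Ingest an external facility-level aggregate table directly.

    Bypasses the patient-level stages: the result plays the role of a profiles
    table for :func:`summarize_cohort` and for the population scenario. The
    table must carry :data:`FACILITY_TABLE_COLUMNS`.
    """
    df = pd.read_csv(path, sep=sep, dtype={"facility_id": str})
    missing = [c for c in FACILITY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"facility table is missing columns: {missing}")
    return df
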