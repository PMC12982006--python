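"""Composition of the patient-level stages into facility profiles.

Fixed stage order: exclusion cascade → facility-year tallies → minimum
<34w-volume filter → MAD outlier filter on the ACS/34w rate → annual-mean
profiles. Each stage's attrition is captured in a :class:`PipelineLog`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import metrics as fm
from .registry import ExclusionLog, apply_exclusions


@dataclass
class PipelineLog:
    exclusions: ExclusionLog
    n_facility_years: int
    n_removed_min_preterm: int
    n_removed_mad: int
    n_facility_years_retained: int
    n_facilities: int
    mad_median: float | None = None
    mad_value: float | None = None


def profiles_from_records(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    min_lt34: int = 10,
    mad_k: float | None = 2.5,
    mad_consistency: float = 1.0,
    mad_two_sided: bool = True,
    duplicate_subset: list[str] | None = None,
) -> tuple[pd.DataFrame, PipelineLog]:
    """Run records through the whole pipeline; return (profiles, log).

    ``mad_k=None`` disables the outlier filter (used e.g. when analysing
    clean synthetic cohorts with no reporting artifacts).
    """
    retained, exc_log = apply_exclusions(records, duplicate_subset=duplicate_subset)
    fy = fm.compute_facility_year_metrics(retained)
    kept, removed_small = fm.filter_min_preterm(fy, min_lt34=min_lt34)
    mad_median = mad_value = None
    if mad_k is not None and len(kept) > 0:
        kept, removed_mad, mad_res = fm.apply_mad_filter(
            kept, k=mad_k, consistency=mad_consistency, two_sided=mad_two_sided
        )
        n_removed_mad = len(removed_mad)
        mad_median, mad_value = mad_res.median, mad_res.mad
    else:
        n_removed_mad = 0
    profiles = fm.build_profiles(kept, attributes)
    log = PipelineLog(
        exclusions=exc_log,
        n_facility_years=len(fy),
        n_removed_min_preterm=len(removed_small),
        n_removed_mad=n_removed_mad,
        n_facility_years_retained=len(kept),
        n_facilities=len(profiles),
        mad_median=mad_median,
        mad_value=mad_value,
    )
    return profiles, log
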