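"""Synthetic facility-level aggregate table for the nationwide cohort.

The study's deposited data are facility-level aggregates (one row per
facility: annual-mean deliveries, <34w deliveries, and the four ACS metrics).
That table is not redistributable here, so this module constructs a
*synthetic* stand-in whose published summary statistics are built in as
construction constraints:

* 244 facilities;
* ACS/34w rates with sample mean 63.4% and SD 16.3 (left-skewed, Beta-shaped);
* optimal-ACS/34w mean 46.9%, term/ACS mean 12.0%, ACS-overall mean 6.3%;
* annual <34w deliveries matched to mean ~31.7 / SD ~17.6, scaled so the
  facilities below an 80% ACS/34w rate jointly hold 6577 annual <34w
  deliveries and 123 234 annual deliveries;
* the pairing of volumes with rates calibrated so that lifting every
  below-80% facility to 80% adds exactly 1211 treated-<34w births per year.

Every choice is deterministic (quantile constructions plus one fixed
permutation), so repeated calls are byte-identical. The table exercises the
descriptive and population-scenario stages exactly as an externally supplied
facility table would; it is a stand-in, not the study's data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

N_FACILITIES = 244
CAP = 80.0
ELIGIBLE_PRETERM34 = 6577.0
ELIGIBLE_DELIVERIES = 123_234.0
ELIGIBLE_D_TREATED34 = 1211.0

_MEAN_R, _SD_R = 63.4, 16.3
_MEAN_OPT = 46.9
_MEAN_TERM = 12.0
_SD_TERM = 9.3
_MEAN_ALL, _SD_ALL = 6.3, 4.0
_MEAN_N34, _SD_N34 = 31.7, 17.6
_MEAN_NTOT, _SD_NTOT = 583.2, 335.3

_PAIRING_SEED = 709  # fixture constant: fixes the volume-rate pairing only


def _beta_quantiles(n: int, mean: float, sd: float) -> np.ndarray:
    v = sd**2
    nu = mean * (1 - mean) / v - 1.0
    q = (np.arange(n) + 0.5) / n
    return stats.beta.ppf(q, mean * nu, (1 - mean) * nu)


def _lognorm_quantiles(n: int, mean: float, sd: float) -> np.ndarray:
    s2 = np.log(1 + (sd / mean) ** 2)
    q = (np.arange(n) + 0.5) / n
    return stats.lognorm.ppf(q, np.sqrt(s2), scale=mean * np.exp(-s2 / 2))


def _match_moments(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affine map to exact sample mean and sample SD (ddof=1)."""
    x = np.asarray(x, dtype=float)
    return mean + (x - x.mean()) * (sd / x.std(ddof=1))


def synthetic_file_s1() -> pd.DataFrame:
    """Deterministic synthetic stand-in for the facility-level data table."""
    n = N_FACILITIES
    rng = np.random.default_rng(_PAIRING_SEED)

    # ACS/34w rates: Beta-shaped quantiles, moment-matched exactly.
    r = _match_moments(100 * _beta_quantiles(n, _MEAN_R / 100, _SD_R / 100),
                       _MEAN_R, _SD_R)
    r = rng.permutation(r)
    if r.min() < 0 or r.max() > 100:
        raise AssertionError("rate construction left [0, 100]")
    eligible = r < CAP

    # annual <34w deliveries: lognormal quantiles (floored at the 10/year
    # inclusion threshold), eligible subset scaled to the published pool.
    n34 = np.maximum(10.5, _lognorm_quantiles(n, _MEAN_N34, _SD_N34))
    n34 = rng.permutation(n34)
    n34[eligible] *= ELIGIBLE_PRETERM34 / n34[eligible].sum()

    # pairing calibration: interpolate between the current arrangement and the
    # comonotone one (same multiset, so the eligible-pool total is untouched)
    # until the cap-lift delta Σ n34·(80−R)/100 hits the published value.
    w = (CAP - r[eligible]) / 100.0
    a0 = n34[eligible]
    order = np.argsort(r[eligible])
    a1 = np.empty_like(a0)
    a1[order] = np.sort(a0)          # larger n34 with larger R -> minimal delta
    d0, d1 = float(a0 @ w), float(a1 @ w)
    if not (min(d0, d1) <= ELIGIBLE_D_TREATED34 <= max(d0, d1)):
        raise AssertionError("published delta outside attainable pairing range")
    t = (d0 - ELIGIBLE_D_TREATED34) / (d0 - d1)
    n34[eligible] = (1 - t) * a0 + t * a1

    # total deliveries: roughly proportional to n34 (shared case-mix), scaled
    # so the eligible facilities hold the published delivery pool.
    ratio = np.clip(rng.normal(0.063, 0.020, n), 0.02, 0.15)
    n_total = n34 / ratio
    n_total[eligible] *= ELIGIBLE_DELIVERIES / n_total[eligible].sum()
    n_total = np.maximum(n_total, n34 + 1)

    # optimal timing: ~74% of the covered <34w births, scaled to the exact
    # mean; the fraction stays below 1 so optimal <= ACS/34w rate everywhere.
    frac = np.clip(rng.normal(0.74, 0.08, n), 0.40, 0.95)
    scale = _MEAN_OPT / (r * frac).mean()
    if (frac * scale).max() >= 1.0:
        raise AssertionError("optimal-rate construction exceeded the ACS/34w rate")
    opt = r * frac * scale

    # term/ACS proportion and overall ACS rate: skewed, exact means.
    term = 100 * _beta_quantiles(n, _MEAN_TERM / 100, _SD_TERM / 100)
    term = rng.permutation(term) * (_MEAN_TERM / term.mean())
    acs_all = 100 * _beta_quantiles(n, _MEAN_ALL / 100, _SD_ALL / 100)
    acs_all = rng.permutation(acs_all) * (_MEAN_ALL / acs_all.mean())

    return pd.DataFrame(
        {
            "facility_id": [f"S{i:04d}" for i in range(n)],
            "n_total": n_total,
            "n_lt34": n34,
            "acs34_rate": r,
            "optimal34_rate": opt,
            "term_acs_prop": term,
            "acs_all_rate": acs_all,
        }
    )
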