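"""Synthetic perinatal-registry generator with planted facility-level structure.

The generator emulates a nationwide hospital-based delivery registry dominated
by tertiary perinatal centers: ~244 facilities observed over three calendar
years, annual volumes around 583 (SD ~335), about 6.3% of deliveries before 34
weeks, high-risk complication prevalences among those early-preterm births,
and a facility-heterogeneous propensity to give antenatal corticosteroids
(ACS) before 34 weeks (mean ~63%, between-facility SD ~16 percentage points).

Facility-level associations are *planted*: the per-record probability of ACS
receipt before 34 weeks is logistic with a facility random intercept plus
slopes on the facility's own realized factor values (the same annual-mean
factors the metrics stage later computes), so downstream model fits can be
checked against an exact known truth (:func:`planted_truth`).

Everything is deterministic given the configuration seed, with one RNG stream
per facility so facility k's records do not change when ``n_facilities``
grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .registry import (
    ACS_INTERVALS,
    ACS_DOSES_MG,
    COMPLICATIONS,
    MANDATORY_FIELDS,
    REGISTRY_COLUMNS,
)

CARE_LEVELS = ["comprehensive", "regional", "nondesignated"]
GA_STRATA = ["lt28", "28_31", "32_33", "34_36", "term"]
# total-day bounds per stratum: [low, high] inclusive
GA_BOUNDS = np.array([[154, 195], [196, 223], [224, 237], [238, 258], [259, 293]])

#: Centering constants for the planted logistic model (cohort-typical factor values).
FACTOR_CENTERS = {
    "tpl": 48.8, "hdp": 19.2, "pprom": 29.3, "previa": 4.8,
    "multiple": 11.4, "fgr": 14.3, "abruption": 5.9,
    "transfer": 49.8, "cesarean": 73.0,
    "n_total": 583.2, "n_lt34": 31.7,
}

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)


def _gauss_mean(fn, sigma: float) -> float:
    """E[fn(u)] for u ~ N(0, sigma^2) by Gauss-Hermite quadrature."""
    if sigma == 0:
        return float(fn(np.array([0.0]))[0])
    u = math.sqrt(2.0) * sigma * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * fn(u)) / math.sqrt(math.pi))


@dataclass
class AcsModel:
    """Planted model for ACS receipt among deliveries before 34 weeks.

    ``base_rate`` is the marginal ACS/34w propensity at factor centers;
    ``slopes_pp`` maps a facility-level factor name (a profile column such as
    ``"tpl"`` or ``"n_total"``) to the planted change in the ACS/34w rate, in
    percentage points per natural unit of the factor. Internally the model is
    logistic — slopes act on the logit, converted so that the stated pp-scale
    slope is exact at the factor centers — with a facility random intercept of
    SD ``sigma_logit`` on the logit scale.
    """

    base_rate: float = 0.634
    slopes_pp: dict[str, float] = field(default_factory=lambda: {"tpl": 0.27})
    sigma_logit: float = 0.63
    centers: dict[str, float] = field(default_factory=lambda: dict(FACTOR_CENTERS))

    def intercept_logit(self) -> float:
        """Logit intercept solving E_u[expit(b0 + u)] = base_rate."""
        if self.base_rate >= 1.0:
            return math.inf
        if self.base_rate <= 0.0:
            return -math.inf
        f = lambda b0: _gauss_mean(lambda u: expit(b0 + u), self.sigma_logit) - self.base_rate
        return brentq(f, -30.0, 30.0, xtol=1e-12)

    def mean_pq(self) -> float:
        """E_u[p(1-p)] at factor centers; the pp-to-logit conversion factor / 100."""
        b0 = self.intercept_logit()
        if not math.isfinite(b0):
            return 0.0
        return _gauss_mean(lambda u: expit(b0 + u) * (1 - expit(b0 + u)), self.sigma_logit)

    def slopes_logit(self) -> dict[str, float]:
        pq = self.mean_pq()
        if pq == 0.0:
            return {k: 0.0 for k in self.slopes_pp}
        return {k: v / (100.0 * pq) for k, v in self.slopes_pp.items()}


@dataclass
class RegistryConfig:
    """Generator configuration; defaults emulate the 2020-2022 cohort structure."""

    n_facilities: int = 244
    years: tuple[int, ...] = (2020, 2021, 2022)
    care_level_mix: dict[str, float] = field(
        default_factory=lambda: {
            "comprehensive": 0.426, "regional": 0.561, "nondesignated": 0.013,
        }
    )
    city_prob: float = 0.369
    volume_law: tuple[float, float] = (583.2, 335.3)  # mean, SD of annual deliveries
    min_volume: int = 50
    volume_year_jitter: float = 0.08    # CV of year-to-year volume around facility size
    ga_mix: tuple[float, ...] = (0.014, 0.022, 0.027, 0.106, 0.831)
    #: facility case-mix tilt: preterm strata scaled by a lognormal factor with
    #: this CV, damped against volume by the given exponent (tertiary referral
    #: centers are smaller-volume but preterm-heavy).
    case_mix_sd: float = 0.5
    case_mix_volume_exp: float = -0.5
    #: marginal prevalence among births <34w
    complication_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "tpl": 0.488, "hdp": 0.192, "pprom": 0.293, "previa": 0.048,
            "multiple": 0.114, "fgr": 0.143, "abruption": 0.059,
        }
    )
    #: between-facility SD of the prevalence (percentage points)
    complication_dispersion: dict[str, float] = field(
        default_factory=lambda: {
            "tpl": 16.2, "hdp": 8.1, "pprom": 11.2, "previa": 3.6,
            "multiple": 5.5, "fgr": 7.1, "abruption": 7.1,
        }
    )
    acs_model: AcsModel = field(default_factory=AcsModel)
    #: interval-category mix given ACS, by stratum; 5th slot is "missing"
    timing_mix: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "lt34": (0.45, 0.29, 0.13, 0.09, 0.04),
            "other": (0.14, 0.19, 0.33, 0.30, 0.04),
        }
    )
    #: total-dose mix given ACS {12, 24, 36, 48 mg, missing}
    dose_mix: tuple[float, ...] = (0.177, 0.764, 0.002, 0.010, 0.047)
    term_acs_rate: float = 0.0093
    term_acs_dispersion: float = 0.75   # between-facility SD, pp
    late_preterm_acs_rate: float = 0.20
    transfer_prob: float = 0.498        # among births <34w
    transfer_dispersion: float = 17.5   # between-facility SD, pp
    cs_prob: float = 0.730              # among births <34w
    cs_dispersion: float = 11.3
    grade1_given_cs: float = 0.15
    term_transfer_prob: float = 0.02
    term_cs_prob: float = 0.20
    term_grade1_given_cs: float = 0.05
    term_multiple_prob: float = 0.012
    triplet_given_multiple: float = 0.04
    stillbirth_mix: tuple[float, float, float] = (0.985, 0.012, 0.003)
    missingness: dict[str, float] = field(
        default_factory=lambda: {"acs_checkbox": 0.05}
    )
    mandatory_missing_prob: float = 0.003
    duplicate_prob: float = 0.001
    include_later_born: bool = False
    seed: int = 0

    def validate(self) -> None:
        def check_simplex(name, probs):
            p = np.asarray(list(probs), dtype=float)
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"probabilities in {name!r} must lie in [0, 1]")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"probability vector {name!r} must sum to 1")

        check_simplex("care_level_mix", self.care_level_mix.values())
        check_simplex("ga_mix", self.ga_mix)
        check_simplex("dose_mix", self.dose_mix)
        check_simplex("stillbirth_mix", self.stillbirth_mix)
        for k, mix in self.timing_mix.items():
            check_simplex(f"timing_mix[{k}]", mix)
        for name, p in [
            ("city_prob", self.city_prob),
            ("term_acs_rate", self.term_acs_rate),
            ("late_preterm_acs_rate", self.late_preterm_acs_rate),
            ("transfer_prob", self.transfer_prob),
            ("cs_prob", self.cs_prob),
            ("grade1_given_cs", self.grade1_given_cs),
            ("mandatory_missing_prob", self.mandatory_missing_prob),
            ("duplicate_prob", self.duplicate_prob),
            *[(f"complication_prevalence[{k}]", v)
              for k, v in self.complication_prevalence.items()],
            *[(f"missingness[{k}]", v) for k, v in self.missingness.items()],
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name!r}={p} must lie in [0, 1]")
        if self.volume_law[0] <= 0:
            raise ValueError("volume_law mean must be positive")
        if self.n_facilities < 1:
            raise ValueError("n_facilities must be >= 1")
        if not self.years:
            raise ValueError("years must be non-empty")
        for k in self.acs_model.slopes_pp:
            if k not in FACTOR_CENTERS:
                raise ValueError(f"acs_model slope on unknown factor {k!r}")

    # --- YAML round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RegistryConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["acs_model"] = AcsModel(**d["acs_model"])
        for k in ("years", "volume_law", "ga_mix", "dose_mix", "stillbirth_mix"):
            d[k] = tuple(d[k])
        d["timing_mix"] = {k: tuple(v) for k, v in d["timing_mix"].items()}
        return cls(**d)


@dataclass
class PlantedTruth:
    """Ground truth implied by a configuration, for recovery tests."""

    slope_per_pp: dict[str, float]
    base_rates: dict[str, float]


def planted_truth(config: RegistryConfig) -> PlantedTruth:
    """Exact facility-level slopes and marginal rates implied by the config.

    Slopes pass through from ``acs_model.slopes_pp`` (the model is
    parameterized directly on that scale). Base rates are the configured
    marginals.
    """
    config.validate()
    tm = config.timing_mix["lt34"]
    return PlantedTruth(
        slope_per_pp=dict(config.acs_model.slopes_pp),
        base_rates={
            "acs34": config.acs_model.base_rate,
            "optimal34": config.acs_model.base_rate * (tm[0] + tm[1]),
            "term_acs": config.term_acs_rate,
            "late_preterm_acs": config.late_preterm_acs_rate,
        },
    )


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(a, b); sd capped just under the feasible maximum."""
    v_max = mean * (1 - mean)
    v = min(sd**2, 0.95 * v_max)
    if v <= 0:
        return math.inf, math.inf  # degenerate: treated as a point mass
    nu = v_max / v - 1.0
    return mean * nu, (1 - mean) * nu


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _draw_facility_prop(rng, mean: float, sd_pp: float) -> float:
    """Facility-level propensity around a marginal mean with given pp SD."""
    if sd_pp <= 0:
        return mean
    a, b = _beta_params(mean, sd_pp / 100.0)
    if not math.isfinite(a):
        return mean
    return float(rng.beta(a, b))


@dataclass
class SyntheticRegistry:
    """Patient-level records plus the facility attributes table."""

    records: pd.DataFrame
    attributes: pd.DataFrame


def generate_registry(config: RegistryConfig) -> SyntheticRegistry:
    """Generate patient-level delivery records for the configured cohort.

    One RNG stream per facility (spawned from ``config.seed``). Records for
    multiple pregnancies are emitted for the first-born only unless
    ``config.include_later_born`` is set, in which case later-born rows are
    also emitted (they carry ``birth_order`` 2..n and are meant to exercise
    the exclusion cascade).
    """
    config.validate()
    model = config.acs_model
    b0 = model.intercept_logit()
    b_logit = model.slopes_logit()
    centers = model.centers
    mu_v, sig_v = _lognormal_params(*config.volume_law)
    n_years = len(config.years)
    years_arr = np.asarray(config.years)
    sb_statuses = np.array(
        ["livebirth", "stillbirth_known_timing", "unknown_timing"], dtype=object
    )
    interval_labels = np.array(ACS_INTERVALS + [np.nan], dtype=object)
    dose_values = np.array(ACS_DOSES_MG + [np.nan])

    seqs = np.random.SeedSequence(config.seed).spawn(config.n_facilities)
    frames: list[dict[str, np.ndarray]] = []
    frame_fids: list[str] = []
    attr_rows = []

    for i, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        fid = f"F{i:04d}"
        care = CARE_LEVELS[
            rng.choice(3, p=[config.care_level_mix[c] for c in CARE_LEVELS])
        ]
        city = bool(rng.random() < config.city_prob)
        attr_rows.append((fid, care, int(city)))
        u = rng.normal(0.0, model.sigma_logit)

        # facility-level propensities (case-mix heterogeneity)
        comp_p = {
            c: _draw_facility_prop(
                rng,
                config.complication_prevalence[c],
                config.complication_dispersion.get(c, 0.0),
            )
            for c in COMPLICATIONS
        }
        p_transfer = _draw_facility_prop(rng, config.transfer_prob, config.transfer_dispersion)
        p_cs = _draw_facility_prop(rng, config.cs_prob, config.cs_dispersion)
        p_term_acs = _draw_facility_prop(
            rng, config.term_acs_rate, config.term_acs_dispersion
        )

        # persistent facility size with modest year-to-year jitter
        size = rng.lognormal(mu_v, sig_v)
        jit = config.volume_year_jitter
        vols = np.maximum(
            config.min_volume,
            np.rint(size * rng.lognormal(-jit**2 / 2, jit, n_years)).astype(int),
        )
        n = int(vols.sum())
        year = np.repeat(years_arr, vols)

        # facility case-mix: preterm-stratum mass tilted, term takes the rest
        s_cm = math.sqrt(math.log(1.0 + config.case_mix_sd**2))
        tilt = rng.lognormal(-s_cm**2 / 2, s_cm) * (
            size / config.volume_law[0]
        ) ** config.case_mix_volume_exp
        pre = np.asarray(config.ga_mix[:4]) * tilt
        total_pre = pre.sum()
        if total_pre > 0.6:
            pre *= 0.6 / total_pre
        ga_probs = np.append(pre, 1.0 - pre.sum())
        stratum = rng.choice(5, size=n, p=ga_probs)
        low = GA_BOUNDS[stratum, 0]
        span = GA_BOUNDS[stratum, 1] - low + 1
        ga = (low + np.floor(rng.random(n) * span)).astype(float)
        lt34 = stratum <= 2
        late = stratum == 3
        term = stratum == 4
        n34 = int(lt34.sum())

        p_vec = np.array([comp_p[c] for c in COMPLICATIONS])
        comp_draws = rng.random((n34, len(COMPLICATIONS))) < p_vec
        flags = {}
        for j, c in enumerate(COMPLICATIONS):
            f = np.zeros(n, dtype=np.int64)
            f[lt34] = comp_draws[:, j]
            flags[c] = f
        flags["multiple"][~lt34] = rng.random(n - n34) < config.term_multiple_prob
        n_fetuses = 1.0 + flags["multiple"] * (
            1 + (rng.random(n) < config.triplet_given_multiple)
        )

        mode_u = rng.random((n, 3))
        cs = (
            mode_u[:, 0] < np.where(lt34, p_cs, config.term_cs_prob)
        ).astype(np.int64)
        g1p = np.where(lt34, config.grade1_given_cs, config.term_grade1_given_cs)
        grade1 = (cs == 1) & (mode_u[:, 1] < g1p)
        transfer = (
            mode_u[:, 2] < np.where(lt34, p_transfer, config.term_transfer_prob)
        ).astype(np.int64)

        # realized annual-mean factors, computed the way the profiles stage does
        factor_flags = {**flags, "transfer": transfer, "cesarean": cs}
        z: dict[str, float] = {}
        yearly_n34 = np.array([int((lt34 & (year == y)).sum()) for y in years_arr])
        for name in b_logit:
            if name == "n_total":
                z[name] = float(vols.mean())
            elif name == "n_lt34":
                z[name] = float(yearly_n34.mean())
            else:
                flag = factor_flags[name]
                props = []
                for y in years_arr:
                    sel = lt34 & (year == y)
                    if sel.sum() > 0:
                        props.append(100.0 * flag[sel].mean())
                z[name] = float(np.mean(props)) if props else centers[name]

        eta = b0 + u + sum(b_logit[k] * (z[k] - centers[k]) for k in b_logit)
        p34 = float(expit(eta)) if math.isfinite(eta) else (1.0 if eta > 0 else 0.0)

        acs = np.zeros(n, dtype=bool)
        acs[lt34] = rng.random(n34) < p34
        acs[late] = rng.random(int(late.sum())) < config.late_preterm_acs_rate
        acs[term] = rng.random(int(term.sum())) < p_term_acs

        interval = np.full(n, np.nan, dtype=object)
        dose = np.full(n, np.nan)
        for sel, mix_key in ((acs & lt34, "lt34"), (acs & ~lt34, "other")):
            k = int(sel.sum())
            if k:
                idx = rng.choice(5, size=k, p=config.timing_mix[mix_key])
                interval[sel] = interval_labels[idx]
        n_acs = int(acs.sum())
        dose[acs] = dose_values[rng.choice(5, size=n_acs, p=config.dose_mix)]
        checkbox = np.zeros(n, dtype=np.int64)
        p_cb_missing = config.missingness.get("acs_checkbox", 0.0)
        checkbox[acs] = rng.random(n_acs) >= p_cb_missing

        sb = sb_statuses[rng.choice(3, size=n, p=config.stillbirth_mix)]

        cols = {
            "year": year.astype(np.int64),
            "gestational_age_days": ga,
            "birth_order": np.ones(n, dtype=np.int64),
            "n_fetuses": n_fetuses,
            "stillbirth_status": sb,
            "parity": rng.poisson(0.8, n).astype(float),
            "infertility_treatment": (rng.random(n) < 0.12).astype(float),
            "neonatal_sex": np.where(rng.random(n) < 0.513, "M", "F").astype(object),
            "maternal_age": np.clip(np.rint(rng.normal(32.0, 5.0, n)), 16, 50),
            "birth_weight": np.maximum(
                300.0,
                np.rint(3250.0 - 125.0 * (40.0 - ga / 7.0) + rng.normal(0, 420.0, n)),
            ),
            "blood_loss": np.rint(rng.lognormal(6.4, 0.6, n)),
            "maternal_survival": (rng.random(n) < 0.9999).astype(float),
            **{c: flags[c] for c in COMPLICATIONS},
            "transfer_in": transfer,
            "cesarean": cs,
            "cesarean_grade1": grade1.astype(np.int64),
            "acs_checkbox": checkbox,
            "acs_dose_mg": dose,
            "acs_interval": interval,
        }

        # sprinkle mandatory-field missingness (simulated entry errors)
        miss = rng.random(n) < config.mandatory_missing_prob
        if miss.any():
            which = rng.integers(0, len(MANDATORY_FIELDS), size=n)
            for k_f, fname in enumerate(MANDATORY_FIELDS):
                hit = miss & (which == k_f)
                if not hit.any():
                    continue
                if fname == "neonatal_sex":
                    cols[fname] = cols[fname].copy()
                    cols[fname][hit] = np.nan
                else:
                    cols[fname] = cols[fname].astype(float, copy=True)
                    cols[fname][hit] = np.nan

        frames.append(cols)
        frame_fids.append(fid)

        if config.include_later_born:
            mult = flags["multiple"] == 1
            if mult.any():
                extra = {k: np.asarray(v)[mult].copy() for k, v in cols.items()}
                extra["birth_order"] = np.full(int(mult.sum()), 2, dtype=np.int64)
                frames.append(extra)
                frame_fids.append(fid)

        if config.duplicate_prob > 0:
            dup = rng.random(n) < config.duplicate_prob
            if dup.any():
                frames.append({k: np.asarray(v)[dup].copy() for k, v in cols.items()})
                frame_fids.append(fid)

    merged = {
        col: np.concatenate([f[col] for f in frames])
        for col in REGISTRY_COLUMNS
        if col != "facility_id"
    }
    counts = [len(f["year"]) for f in frames]
    merged["facility_id"] = np.repeat(np.array(frame_fids, dtype=object), counts)
    records = pd.DataFrame(
        {col: merged[col] for col in REGISTRY_COLUMNS}, copy=False
    )
    attributes = pd.DataFrame(
        attr_rows, columns=["facility_id", "care_level", "in_designated_city"]
    )
    return SyntheticRegistry(records=records, attributes=attributes)
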