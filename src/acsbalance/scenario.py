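"""Scenario projections for raising a facility's ACS/34w rate.

Given a facility baseline and per-pp slopes (how much the optimally-timed
rate, the overall ACS rate, and the term/ACS proportion move per percentage
point of ACS/34w rate, taken from the de-standardized regression
coefficients), the engine projects the consequences of lifting the ACS/34w
rate R to a target R*:

* additional treated-<34w births:      Δtreated34 = n34 · ΔR / 100 (exact);
* additional optimally timed births:   Δoptimal34 = n34 · s_opt · ΔR / 100;
* additional recipients overall:       ΔA = N · s_all · ΔR / 100;
* post term-exposed births:            T* = (A + ΔA)(p_term + s_term·ΔR)/100,

with ΔR = R* − R in percentage points. The term-birth delta decomposes into a
part linear in ΔR and a quadratic part ΔA · s_term · ΔR / 100: because more
coverage raises both the number of recipients and the term share among them,
term-exposed births accelerate as the target rises.

Deltas are finally translated into expected clinical outcome counts through
user-supplied absolute risk differences (benefits per additional treated or
optimally-timed <34w birth; harms per additional term-exposed birth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScenarioBaseline:
    """Annual baseline figures for one facility."""

    N: float            # annual deliveries
    n34: float          # annual deliveries <34w
    R: float            # baseline ACS/34w rate, pp
    treated34: float    # ACS recipients delivering <34w
    optimal34: float    # optimally timed recipients <34w
    A: float            # ACS recipients overall
    T: float            # term births among recipients

    def __post_init__(self):
        if min(self.N, self.n34, self.R, self.treated34,
               self.optimal34, self.A, self.T) < 0:
            raise ValueError("baseline figures must be non-negative")
        if abs(self.treated34 - self.n34 * self.R / 100.0) > 0.5 + 1e-9:
            raise ValueError("treated34 must equal n34 * R / 100 within rounding")
        if self.optimal34 > self.treated34 + 1e-9:
            raise ValueError("optimal34 cannot exceed treated34")
        if self.T > self.A + 1e-9:
            raise ValueError("term births among recipients cannot exceed recipients")

    @property
    def p_term(self) -> float:
        """Baseline term share among recipients, pp."""
        return 100.0 * self.T / self.A if self.A > 0 else 0.0

    @classmethod
    def from_profile(cls, row) -> "ScenarioBaseline":
        """Baseline from one facility-profile (or facility-table) row."""
        n34 = float(row["n_lt34"])
        N = float(row["n_total"])
        R = float(row["acs34_rate"])
        A = N * float(row["acs_all_rate"]) / 100.0
        return cls(
            N=N,
            n34=n34,
            R=R,
            treated34=n34 * R / 100.0,
            optimal34=n34 * float(row["optimal34_rate"]) / 100.0,
            A=A,
            T=A * float(row["term_acs_prop"]) / 100.0,
        )


@dataclass(frozen=True)
class SimulationSlopes:
    """Per-pp slopes of the three secondary metrics in the ACS/34w rate."""

    s_opt: float = 11.5 / 16.3   # pp of optimal34_rate per pp of R
    s_all: float = 1.6 / 16.3    # pp of acs_all_rate per pp of R
    s_term: float = 2.0 / 16.3   # pp of term_acs_prop per pp of R

    @classmethod
    def from_standardized(
        cls, coef_opt: float, coef_all: float, coef_term: float, sd_r: float
    ) -> "SimulationSlopes":
        """De-standardize per-SD coefficients with the SD of the ACS/34w rate."""
        return cls(coef_opt / sd_r, coef_all / sd_r, coef_term / sd_r)

    @classmethod
    def from_model_fits(cls, fits: dict) -> "SimulationSlopes":
        """Pull the raw (per-natural-unit) ACS/34w-rate coefficients from fits."""
        return cls(
            s_opt=float(fits["optimal34_rate"].table.loc["acs34_rate", "raw_coef"]),
            s_all=float(fits["acs_all_rate"].table.loc["acs34_rate", "raw_coef"]),
            s_term=float(fits["term_acs_prop"].table.loc["acs34_rate", "raw_coef"]),
        )


@dataclass(frozen=True)
class ScenarioResult:
    """Deltas and post values of one projection (full precision; round on report)."""

    baseline: ScenarioBaseline
    d_rate: float
    d_treated34: float
    d_optimal34: float
    d_acs_all: float
    d_term: float
    term_linear: float     # part of d_term linear in ΔR
    term_quadratic: float  # ΔA · s_term · ΔR / 100

    @property
    def post_treated34(self) -> float:
        return self.baseline.treated34 + self.d_treated34

    @property
    def post_optimal34(self) -> float:
        return self.baseline.optimal34 + self.d_optimal34

    @property
    def post_acs_all(self) -> float:
        return self.baseline.A + self.d_acs_all

    @property
    def post_term(self) -> float:
        return self.baseline.T + self.d_term


def simulate_facility(
    baseline: ScenarioBaseline,
    slopes: SimulationSlopes,
    target_rate: float,
) -> ScenarioResult:
    """Project one facility from its baseline rate R up to ``target_rate``.

    Raises when the target lies below the baseline — the projection is
    defined for coverage increases only. The treated-<34w delta is computed
    in exact rational arithmetic, so integer inputs give drift-free results.
    """
    if target_rate < baseline.R:
        raise ValueError(
            f"target rate {target_rate} is below baseline {baseline.R}; "
            "downward extrapolation is not supported"
        )
    dr = target_rate - baseline.R
    if dr == 0:
        return ScenarioResult(baseline, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    d_treated = float(
        Fraction(baseline.n34) * Fraction(target_rate - baseline.R) / 100
    )
    d_opt = baseline.n34 * slopes.s_opt * dr / 100.0
    d_all = baseline.N * slopes.s_all * dr / 100.0
    p_term = baseline.p_term
    post_term = (baseline.A + d_all) * (p_term + slopes.s_term * dr) / 100.0
    term_quad = d_all * slopes.s_term * dr / 100.0
    term_lin = (d_all * p_term + baseline.A * slopes.s_term * dr) / 100.0
    return ScenarioResult(
        baseline=baseline,
        d_rate=dr,
        d_treated34=d_treated,
        d_optimal34=d_opt,
        d_acs_all=d_all,
        d_term=post_term - baseline.T,
        term_linear=term_lin,
        term_quadratic=term_quad,
    )


@dataclass
class PopulationScenario:
    """Aggregate of per-facility projections under a coverage cap."""

    result: ScenarioResult          # sums over eligible facilities
    n_eligible: int
    n_untouched: int
    eligible_deliveries: float      # annual deliveries in eligible facilities
    eligible_preterm34: float       # annual <34w deliveries in eligible facilities
    per_facility: pd.DataFrame


def simulate_population(
    profiles: pd.DataFrame,
    slopes: SimulationSlopes,
    cap: float = 80.0,
) -> PopulationScenario:
    """Lift every facility below ``cap`` to exactly ``cap``; sum the deltas.

    Facilities already at or above the cap are untouched. Baselines come from
    each facility's own profile row. The eligibility summary reports total
    annual deliveries and <34w deliveries over the lifted facilities.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be non-empty")
    eligible = profiles["acs34_rate"] < cap
    rows = []
    agg = dict.fromkeys(
        ["N", "n34", "treated34", "optimal34", "A", "T",
         "d_treated34", "d_optimal34", "d_acs_all", "d_term",
         "term_linear", "term_quadratic"], 0.0
    )
    for _, row in profiles.loc[eligible].iterrows():
        base = ScenarioBaseline.from_profile(row)
        res = simulate_facility(base, slopes, cap)
        rows.append(
            {
                "facility_id": row["facility_id"],
                "baseline_rate": base.R,
                "d_treated34": res.d_treated34,
                "d_optimal34": res.d_optimal34,
                "d_acs_all": res.d_acs_all,
                "d_term": res.d_term,
            }
        )
        for k in ("N", "n34", "treated34", "optimal34", "A", "T"):
            agg[k] += getattr(base, k)
        for k in ("d_treated34", "d_optimal34", "d_acs_all", "d_term",
                  "term_linear", "term_quadratic"):
            agg[k] += getattr(res, k)

    pooled_base = ScenarioBaseline.__new__(ScenarioBaseline)
    object.__setattr__(pooled_base, "N", agg["N"])
    object.__setattr__(pooled_base, "n34", agg["n34"])
    object.__setattr__(
        pooled_base, "R",
        100.0 * agg["treated34"] / agg["n34"] if agg["n34"] else 0.0,
    )
    object.__setattr__(pooled_base, "treated34", agg["treated34"])
    object.__setattr__(pooled_base, "optimal34", agg["optimal34"])
    object.__setattr__(pooled_base, "A", agg["A"])
    object.__setattr__(pooled_base, "T", agg["T"])
    result = ScenarioResult(
        baseline=pooled_base,
        d_rate=float("nan") if agg["n34"] else 0.0,  # per-facility ΔR varies
        d_treated34=agg["d_treated34"],
        d_optimal34=agg["d_optimal34"],
        d_acs_all=agg["d_acs_all"],
        d_term=agg["d_term"],
        term_linear=agg["term_linear"],
        term_quadratic=agg["term_quadratic"],
    )
    return PopulationScenario(
        result=result,
        n_eligible=int(eligible.sum()),
        n_untouched=int((~eligible).sum()),
        eligible_deliveries=agg["N"],
        eligible_preterm34=agg["n34"],
        per_facility=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class EffectEstimates:
    """Absolute risk differences translating deltas into outcome counts.

    These effect sizes are user-supplied configuration (e.g. from systematic
    reviews of ACS trials and large observational cohorts); nothing in this
    package derives them. Benefits apply per additional treated-<34w (or
    optimally timed) birth; harms per additional term-exposed birth.
    """

    benefit_rd: dict[str, float] = field(default_factory=dict)
    harm_rd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, rd in {**self.benefit_rd, **self.harm_rd}.items():
            if not (0.0 <= rd <= 1.0):
                raise ValueError(f"risk difference {name!r}={rd} must lie in [0, 1]")


def risk_benefit(
    result: ScenarioResult,
    effects: EffectEstimates,
    denominator: str = "treated34",
) -> dict[str, float]:
    """Expected outcome counts: prevented cases per benefit, added per harm.

    ``denominator`` chooses whether benefits accrue per additional treated
    (<34w) birth or per additional optimally timed one. Linear in the deltas.
    """
    if denominator == "treated34":
        d_ben = result.d_treated34
    elif denominator == "optimal34":
        d_ben = result.d_optimal34
    else:
        raise ValueError(f"unknown denominator choice {denominator!r}")
    out = {f"prevented_{k}": d_ben * rd for k, rd in effects.benefit_rd.items()}
    out.update({f"added_{k}": result.d_term * rd for k, rd in effects.harm_rd.items()})
    return out


_METRIC_LABELS = [
    ("treated34", "ACS, delivered <34w"),
    ("optimal34", "optimally timed ACS, delivered <34w"),
    ("acs_all", "ACS (overall)"),
    ("term", "ACS, delivered at term"),
]


def _fmt_value(x: float) -> str:
    r = round(x, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


def format_cell(delta: float, base: float, post: float) -> str:
    """Render one report cell, e.g. ``+6.0 (18 → 24)``."""
    return f"+{delta:.1f} ({_fmt_value(base)} → {_fmt_value(post)})"


def report_scenarios(
    results: list[tuple[str, ScenarioResult]],
) -> tuple[str, pd.DataFrame]:
    """Tabulate scenarios: a plain-text report plus a machine-readable twin.

    The text report rounds to one decimal; the machine-readable frame keeps
    full precision (baseline, post and delta per metric) and round-trips via
    :func:`scenario_results_from_frame`.
    """
    if not results:
        raise ValueError("need at least one scenario result")
    lines, records = [], []
    for label, res in results:
        b = res.baseline
        lines.append(label)
        vals = {
            "treated34": (res.d_treated34, b.treated34, res.post_treated34),
            "optimal34": (res.d_optimal34, b.optimal34, res.post_optimal34),
            "acs_all": (res.d_acs_all, b.A, res.post_acs_all),
            "term": (res.d_term, b.T, res.post_term),
        }
        for key, title in _METRIC_LABELS:
            d, base, post = vals[key]
            lines.append(f"  {title}: {format_cell(d, base, post)}")
        records.append(
            {
                "label": label,
                "N": b.N, "n34": b.n34, "R": b.R,
                "treated34": b.treated34, "optimal34": b.optimal34,
                "A": b.A, "T": b.T,
                "d_rate": res.d_rate,
                "d_treated34": res.d_treated34, "d_optimal34": res.d_optimal34,
                "d_acs_all": res.d_acs_all, "d_term": res.d_term,
                "term_linear": res.term_linear,
                "term_quadratic": res.term_quadratic,
            }
        )
    return "\n".join(lines), pd.DataFrame(records)


def scenario_results_from_frame(frame: pd.DataFrame) -> list[tuple[str, ScenarioResult]]:
    """Rebuild scenario results from the machine-readable report frame."""
    out = []
    for _, r in frame.iterrows():
        base = ScenarioBaseline(
            N=r["N"], n34=r["n34"], R=r["R"], treated34=r["treated34"],
            optimal34=r["optimal34"], A=r["A"], T=r["T"],
        )
        out.append(
            (
                r["label"],
                ScenarioResult(
                    baseline=base,
                    d_rate=r["d_rate"],
                    d_treated34=r["d_treated34"],
                    d_optimal34=r["d_optimal34"],
                    d_acs_all=r["d_acs_all"],
                    d_term=r["d_term"],
                    term_linear=r["term_linear"],
                    term_quadratic=r["term_quadratic"],
                ),
            )
        )
    return out
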