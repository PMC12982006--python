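"""Shared fixtures: small generated cohorts and the replicated recovery study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import acsbalance as ab
from acsbalance import models
from acsbalance.synthetic import AcsModel, RegistryConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

PLANTED_TPL_SLOPE = 0.27  # pp of ACS/34w rate per pp of TPL prevalence
N_RECOVERY_REPS = 200


def small_config(seed: int = 11, **kw) -> RegistryConfig:
    """A fast, small cohort for unit tests (not the study-scale conditions)."""
    defaults = dict(
        n_facilities=8,
        years=(2021, 2022),
        volume_law=(220.0, 90.0),
        seed=seed,
    )
    defaults.update(kw)
    return RegistryConfig(**defaults)


@pytest.fixture(scope="session")
def small_registry():
    return ab.generate_registry(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale cohort (244 facilities, 3 years) through the full pipeline."""
    reg = ab.generate_registry(RegistryConfig(seed=20201))
    retained, log = ab.apply_exclusions(reg.records)
    profiles, plog = ab.profiles_from_records(reg.records, reg.attributes)
    return {
        "registry": reg,
        "retained": retained,
        "exclusion_log": log,
        "profiles": profiles,
        "pipeline_log": plog,
    }


@pytest.fixture(scope="session")
def recovery_results():
    """Replicated recovery study: refit the coverage model on independently
    generated cohorts with one planted TPL slope; collect estimates and CIs.

    The MAD outlier filter is off here: the clean generator produces no
    reporting artifacts, and truncating the outcome tail would bias any slope
    by construction.
    """
    seeds = np.random.SeedSequence(1234).generate_state(N_RECOVERY_REPS) % (2**31)
    rows = []
    for s in seeds:
        cfg = RegistryConfig(
            seed=int(s),
            acs_model=AcsModel(slopes_pp={"tpl": PLANTED_TPL_SLOPE}),
        )
        reg = ab.generate_registry(cfg)
        profiles, _ = ab.profiles_from_records(
            reg.records, reg.attributes, mad_k=None
        )
        fit = models.fit_outcome_model(profiles, models.ModelSpec(outcome="acs34_rate"))
        t = fit.table.loc["tpl"]
        rows.append(
            {
                "coef_std": t["coef"],
                "raw_coef": t["raw_coef"],
                "raw_ci_low": t["raw_ci_low"],
                "raw_ci_high": t["raw_ci_high"],
                "significant": bool(t["significant"]),
            }
        )
    return pd.DataFrame(rows)
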