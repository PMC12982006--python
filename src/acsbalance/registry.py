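"""Delivery-record schema, tabular IO, and the patient-level exclusion cascade.

The unit of analysis is one delivery row per first-born neonate. A perinatal
registry of this kind records every delivery after 22 completed weeks of
gestation, with a small set of mandatory obstetric fields (missing values in
those fields indicate data-entry errors and lead to exclusion), complication
flags, mode-of-delivery fields, and three antenatal-corticosteroid (ACS)
fields: an administration checkbox, a total-dose category, and an
administration-to-delivery interval category.

Records are held in a pandas DataFrame with the columns of
:data:`REGISTRY_COLUMNS`; gestational age is stored as total days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --- gestational-age thresholds (total days; week w starts at day 7*w) ---
GA_MIN_DAYS = 154   # 22+0: the registry covers all deliveries after 22 weeks
LT28_DAYS = 196     # strictly before 28+0
LT32_DAYS = 224
LT34_DAYS = 238     # "<34 weeks" = strictly before 34+0
LT37_DAYS = 259
TERM_DAYS = 259     # term = 37+0 or later

ACS_INTERVALS = ["<48h", "48h-7d", "7d-1mo", ">1mo"]
OPTIMAL_INTERVALS = ["<48h", "48h-7d"]  # within 7 days before delivery
ACS_DOSES_MG = [12.0, 24.0, 36.0, 48.0]
STILLBIRTH_STATUSES = ["livebirth", "stillbirth_known_timing", "unknown_timing"]
SEXES = ["M", "F"]

COMPLICATIONS = ["tpl", "hdp", "pprom", "previa", "multiple", "fgr", "abruption"]

#: Mandatory registry fields; a missing value in any of them excludes the row.
MANDATORY_FIELDS = [
    "parity",
    "infertility_treatment",
    "n_fetuses",
    "neonatal_sex",
    "maternal_age",
    "gestational_age_days",
    "birth_weight",
    "blood_loss",
    "maternal_survival",
]

FLAG_COLUMNS = COMPLICATIONS + [
    "transfer_in", "cesarean", "cesarean_grade1", "acs_checkbox",
]

#: Canonical column -> dtype for a registry table.
REGISTRY_COLUMNS: dict[str, object] = {
    "facility_id": str,
    "year": np.int64,
    "gestational_age_days": np.float64,
    "birth_order": np.int64,
    "n_fetuses": np.float64,
    "stillbirth_status": str,
    "parity": np.float64,
    "infertility_treatment": np.float64,
    "neonatal_sex": str,
    "maternal_age": np.float64,
    "birth_weight": np.float64,
    "blood_loss": np.float64,
    "maternal_survival": np.float64,
    **{c: np.int64 for c in FLAG_COLUMNS},
    "acs_dose_mg": np.float64,
    "acs_interval": str,
}


class SchemaError(ValueError):
    """The table is missing required columns."""


class ParseError(ValueError):
    """A row holds a value outside the documented enumerations."""


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col, dtype in REGISTRY_COLUMNS.items():
        s = df[col]
        if dtype is str:
            s = s.astype("object")
            s = s.where(~pd.isna(s), other=np.nan)
        else:
            s = s.astype(dtype)
        out[col] = s
    return pd.DataFrame(out)


def validate_registry(df: pd.DataFrame) -> None:
    """Validate enumerations and structural invariants; raise on violation.

    Checks performed:

    * all canonical columns present (:class:`SchemaError` otherwise);
    * categorical fields within their enumerations, flags in {0, 1}
      (:class:`ParseError` naming offending rows and field);
    * gestational age >= 22+0 weeks when present;
    * Grade-1 cesarean implies cesarean;
    * multiple-pregnancy flag consistent with the number of fetuses.
    """
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry table is missing columns: {missing}")

    def bad_rows(mask: pd.Series, fieldname: str) -> None:
        if mask.any():
            rows = list(np.flatnonzero(mask.to_numpy())[:20])
            raise ParseError(f"invalid value in field {fieldname!r} at rows {rows}")

    iv = df["acs_interval"]
    bad_rows(~(iv.isna() | iv.isin(ACS_INTERVALS)), "acs_interval")
    dose = df["acs_dose_mg"]
    bad_rows(~(dose.isna() | dose.isin(ACS_DOSES_MG)), "acs_dose_mg")
    bad_rows(~df["stillbirth_status"].isin(STILLBIRTH_STATUSES), "stillbirth_status")
    sex = df["neonatal_sex"]
    bad_rows(~(sex.isna() | sex.isin(SEXES)), "neonatal_sex")
    for c in FLAG_COLUMNS:
        bad_rows(~df[c].isin([0, 1]), c)

    ga = df["gestational_age_days"]
    bad_rows(ga.notna() & (ga < GA_MIN_DAYS), "gestational_age_days")
    bad_rows((df["cesarean_grade1"] == 1) & (df["cesarean"] == 0), "cesarean_grade1")
    nf = df["n_fetuses"]
    bad_rows(nf.notna() & ((nf > 1) != (df["multiple"] == 1)), "multiple")


def read_registry(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited registry table, validate it, and coerce dtypes.

    Empty cells denote missing values. TSV is the default dialect; pass
    ``sep=","`` for CSV.
    """
    df = pd.read_csv(path, sep=sep, dtype={"facility_id": str})
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry table at {path} is missing columns: {missing}")
    df = _coerce_dtypes(df)
    validate_registry(df)
    return df


def write_registry(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a registry table as delimited text (missing values as empty cells)."""
    df.to_csv(path, sep=sep, index=False, na_rep="")


def is_acs_recipient(df: pd.DataFrame) -> pd.Series:
    """True where the row counts as an ACS recipient.

    A documented total dose or administration-to-delivery interval counts as
    receipt even when the administration checkbox was left unfilled, so the
    predicate is: checkbox ticked OR dose present OR interval present.
    """
    return (
        (df["acs_checkbox"] == 1)
        | df["acs_dose_mg"].notna()
        | df["acs_interval"].notna()
    )


@dataclass
class ExclusionLog:
    """Audit log of the patient-level exclusion cascade.

    Each record is counted at its first failing step, in the fixed order:
    duplicates, stillbirth/perinatal death of unknown timing, non-first-born
    of a multiple pregnancy, missing mandatory field.
    """

    n_input: int = 0
    duplicates: int = 0
    unknown_timing_death: int = 0
    non_first_born_multiple: int = 0
    missing_mandatory_field: int = 0
    retained: int = 0

    STEPS = (
        "duplicates",
        "unknown_timing_death",
        "non_first_born_multiple",
        "missing_mandatory_field",
    )

    def check(self) -> None:
        total = sum(getattr(self, s) for s in self.STEPS) + self.retained
        if total != self.n_input:
            raise AssertionError("exclusion log does not conserve records")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(s, getattr(self, s)) for s in self.STEPS]
        rows.append(("retained", self.retained))
        return pd.DataFrame(rows, columns=["step", "n"])

    def __str__(self) -> str:
        lines = [f"records in: {self.n_input}"]
        for s in self.STEPS:
            lines.append(f"  excluded ({s.replace('_', ' ')}): {getattr(self, s)}")
        lines.append(f"retained: {self.retained}")
        return "\n".join(lines)


def apply_exclusions(
    df: pd.DataFrame, duplicate_subset: list[str] | None = None
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion cascade; return the retained rows and an audit log.

    Steps, in order: exact-duplicate rows (all fields identical unless
    ``duplicate_subset`` narrows the key); stillbirths or perinatal deaths with
    unknown timing; neonates other than first-born in multiple pregnancies;
    rows with any missing mandatory field. The retained *set* does not depend
    on the step order — only the attribution of counts does.
    """
    log = ExclusionLog(n_input=len(df))

    # exact-row duplicate detection, screen-accelerated: rows sharing a cheap
    # numeric fingerprint are re-checked field-by-field, so equality is exact.
    key = df if duplicate_subset is None else df[duplicate_subset]
    screen_cols = [
        c for c in ("birth_weight", "blood_loss", "maternal_age",
                    "gestational_age_days", "parity")
        if c in key.columns
    ]
    if screen_cols:
        fp = np.zeros(len(key))
        for i, c in enumerate(screen_cols):
            fp += np.nan_to_num(key[c].to_numpy(dtype=float), nan=-1.0) * (
                7919.0 ** (i / len(screen_cols))
            )
        candidates = pd.Series(fp).duplicated(keep=False).to_numpy()
    else:
        candidates = np.ones(len(key), dtype=bool)
    dup = np.zeros(len(df), dtype=bool)
    if candidates.any():
        dup[candidates] = key.loc[candidates].duplicated(keep="first").to_numpy()

    # each record counted at its first failing step; one final copy
    unk = (df["stillbirth_status"] == "unknown_timing").to_numpy() & ~dup
    later = (df["birth_order"] > 1).to_numpy() & ~dup & ~unk
    miss = (
        df[MANDATORY_FIELDS].isna().any(axis=1).to_numpy() & ~dup & ~unk & ~later
    )
    log.duplicates = int(dup.sum())
    log.unknown_timing_death = int(unk.sum())
    log.non_first_born_multiple = int(later.sum())
    log.missing_mandatory_field = int(miss.sum())
    retained = df.loc[~(dup | unk | later | miss)]
    log.retained = len(retained)
    log.check()
    return retained, log


def sensitivity_subset(df: pd.DataFrame) -> pd.DataFrame:
    """Drop pregnancies with placental abruption or a Grade-1 cesarean.

    In the most acute presentations there is no opportunity to give ACS before
    delivery; the sensitivity analysis removes those records and reruns the
    whole pipeline. Idempotent.
    """
    drop = (df["abruption"] == 1) | (df["cesarean_grade1"] == 1)
    return df.loc[~drop]
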