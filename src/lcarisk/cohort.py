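"""Patient-level cohort table: schema, validation, and CSV round-trip.

A cohort couples five categorical indicators (age group at diagnosis, sex,
race/ethnicity, tumor site, stage) with right-censored competing-risks
follow-up: time in months and an event code (0 = censored, 1 = cancer death,
2 = other-cause death).  A molecular-subtype label and, for simulated
cohorts, the latent class that generated each patient are optional columns.

Validation is row-wise and strict: a row with an out-of-vocabulary indicator
level, a negative or missing time, or an event code outside {0, 1, 2} is
rejected and counted; the surviving rows form the :class:`Cohort`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

INDICATORS: tuple[str, ...] = ("age_group", "sex", "race", "site", "stage")

#: Default level sets, in the category order used throughout the package.
DEFAULT_LEVELS: dict[str, list[str]] = {
    "age_group": ["18-44", "45-69", "70+"],
    "sex": ["Female", "Male"],
    "race": ["NH White", "NH Black", "Hispanic", "Other"],
    "site": ["right colon", "left colon", "rectum"],
    "stage": ["I", "II", "III", "IV"],
}

REQUIRED_COLUMNS = ("patient_id",) + INDICATORS + ("time_months", "event")
OPTIONAL_COLUMNS = ("subtype", "true_class")

EVENT_CENSORED, EVENT_CANCER, EVENT_OTHER = 0, 1, 2


@dataclass(frozen=True)
class Cohort:
    """A validated patient-level table plus its frozen indicator level sets."""

    data: pd.DataFrame
    levels: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    n_rejected: int = 0

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def patient_id(self) -> np.ndarray:
        return self.data["patient_id"].to_numpy()

    @property
    def has_subtype(self) -> bool:
        return "subtype" in self.data.columns

    @property
    def has_true_class(self) -> bool:
        return "true_class" in self.data.columns

    def indicator_frame(self) -> pd.DataFrame:
        return self.data[list(self.levels.keys())]


def indicator_codes(
    cohort: Cohort | pd.DataFrame, levels: dict[str, list[str]] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Integer-code the indicator columns against declared level sets.

    Returns an ``(n, J)`` int array (category index per indicator, in the
    declared order) and the list of level-set sizes.  An observation whose
    level is absent from the declared set raises ``ValueError`` naming the
    indicator and the offending level.
    """
    if isinstance(cohort, Cohort):
        df, levels = cohort.data, cohort.levels
    else:
        df = cohort
        if levels is None:
            levels = DEFAULT_LEVELS
    cols = []
    sizes = []
    for name, lv in levels.items():
        cat = pd.Categorical(df[name], categories=lv)
        codes = np.asarray(cat.codes)
        if (codes < 0).any():
            bad = sorted(set(np.asarray(df[name])[codes < 0].astype(str)))
            raise ValueError(
                f"indicator '{name}': unseen level(s) {bad}; declared levels are {lv}"
            )
        cols.append(codes.astype(np.int64))
        sizes.append(len(lv))
    return np.column_stack(cols), sizes


def validate_cohort(
    df: pd.DataFrame,
    levels: dict[str, list[str]] | None = None,
    max_reject_fraction: float = 1.0,
) -> Cohort:
    """Validate a raw table row-wise and return the surviving rows as a Cohort.

    Rows failing any check (unknown indicator level, missing value, negative
    or non-finite time, event code outside {0,1,2}) are dropped and counted;
    the count is logged.  If more than ``max_reject_fraction`` of rows fail,
    a ``ValueError`` is raised.
    """
    levels = dict(levels or DEFAULT_LEVELS)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")

    df = df.copy()
    ok = pd.Series(True, index=df.index)
    for name, lv in levels.items():
        in_set = df[name].isin(lv)
        n_bad = int((~in_set).sum())
        if n_bad:
            bad_vals = sorted(set(df.loc[~in_set, name].astype(str)))[:5]
            log.warning(
                "indicator '%s': %d row(s) with unknown level(s) %s rejected",
                name, n_bad, bad_vals,
            )
        ok &= in_set

    t = pd.to_numeric(df["time_months"], errors="coerce")
    ok &= t.notna() & np.isfinite(t) & (t >= 0)
    e = pd.to_numeric(df["event"], errors="coerce")
    ok &= e.isin([EVENT_CENSORED, EVENT_CANCER, EVENT_OTHER])
    ok &= df["patient_id"].notna()

    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("cohort validation rejected %d of %d rows", n_rejected, len(df))
    if len(df) and n_rejected / len(df) > max_reject_fraction:
        raise ValueError(
            f"{n_rejected} of {len(df)} rows failed validation "
            f"(> {max_reject_fraction:.0%} allowed)"
        )

    out = df.loc[ok].copy()
    out["time_months"] = t.loc[ok].astype(float)
    out["event"] = e.loc[ok].astype(int)
    out["patient_id"] = out["patient_id"].astype(str)
    for col in OPTIONAL_COLUMNS:
        if col in out.columns and out[col].isna().all():
            out = out.drop(columns=[col])
    if "true_class" in out.columns:
        out["true_class"] = out["true_class"].astype(int)
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in out.columns]
    out = out[keep].reset_index(drop=True)
    return Cohort(data=out, levels=levels, n_rejected=n_rejected)


def read_cohort(
    path,
    levels: dict[str, list[str]] | None = None,
    max_reject_fraction: float = 0.1,
) -> Cohort:
    """Read a cohort CSV (header row required) and validate it.

    More than ``max_reject_fraction`` rejected rows is a hard error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    return validate_cohort(df, levels=levels, max_reject_fraction=max_reject_fraction)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as CSV with a header row (optional columns only if present)."""
    cohort.data.to_csv(path, index=False)
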