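"""Dose-outcome statistics for sonication records.

Links the acoustic monitoring (total cavitation dose per sonication) to the
MRI outcomes (opening volume, delivered Gd, delivery efficiency): ordinary
least-squares regression of outcome on total dose (pooled and per subject)
and a two-tailed Student's t-test comparing SCDh between opened and
unopened sonications.  Significance threshold alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "SonicationRecord",
    "RegressionResult",
    "GroupComparison",
    "records_to_frame",
    "regress_dose_outcome",
    "compare_groups",
    "summary_table",
]

ALPHA = 0.05
OUTCOME_COLUMNS = {
    "volume": "opening_volume_mm3",
    "delivered": "gd_delivered_nmol",
    "efficiency": "delivery_efficiency_pct",
}


@dataclass(frozen=True)
class SonicationRecord:
    """One sonication: acoustic dose plus MRI outcome for one subject/session."""

    subject: str
    pressure_kpa: float
    scdh: float
    scdu: float
    icd: float
    opening_volume_mm3: float = np.nan
    gd_delivered_nmol: float = np.nan
    delivery_efficiency_pct: float = np.nan
    opened: bool | None = None
    sham: bool = False
    calibration: bool = False

    @property
    def total_dose(self) -> float:
        return self.scdh + self.scdu + self.icd


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float
    per_subject: dict[str, "RegressionResult"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "stderr": self.stderr,
        }
        if self.per_subject:
            d["per_subject"] = {k: v.to_dict() for k, v in self.per_subject.items()}
        return d


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    n_opened: int
    n_unopened: int
    significant: bool

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_opened": self.n_opened,
            "n_unopened": self.n_unopened,
            "significant": self.significant,
        }


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject": r.subject,
                "pressure_kpa": r.pressure_kpa,
                "scdh": r.scdh,
                "scdu": r.scdu,
                "icd": r.icd,
                "total_dose": r.total_dose,
                "opening_volume_mm3": r.opening_volume_mm3,
                "gd_delivered_nmol": r.gd_delivered_nmol,
                "delivery_efficiency_pct": r.delivery_efficiency_pct,
                "opened": r.opened,
                "sham": r.sham,
                "calibration": r.calibration,
            }
        )
    return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in the predictor (total dose)")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
        stderr=float(fit.stderr),
    )


def regress_dose_outcome(
    records,
    outcome: str = "volume",
    include_sham: bool = False,
    per_subject: bool = True,
) -> RegressionResult:
    """OLS of an opening outcome on the total cavitation dose.

    ``outcome`` is one of ``"volume"``, ``"delivered"``, ``"efficiency"``.
    Sham and calibration records are excluded by default.  Requires at
    least 3 usable records; per-subject fits (where a subject has >= 3)
    are attached to the pooled result.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise InvalidInputError(f"unknown outcome {outcome!r}")
    df = records_to_frame(records)
    if not include_sham and not df.empty:
        df = df[~df["sham"] & ~df["calibration"]]
    col = OUTCOME_COLUMNS[outcome]
    if not df.empty:
        df = df[np.isfinite(df["total_dose"]) & np.isfinite(df[col])]
    if len(df) < 3:
        raise InvalidInputError(f"need >= 3 records with finite dose and {outcome}")
    pooled = _ols(df["total_dose"].to_numpy(), df[col].to_numpy())
    if per_subject:
        for subject, grp in df.groupby("subject"):
            if len(grp) >= 3 and np.ptp(grp["total_dose"].to_numpy()) > 0:
                pooled.per_subject[str(subject)] = _ols(
                    grp["total_dose"].to_numpy(), grp[col].to_numpy()
                )
    return pooled


def compare_groups(values, opened_flags) -> GroupComparison:
    """Two-sample two-tailed Student's t-test (pooled variance).

    Typically applied to per-sonication SCDh split by whether a significant
    BBB opening was achieved.  Requires >= 2 values per group.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(opened_flags, dtype=bool)
    if values.shape != flags.shape:
        raise InvalidInputError("values and opened_flags must align")
    a = values[flags]
    b = values[~flags]
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs >= 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_statistic=float(t),
        p_value=float(p),
        n_opened=int(a.size),
        n_unopened=int(b.size),
        significant=bool(p < ALPHA),
    )


def summary_table(records) -> pd.DataFrame:
    """Per-subject summary of doses and outcomes (mean +/- SD, counts)."""
    df = records_to_frame(records)
    if df.empty:
        raise InvalidInputError("no records")
    df = df[~df["sham"] & ~df["calibration"]]
    agg = df.groupby("subject").agg(
        n=("total_dose", "size"),
        total_dose_mean=("total_dose", "mean"),
        total_dose_sd=("total_dose", "std"),
        volume_mean=("opening_volume_mm3", "mean"),
        volume_sd=("opening_volume_mm3", "std"),
        delivered_mean=("gd_delivered_nmol", "mean"),
        efficiency_mean=("delivery_efficiency_pct", "mean"),
    )
    return agg
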