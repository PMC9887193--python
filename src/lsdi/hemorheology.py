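"""Rheometer-side hemorheology calculations and small-sample statistics.

The imaging pipeline's product — whole blood relative viscosity (WBRV,
``eta_r``) — is validated against rotary-rheometer measurements: whole
blood viscosity (WBV) at a set of shear rates divided by plasma viscosity
(PV).  This module holds those calculations, the Doppler vascular
resistance index, exact small-sample rank statistics suited to groups of
five animals, and a bundled reference table of rheology records from a
rat study (normal controls, an erythropoietin-treated group with induced
hyperviscosity, and a glioma model group).
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


class ConstantInputError(ValueError):
    """Rank correlation undefined for constant input."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RheologyRecord:
    """One subject's rotary-rheometer panel.

    ``wbv_by_shear`` maps shear rate (1/s) to whole blood viscosity
    (mPa*s); ``pv`` is plasma viscosity (mPa*s); ``hct`` hematocrit
    fraction; ``ai``/``ri`` the aggregation and rigidity indices as
    reported by the rheometer.
    """

    subject_id: str
    group: str
    wbv_by_shear: dict
    pv: float
    hct: float
    ai: float
    ri: float

    def __post_init__(self) -> None:
        if not self.pv > 0:
            raise ValueError("plasma viscosity must be positive")
        for rate, wbv in self.wbv_by_shear.items():
            if wbv < self.pv:
                raise ValueError(
                    f"WBV {wbv} at {rate}/s below plasma viscosity {self.pv}"
                )

    def wbrv(self, shear_rate: float) -> float:
        """Whole blood relative viscosity WBV/PV at the given shear rate."""
        return relative_viscosity(self.wbv_by_shear[shear_rate], self.pv)


@dataclass(frozen=True)
class DopplerRecord:
    """Pulsed-Doppler velocity pair (mm/s)."""

    psv: float  # peak systolic velocity
    edv: float  # end-diastolic velocity

    def __post_init__(self) -> None:
        if not self.psv > 0:
            raise ValueError("PSV must be positive")
        if not 0 <= self.edv <= self.psv:
            raise ValueError("EDV must satisfy 0 <= EDV <= PSV")


# ---------------------------------------------------------------------------
# Scalar quantities
# ---------------------------------------------------------------------------

def relative_viscosity(wbv: float, pv: float) -> float:
    """WBRV = whole blood viscosity / plasma viscosity (dimensionless)."""
    if not pv > 0:
        raise ValueError(f"plasma viscosity must be positive, got {pv}")
    return wbv / pv


def vri(rec: DopplerRecord) -> float:
    """Vascular resistance index (PSV - EDV) / PSV, in [0, 1]."""
    return (rec.psv - rec.edv) / rec.psv


# ---------------------------------------------------------------------------
# Small-sample statistics
# ---------------------------------------------------------------------------

def mann_whitney_exact(group_a, group_b) -> tuple[float, float]:
    """Exact two-sided rank-sum test by full enumeration.

    Computes the Mann-Whitney U of ``group_a`` (number of (a, b) pairs with
    a > b, ties counted half) and the exact two-sided p-value: the
    proportion of all C(nA+nB, nA) relabelings whose U deviates from the
    null mean nA*nB/2 by at least as much as observed.  Intended for the
    tiny samples of animal studies (enumeration is capped at 12 per group);
    with n = 5 per group the smallest attainable p is 2/252 ~ 0.0079.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size > 12 or b.size > 12:
        raise ValueError("exact enumeration supports at most 12 per group")

    def u_stat(x, y):
        diff = x[:, None] - y[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_stat(a, b)
    pooled = np.concatenate([a, b])
    n = pooled.size
    n_a = a.size
    null_mean = n_a * (n - n_a) / 2.0
    dev_obs = abs(u_obs - null_mean)
    count = 0
    total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if abs(u - null_mean) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def students_t_test(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (normal-theory alternative).

    Provided alongside :func:`mann_whitney_exact` because the choice of
    test for n = 5 groups is a judgement call; the exact rank test makes
    no normality assumption.
    """
    t, p = scipy.stats.ttest_ind(group_a, group_b, equal_var=True)
    return float(t), float(p)


def spearman_rank(x, y) -> float:
    """Spearman rank correlation with midrank ties, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("rank correlation undefined for constant input")
    return float(scipy.stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Bundled reference table
# ---------------------------------------------------------------------------

# Rheology panel of 13 rats: normal controls (NC), erythropoietin-treated
# (EPO, drug-induced hyperviscosity) and glioma-bearing (C6).  WBV columns
# are whole blood viscosity (mPa*s) at 1, 50 and 200 1/s; PV is plasma
# viscosity (mPa*s); HCT hematocrit; AI/RI aggregation and rigidity index.
_TABLE_CSV = """\
subject_id,group,wbv_1,wbv_50,wbv_200,pv,hct,ai,ri
NC 1,NC,36.49,5.96,4.60,1.08,0.49,7.93,6.65
NC 2,NC,25.66,6.59,5.58,1.14,0.45,4.60,8.65
NC 3,NC,28.26,5.96,4.86,1.20,0.52,5.81,5.87
NC 4,NC,40.61,6.87,5.34,1.09,0.53,7.60,7.36
NC 5,NC,43.06,6.83,5.23,0.98,0.52,8.23,8.34
EPO 6,EPO,49.72,9.58,7.67,1.04,0.53,6.48,12.03
EPO 7,EPO,41.38,8.68,7.07,1.08,0.50,5.85,11.09
EPO 8,EPO,44.14,12.45,10.70,0.97,0.57,4.13,17.60
EPO 9,EPO,43.02,9.14,7.46,1.07,0.53,5.77,11.27
EPO 10,EPO,40.80,10.59,8.98,1.16,0.55,4.54,12.26
C6 11,C6,48.15,8.04,6.41,1.17,0.59,7.51,7.58
C6 12,C6,52.52,8.66,6.70,1.24,0.46,7.84,9.56
C6 13,C6,46.81,7.85,6.18,1.20,0.46,7.57,9.02
"""

#: Reported WBRV values (WBV/PV rounded to 2 decimals) for cross-checks.
REPORTED_WBRV = {
    1.0: [33.79, 22.51, 23.55, 37.26, 43.94, 47.81, 38.31, 45.51, 40.21,
          35.17, 41.15, 42.35, 39.01],
    200.0: [4.26, 4.89, 4.05, 4.90, 5.34, 7.38, 6.55, 11.03, 6.97, 7.74,
            5.47, 5.40, 5.15],
}


def table1_fixture() -> list[RheologyRecord]:
    """The bundled 13-subject rheology panel as records."""
    return records_from_frame(pd.read_csv(io.StringIO(_TABLE_CSV)))


def table1_frame() -> pd.DataFrame:
    """The bundled panel as a DataFrame (column layout of the CSV schema)."""
    return pd.read_csv(io.StringIO(_TABLE_CSV))


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

_SHEAR_COLUMNS = {"wbv_1": 1.0, "wbv_50": 50.0, "wbv_200": 200.0}


def records_from_frame(frame: pd.DataFrame) -> list[RheologyRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(
            RheologyRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                wbv_by_shear={
                    rate: float(row[col]) for col, rate in _SHEAR_COLUMNS.items()
                },
                pv=float(row["pv"]),
                hct=float(row["hct"]),
                ai=float(row["ai"]),
                ri=float(row["ri"]),
            )
        )
    return records


def read_rheology_csv(path) -> list[RheologyRecord]:
    """Read subject records from CSV (columns as in the bundled table)."""
    return records_from_frame(pd.read_csv(path))


def write_rheology_csv(records: list[RheologyRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "group": rec.group}
        for col, rate in _SHEAR_COLUMNS.items():
            row[col] = rec.wbv_by_shear[rate]
        row.update({"pv": rec.pv, "hct": rec.hct, "ai": rec.ai, "ri": rec.ri})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def compare_groups(
    records: list[RheologyRecord],
    group_a: str,
    group_b: str,
    shear_rate: float = 200.0,
    test: str = "exact",
) -> dict:
    """Compare WBRV between two groups at one shear rate.

    Returns a dict with the per-group WBRV values, the test statistic and
    the two-sided p-value (``test`` is "exact" for the enumerated rank test
    or "t" for the pooled t-test).
    """
    vals_a = [r.wbrv(shear_rate) for r in records if r.group == group_a]
    vals_b = [r.wbrv(shear_rate) for r in records if r.group == group_b]
    if test == "exact":
        stat, p = mann_whitney_exact(vals_a, vals_b)
    elif test == "t":
        stat, p = students_t_test(vals_a, vals_b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "group_a": group_a,
        "group_b": group_b,
        "shear_rate": shear_rate,
        "values_a": vals_a,
        "values_b": vals_b,
        "statistic": stat,
        "p_value": p,
        "test": test,
    }
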