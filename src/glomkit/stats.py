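"""Agreement and prognostic statistics.

Cohen's kappa between two raters, Spearman correlations, the
dependent-overlapping-correlation Z comparison, time-averaged
proteinuria, OLS eGFR slope, the ESRD event definition with its
3-month persistence clause, and the prognostic-table assembly.

Times are years throughout; 1 month = 1/12 year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ClinicalTrajectory, RPSClass

__all__ = [
    "AgreementResult",
    "SpearmanResult",
    "CorrelationComparison",
    "EsrdEvent",
    "FilterReport",
    "cohens_kappa",
    "spearman",
    "compare_dependent_correlations",
    "time_average_proteinuria",
    "egfr_slope",
    "esrd_event",
    "prognosis_filter",
    "prognostic_table",
    "PROGNOSTIC_INDICATORS",
]

ESRD_EGFR_THRESHOLD = 15.0
ESRD_PERSISTENCE_YEARS = 3.0 / 12.0
MIN_FOLLOWUP_YEARS = 1.0 / 12.0
MIN_BASELINE_EGFR = 30.0


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement; kappa is NaN when the expected
    agreement is 1 (both raters constant and equal)."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n: int


def cohens_kappa(a: Sequence, b: Sequence, weights: Optional[str] = None) -> AgreementResult:
    """Cohen's kappa between two raters over a shared label universe.

    ``weights=None`` is the unweighted kappa; ``weights="linear"``
    penalizes disagreements by ordinal distance (labels sorted by their
    natural order).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("cohens_kappa requires at least 2 paired ratings")
    labels = sorted(set(a) | set(b), key=lambda v: (str(type(v)), v))
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    table = np.zeros((k, k), dtype=float)
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    n = table.sum()
    table /= n

    if weights is None:
        w = np.eye(k)
    elif weights == "linear":
        idx = np.arange(k)
        w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / max(k - 1, 1)
    else:
        raise ValueError(f"unknown weights {weights!r}; expected None or 'linear'")

    po = float((w * table).sum())
    pe = float((w * np.outer(table.sum(axis=1), table.sum(axis=0))).sum())
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else math.nan
    return AgreementResult(kappa=kappa, observed_agreement=po, expected_agreement=pe,
                           n=int(n))


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    A constant input vector yields an explicit NaN result rather than an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(math.nan, math.nan, int(x.size))
    res = sps.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue), int(x.size))


@dataclass(frozen=True)
class CorrelationComparison:
    """Comparison of two dependent correlations r_jk and r_jh that share
    the variable j, with r_kh the correlation of the two predictors."""

    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z: float
    p: float
    method: str


def compare_dependent_correlations(r_jk: float, r_jh: float, r_kh: float, n: int,
                                   method: str = "hittner2003") -> CorrelationComparison:
    """Z test for two overlapping dependent correlations.

    The default is Dunn & Clark's z with the backtransformed average of
    the two Fisher-transformed correlations plugged into the covariance
    term (the variant reference implementations label "hittner2003").
    ``dunn1969``/``steiger1980`` use the plain average of the raw
    correlations; ``meng1992`` is Meng, Rosenthal & Rubin's z.
    """
    if n < 10:
        raise ValueError("compare_dependent_correlations requires n >= 10")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1 <= r <= 1:
            raise ValueError(f"{name} must be in [-1, 1], got {r}")
    if abs(r_jk) == 1 or abs(r_jh) == 1:
        raise ValueError("Fisher transform diverges at |r| = 1")

    zjk = math.atanh(r_jk)
    zjh = math.atanh(r_jh)
    if zjk == zjh:
        # equal correlations: Z = 0 by definition, even when the
        # covariance term degenerates (e.g. identical predictors, r_kh = 1)
        return CorrelationComparison(r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=int(n),
                                     z=0.0, p=1.0, method=method)
    if method in ("hittner2003", "dunn1969", "steiger1980"):
        if method == "hittner2003":
            rm = math.tanh((zjk + zjh) / 2.0)
        else:
            rm = (r_jk + r_jh) / 2.0
        rm2 = rm * rm
        cov = (r_kh * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r_kh**2)) / (
            (1.0 - rm2) ** 2
        )
        if cov >= 1.0:
            raise ValueError(
                "degenerate correlation structure (covariance term >= 1); "
                "the two predictors are effectively identical"
            )
        z = (zjk - zjh) * math.sqrt((n - 3) / (2.0 - 2.0 * cov))
    elif method == "meng1992":
        rbar2 = (r_jk**2 + r_jh**2) / 2.0
        f = min((1.0 - r_kh) / (2.0 * (1.0 - rbar2)), 1.0)
        h = (1.0 - f * rbar2) / (1.0 - rbar2)
        z = (zjk - zjh) * math.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    else:
        raise ValueError(
            f"unknown method {method!r}; expected hittner2003, dunn1969, "
            "steiger1980 or meng1992"
        )
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationComparison(r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=int(n),
                                 z=float(z), p=float(p), method=method)


# ---------------------------------------------------------------------------
# longitudinal renal function
# ---------------------------------------------------------------------------


def time_average_proteinuria(t: ClinicalTrajectory) -> float:
    """Trapezoidal AUC of proteinuria over time divided by the span of
    its measurements; NaN when fewer than two measurements exist."""
    ok = np.isfinite(t.proteinuria)
    if ok.sum() < 2:
        return math.nan
    times = t.times[ok]
    values = t.proteinuria[ok]
    return float(np.trapezoid(values, times) / (times[-1] - times[0]))


def egfr_slope(t: ClinicalTrajectory) -> float:
    """Ordinary-least-squares slope of eGFR on time, per year; NaN when
    fewer than two distinct visit times exist."""
    ok = np.isfinite(t.egfr)
    times = t.times[ok]
    if times.size < 2 or np.unique(times).size < 2:
        return math.nan
    return float(np.polyfit(times, t.egfr[ok], 1)[0])


@dataclass(frozen=True)
class EsrdEvent:
    event: bool
    time_years: float
    reason: Optional[str]


def esrd_event(t: ClinicalTrajectory) -> EsrdEvent:
    """ESRD: eGFR < 15 or dialysis persisting over 3 months, or renal
    transplantation (immediate).

    Persistence at visit resolution: the criterion must hold at every
    visit from its onset through the first visit at least 3 months
    later; a criterion holding at the final visit only (no later visit
    to confirm) also counts, as censoring-adjacent.
    """
    if np.any(t.transplant):
        i = int(np.argmax(t.transplant))
        return EsrdEvent(True, float(t.times[i]), "transplant")
    crit = (t.egfr < ESRD_EGFR_THRESHOLD) | t.dialysis
    n = crit.size
    for i in range(n):
        if not crit[i]:
            continue
        later = np.flatnonzero(t.times >= t.times[i] + ESRD_PERSISTENCE_YEARS)
        if later.size == 0:
            # no visit 3 months on; sustained through the end of follow-up?
            if crit[i:].all():
                return EsrdEvent(True, float(t.times[i]), "egfr_dialysis")
            continue
        j = int(later[0])
        if crit[i : j + 1].all():
            return EsrdEvent(True, float(t.times[i]), "egfr_dialysis")
    return EsrdEvent(False, math.nan, None)


@dataclass(frozen=True)
class FilterReport:
    n_total: int
    n_retained: int
    n_excluded_followup: int
    n_excluded_baseline_egfr: int


def prognosis_filter(visits: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Retain patients with follow-up >= 1 month and baseline eGFR >= 30.

    *visits* is the long table (``patient_id, time_years, egfr, ...``);
    returns the filtered table plus per-criterion exclusion counts (a
    patient may count against both criteria).
    """
    keep_ids = []
    n_fu = n_egfr = 0
    for pid, grp in visits.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_years")
        followup = grp["time_years"].iloc[-1] - grp["time_years"].iloc[0]
        baseline = grp["egfr"].iloc[0]
        bad_fu = followup < MIN_FOLLOWUP_YEARS
        bad_egfr = baseline < MIN_BASELINE_EGFR
        n_fu += int(bad_fu)
        n_egfr += int(bad_egfr)
        if not bad_fu and not bad_egfr:
            keep_ids.append(pid)
    n_total = visits["patient_id"].nunique()
    report = FilterReport(
        n_total=int(n_total), n_retained=len(keep_ids),
        n_excluded_followup=n_fu, n_excluded_baseline_egfr=n_egfr,
    )
    return visits[visits["patient_id"].isin(keep_ids)].copy(), report


# ---------------------------------------------------------------------------
# prognostic table
# ---------------------------------------------------------------------------

PROGNOSTIC_INDICATORS = (
    "baseline_proteinuria", "time_average_proteinuria",
    "baseline_egfr", "egfr_slope", "esrd",
)


def patient_indicators(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-patient prognostic indicators derived from the visits table."""
    rows = []
    for pid, grp in visits.groupby("patient_id", sort=True):
        traj = ClinicalTrajectory.from_frame(pid, grp)
        rows.append({
            "patient_id": pid,
            "baseline_proteinuria": traj.baseline_proteinuria,
            "time_average_proteinuria": time_average_proteinuria(traj),
            "baseline_egfr": traj.baseline_egfr,
            "egfr_slope": egfr_slope(traj),
            "esrd": int(esrd_event(traj).event),
        })
    return pd.DataFrame(rows).set_index("patient_id")


def _ordinal(classes: pd.Series) -> pd.Series:
    return classes.map(lambda c: int(RPSClass.parse(c)))


def prognostic_table(classes: pd.Series, visits: pd.DataFrame,
                     classes2: Optional[pd.Series] = None) -> pd.DataFrame:
    """Spearman correlation of ordinal class with each prognostic
    indicator; with a second class vector, a per-indicator Z comparison
    of the two dependent correlations.

    *classes* (and *classes2*) are Series indexed by patient_id holding
    RPS labels. Indicators with fewer than 3 non-missing values are
    omitted with a warning.
    """
    ind = patient_indicators(visits)
    ord_a = _ordinal(classes.dropna())
    ord_b = _ordinal(classes2.dropna()) if classes2 is not None else None

    rows = []
    for name in PROGNOSTIC_INDICATORS:
        common = ind.index.intersection(ord_a.index)
        if ord_b is not None:
            common = common.intersection(ord_b.index)
        values = ind.loc[common, name]
        ok = values.notna()
        if ok.sum() < 3:
            warnings.warn(f"indicator {name!r} has fewer than 3 non-missing values; omitted",
                          stacklevel=2)
            continue
        sub = values[ok]
        ra = spearman(ord_a.loc[sub.index], sub)
        row = {"indicator": name, "n": ra.n, "r": ra.r, "p": ra.p}
        if ord_b is not None:
            rb = spearman(ord_b.loc[sub.index], sub)
            rab = spearman(ord_a.loc[sub.index], ord_b.loc[sub.index])
            row.update({"r2": rb.r, "p2": rb.p, "r_raters": rab.r})
            if math.isnan(ra.r) or math.isnan(rb.r) or math.isnan(rab.r):
                row.update({"z": math.nan, "p_z": math.nan})
            else:
                try:
                    cmpres = compare_dependent_correlations(ra.r, rb.r, rab.r, ra.n)
                    row.update({"z": cmpres.z, "p_z": cmpres.p})
                except ValueError as exc:
                    warnings.warn(f"Z comparison unavailable for {name!r}: {exc}",
                                  stacklevel=2)
                    row.update({"z": math.nan, "p_z": math.nan})
        rows.append(row)
    return pd.DataFrame(rows)
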