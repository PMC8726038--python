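"""Response rates and training-vs-test baseline comparisons.

Response rates follow the registry convention: returned questionnaires divided
by performed THAs minus THAs of deceased patients.  Baseline comparisons pick
the test the data support: Shapiro–Wilk screens continuous variables for
normality, then Welch's t-test (normal) or the Mann-Whitney U test
(non-normal, with tie correction); categorical variables get Pearson's
chi-square unless an expected cell count falls below 5, in which case Fisher's
exact test is used for 2x2 tables.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

import numpy as np
from scipy import stats

from .instruments import (
    ASA,
    Charnley,
    Cohort,
    Instrument,
    Timepoint,
    score_hoos_ps,
    score_ohs_total,
)

__all__ = [
    "ResponseRateResult",
    "ComparisonMethod",
    "ComparisonRow",
    "response_rate",
    "compare_continuous",
    "compare_categorical",
    "baseline_table",
    "round_half_away",
    "percent_exact",
]


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent_exact(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage computed as an exact rational, then rounded half-away.

    Avoids binary-float artefacts at the rounding boundary: the quotient is
    carried as a :class:`~fractions.Fraction` until the final quantisation.
    """
    frac = Fraction(100 * numerator, denominator)
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResponseRateResult:
    n_returned: int
    n_thas: int
    n_deceased: int
    timepoint: Timepoint | None = None

    @property
    def denominator(self) -> int:
        return self.n_thas - self.n_deceased

    @property
    def rate(self) -> float:
        return self.n_returned / self.denominator

    @property
    def percent(self) -> float:
        """One-decimal percentage, exact-rational rounding."""
        return percent_exact(self.n_returned, self.denominator)


def response_rate(
    n_returned: int,
    n_thas: int,
    n_deceased: int = 0,
    timepoint: Timepoint | None = None,
) -> ResponseRateResult:
    """returned questionnaires / (THAs - THAs of deceased patients)."""
    if n_deceased >= n_thas:
        raise ValueError("n_deceased must be smaller than n_thas")
    if not (0 <= n_returned <= n_thas - n_deceased):
        raise ValueError(
            f"n_returned={n_returned} outside [0, {n_thas - n_deceased}]"
        )
    return ResponseRateResult(n_returned, n_thas, n_deceased, timepoint)


class ComparisonMethod(str, enum.Enum):
    T_TEST = "T_TEST"
    MANN_WHITNEY = "MANN_WHITNEY"
    CHI_SQUARE = "CHI_SQUARE"
    FISHER = "FISHER"


@dataclass
class ComparisonRow:
    variable: str
    summary_a: str
    summary_b: str
    method: ComparisonMethod | None
    statistic: float
    p_value: float
    notes: list[str] = field(default_factory=list)
    expected: np.ndarray | None = None


def _fmt_median_iqr(x: np.ndarray) -> str:
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})"


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False  # degenerate sample; treat as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def compare_continuous(
    a: np.ndarray,
    b: np.ndarray,
    normality_alpha: float = 0.05,
    *,
    welch: bool = True,
    variable: str = "",
) -> ComparisonRow:
    """t-test or Mann-Whitney U depending on the distribution of the data."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per sample")
    notes: list[str] = []
    if np.ptp(np.concatenate([a, b])) == 0:
        notes.append("all values identical in both samples")
        return ComparisonRow(variable, _fmt_median_iqr(a), _fmt_median_iqr(b),
                             ComparisonMethod.MANN_WHITNEY,
                             float(len(a) * len(b) / 2), 1.0, notes)
    if _is_normal(a, normality_alpha) and _is_normal(b, normality_alpha):
        res = stats.ttest_ind(a, b, equal_var=not welch)
        notes.append("Welch" if welch else "pooled")
        return ComparisonRow(variable, _fmt_mean_sd(a), _fmt_mean_sd(b),
                             ComparisonMethod.T_TEST,
                             float(res.statistic), float(res.pvalue), notes)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ComparisonRow(variable, _fmt_median_iqr(a), _fmt_median_iqr(b),
                         ComparisonMethod.MANN_WHITNEY,
                         float(res.statistic), float(res.pvalue), notes)


def _expected_counts(table: np.ndarray) -> np.ndarray:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    return rows * cols / table.sum()


def compare_categorical(table, *, variable: str = "") -> ComparisonRow:
    """Pearson chi-square, or Fisher's exact when an expected count is < 5.

    The expected-count rule applies Fisher only to 2x2 tables; larger sparse
    tables keep the chi-square with a warning note, matching common practice.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (table < 0).any() or (table != np.round(table)).any():
        raise ValueError("table must contain nonnegative integer counts")
    notes: list[str] = []
    zero_margin = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if zero_margin:
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table.astype(int))
            notes.append("zero margin; Fisher exact")
            return ComparisonRow(variable, "", "", ComparisonMethod.FISHER,
                                 float(odds), float(p), notes)
        raise ValueError("zero margin in a table larger than 2x2")
    expected = _expected_counts(table)
    if (expected < 5).any():
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table.astype(int))
            notes.append("expected count < 5; Fisher exact")
            return ComparisonRow(variable, "", "", ComparisonMethod.FISHER,
                                 float(odds), float(p), notes, expected)
        notes.append("expected count < 5; chi-square may be unreliable")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonRow(variable, "", "", ComparisonMethod.CHI_SQUARE,
                         float(chi2), float(p), notes, expected)


def _pre_values(cohort: Cohort, getter) -> np.ndarray:
    vals = [getter(r) for r in cohort.records]
    return np.asarray([v for v in vals if v is not None], dtype=float)


def baseline_table(training: Cohort, test: Cohort) -> list[ComparisonRow]:
    """One comparison row per baseline characteristic and preoperative PRO."""
    rows: list[ComparisonRow] = []

    def add_continuous(name, getter):
        a = _pre_values(training, getter)
        b = _pre_values(test, getter)
        if len(a) < 3 or len(b) < 3:
            rows.append(ComparisonRow(name, "", "", None, float("nan"),
                                      float("nan"), ["not computable"]))
            return
        rows.append(compare_continuous(a, b, variable=name))

    def add_2x2(name, predicate):
        t = [[sum(predicate(r) for r in c.records),
              sum(not predicate(r) for r in c.records)]
             for c in (training, test)]
        row = compare_categorical(t, variable=name)
        n_a, n_b = len(training.records), len(test.records)
        row.summary_a = f"{t[0][0]} ({percent_exact(t[0][0], n_a)})"
        row.summary_b = f"{t[1][0]} ({percent_exact(t[1][0], n_b)})"
        rows.append(row)

    add_continuous("age_years", lambda r: r.age_years)
    add_2x2("gender_male", lambda r: r.gender == "M")
    add_continuous("bmi_kg_m2", lambda r: r.bmi_kg_m2)
    add_2x2("asa_I", lambda r: r.asa is ASA.I)

    charnley_table = [[sum(r.charnley is c for r in coh.records)
                       for c in Charnley] for coh in (training, test)]
    charnley_table = np.asarray(charnley_table).T  # categories x cohorts
    rows.append(compare_categorical(charnley_table, variable="charnley"))

    add_continuous("nrs_rest_pre",
                   lambda r: r.get(Instrument.NRS_REST, 0, Timepoint.PRE))
    add_continuous("nrs_activity_pre",
                   lambda r: r.get(Instrument.NRS_ACTIVITY, 0, Timepoint.PRE))
    add_continuous("hoos_ps_pre", lambda r: score_hoos_ps(r, Timepoint.PRE))
    add_continuous("eq_vas_pre",
                   lambda r: r.get(Instrument.EQVAS, 0, Timepoint.PRE))
    add_continuous("ohs_total_pre", lambda r: score_ohs_total(r, Timepoint.PRE))
    return rows
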