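"""Exact contingency tests, Welch/rank-sum comparisons, diagnostic metrics,
and two-group survival comparison for small clinical cohorts.

The exact tests use the "small-p" two-sided convention: the p-value is the
total probability, under fixed margins, of every table whose hypergeometric
(or multivariate hypergeometric) probability does not exceed that of the
observed table, with a small relative tolerance for floating-point ties.
This is the convention of R's ``fisher.test`` and reproduces the printed
p-values of small published cohort tables; the alternative "doubling"
convention does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fisher_exact_2x2",
    "fisher_freeman_halton",
    "welch_t",
    "welch_t_from_summary",
    "wilcoxon_rank_sum",
    "DiagnosticResult",
    "diagnostic_performance",
    "reproduce_table1",
    "km_logrank",
]

_TIE_RTOL = 1e-7


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("contingency table must be 2-dimensional")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("contingency table must hold integer counts")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("contingency table counts must be nonnegative")
    return arr.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability is <= that of the observed table (relative tolerance
    1e-7), the convention matching R's fisher.test.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    # scipy's two-sided fisher_exact implements exactly this convention
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])


def fisher_freeman_halton(table, max_cells: int = 36, max_total: int = 200) -> float:
    """Two-sided Fisher-Freeman-Halton exact test for an r x c table.

    Enumerates every table with the observed margins, accumulating the
    probability of tables at most as probable as the observed one.  Intended
    for small clinical tables; raises if the enumeration bound is exceeded.
    Reduces exactly to :func:`fisher_exact_2x2` on 2x2 input.
    """
    arr = _as_table(table)
    r, c = arr.shape
    if r * c > max_cells:
        raise ValueError(
            f"table has {r * c} cells, enumeration bound is {max_cells}; "
            "consider a Monte Carlo approximation"
        )
    n = int(arr.sum())
    if n > max_total:
        raise ValueError(
            f"table total {n} exceeds enumeration bound {max_total}; "
            "consider a Monte Carlo approximation"
        )
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if r == 1 or c == 1:
        return 1.0  # margins determine the table uniquely
    lf = _log_factorials(n)
    log_const = lf[row].sum() + lf[col].sum() - lf[n]

    def log_prob(cells: np.ndarray) -> float:
        return log_const - lf[cells].sum()

    obs_lp = log_prob(arr.ravel())
    thresh = obs_lp + math.log1p(_TIE_RTOL)

    total = 0.0
    cells = np.zeros(r * c, dtype=np.int64)
    col_rem = col.copy()

    def recurse(i: int, lp_partial: float) -> None:
        nonlocal total
        if i == r - 1:
            # last row forced by column remainders
            if (col_rem > row[i]).any() or col_rem.sum() != row[i]:
                return
            cells[i * c : (i + 1) * c] = col_rem
            lp = lp_partial - lf[col_rem].sum()
            if lp <= thresh:
                total += math.exp(lp)
            return
        # enumerate row i cell by cell
        def fill(j: int, rem: int, lp_row: float) -> None:
            if j == c - 1:
                if rem > col_rem[c - 1]:
                    return
                cells[i * c + j] = rem
                col_rem[c - 1] -= rem
                recurse(i + 1, lp_row - lf[rem])
                col_rem[c - 1] += rem
                return
            for v in range(min(rem, col_rem[j]) + 1):
                cells[i * c + j] = v
                col_rem[j] -= v
                fill(j + 1, rem - v, lp_row - lf[v])
                col_rem[j] += v

        fill(0, int(row[i]), lp_partial)

    recurse(0, log_const)
    return float(min(total, 1.0))


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t test from group summaries: returns (t, df, two-sided p).

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite df.
    Both-degenerate groups with equal means return (0, df, 1) by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch's t test needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t test from raw samples: returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for combined n <= 20 without ties; normal approximation
    with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires nonempty samples")
    if x.size == y.size == 1 and x[0] == y[0]:
        return 1.0
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass(frozen=True)
class DiagnosticResult:
    """Confusion-matrix counts and derived metrics for a binary biomarker.

    Metrics with an empty denominator are ``None`` and rendered explicitly as
    "k/0" by :meth:`describe` rather than silently NaN — the all-negative-call
    case yields PPV 0/0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    def describe(self) -> dict[str, str]:
        return {
            "sensitivity": f"{self.tp}/{self.tp + self.fn}",
            "specificity": f"{self.tn}/{self.tn + self.fp}",
            "ppv": f"{self.tp}/{self.tp + self.fp}",
            "npv": f"{self.tn}/{self.tn + self.fn}",
        }


def diagnostic_performance(calls, condition) -> DiagnosticResult:
    """Confusion matrix of binary biomarker calls against a condition label.

    ``calls`` are test-positive flags (e.g. ctDNA detected) and ``condition``
    the condition-positive flags.  For MRD monitoring against pathological
    response the condition-positive class is non-response (nMPR): a positive
    ctDNA call is counted as a true positive when the patient failed to
    achieve a major pathological response.
    """
    calls = np.asarray(calls, dtype=bool)
    condition = np.asarray(condition, dtype=bool)
    if calls.shape != condition.shape:
        raise ValueError(
            f"calls and labels must align, got {calls.shape} vs {condition.shape}"
        )
    tp = int(np.sum(calls & condition))
    fp = int(np.sum(calls & ~condition))
    fn = int(np.sum(~calls & condition))
    tn = int(np.sum(~calls & ~condition))
    return DiagnosticResult(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Baseline-characteristics table
# ---------------------------------------------------------------------------

_CONTINUOUS = {"age"}


def _round_half_up(x: float, ndigits: int = 2) -> float:
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


def reproduce_table1(patients: pd.DataFrame, group_col: str = "mpr") -> pd.DataFrame:
    """Per-variable association tests of baseline characteristics vs response.

    ``patients`` holds one row per patient; ``group_col`` is a binary
    response flag (MPR yes/no).  Continuous variables (``age``) are compared
    with Welch's t test; binary factors with the 2x2 Fisher exact test;
    multi-level factors with the Freeman-Halton exact test.  Returns a frame
    with columns ``variable``, ``test``, ``p``, ``p_rounded`` (half-up, 2 dp).
    Constant response columns yield an empty frame with a warning.
    """
    if group_col not in patients.columns:
        raise ValueError(f"missing required column: {group_col}")
    group = patients[group_col].astype(bool)
    rows = []
    if group.nunique() < 2:
        import warnings

        warnings.warn("response column is constant; all tests skipped")
        return pd.DataFrame(columns=["variable", "test", "p", "p_rounded"])
    for col in patients.columns:
        if col == group_col:
            continue
        if col in _CONTINUOUS or pd.api.types.is_float_dtype(patients[col]):
            x = patients.loc[group, col].astype(float)
            y = patients.loc[~group, col].astype(float)
            _, _, p = welch_t(x, y)
            test = "welch_t"
        else:
            ct = pd.crosstab(patients[col], group)
            if ct.shape[0] < 2:
                continue
            if ct.shape == (2, 2):
                p = fisher_exact_2x2(ct.to_numpy())
                test = "fisher_exact"
            else:
                p = fisher_freeman_halton(ct.to_numpy())
                test = "freeman_halton"
        rows.append(
            {"variable": col, "test": test, "p": p, "p_rounded": _round_half_up(p)}
        )
    return pd.DataFrame(rows)


def km_logrank(survival: pd.DataFrame, time_col: str = "time",
               event_col: str = "event", group_col: str = "group"):
    """Kaplan-Meier curves and two-group log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to a
    fitted :class:`lifelines.KaplanMeierFitter`.  Exactly two groups are
    required; the log-rank statistic is referred to chi-square with 1 df.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = survival[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(groups)}")
    if (survival[time_col] < 0).any():
        raise ValueError("survival times must be nonnegative")
    curves = {}
    subsets = []
    for g in groups:
        sub = survival[survival[group_col] == g]
        km = KaplanMeierFitter(label=str(g))
        km.fit(sub[time_col], event_observed=sub[event_col])
        curves[g] = km
        subsets.append(sub)
    res = logrank_test(
        subsets[0][time_col], subsets[1][time_col],
        event_observed_A=subsets[0][event_col],
        event_observed_B=subsets[1][event_col],
    )
    return curves, float(res.test_statistic), float(res.p_value)
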