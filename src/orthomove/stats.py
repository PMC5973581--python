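"""Two-timepoint and two-group t-test layer.

Paired t-tests compare T1 with T2 within a group; independent-samples
t-tests (pooled-variance by default, Welch available) compare the
adolescent and adult groups.  Each test is also available directly from
summary statistics (mean, SD, n) so published tables can be re-analysed
without raw data.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError

DEFAULT_ALPHAS = (0.05, 0.01)


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group for a t-test."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise ValueError("mean and sd must be finite")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def of(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(float(v.mean()), float(v.std(ddof=1)), int(v.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: str

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def paired_t(differences) -> TTestResult:
    """Paired-sample t-test on precomputed within-pair differences.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``df = n - 1``.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("paired test needs at least 2 differences")
    sd = d.std(ddof=1)
    if sd <= 0:
        raise DegenerateTestError("zero variance of paired differences")
    return paired_t_from_summary(float(d.mean()), float(sd), int(d.size))


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> TTestResult:
    """Paired t-test from the mean and SD of the differences."""
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    if sd_diff <= 0:
        raise DegenerateTestError("zero variance of paired differences")
    t = mean_diff / (sd_diff / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), "paired")


def two_sample_t(a, b, method: str = "pooled") -> TTestResult:
    """Independent-samples t-test between two groups of raw values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    return two_sample_t_from_summary(GroupSummary.of(a), GroupSummary.of(b), method)


def two_sample_t_from_summary(
    g1: GroupSummary, g2: GroupSummary, method: str = "pooled"
) -> TTestResult:
    """Independent-samples t-test from (mean, sd, n) of each group.

    ``method="pooled"`` is the classic equal-variance test;
    ``method="welch"`` uses the Welch statistic with Satterthwaite
    degrees of freedom.
    """
    if method not in ("pooled", "welch"):
        raise ValueError(f"method must be 'pooled' or 'welch', got {method!r}")
    if g1.sd <= 0 and g2.sd <= 0:
        raise DegenerateTestError("both groups have zero variance")
    res = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(method == "pooled")
    )
    if method == "pooled":
        df = g1.n + g2.n - 2
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), method)


def _sig_marker(p: float, alphas=DEFAULT_ALPHAS) -> str:
    primary, secondary = alphas
    if p < secondary:
        return "**"
    if p < primary:
        return "*"
    return ""


def build_comparison_tables(
    g1_records: pd.DataFrame,
    g2_records: pd.DataFrame,
    method: str = "pooled",
    alphas=DEFAULT_ALPHAS,
) -> dict:
    """Between-group and within-group tables for per-patient change variables.

    Parameters
    ----------
    g1_records, g2_records
        One row per patient, one column per movement variable (values are
        T1 - T2 changes).  Variables present in only one group are
        reported with the other group's cells empty rather than raising.
    method
        Variance assumption for the between-group test; the other method
        is co-reported in the ``p_welch``/``p_pooled`` column.

    Returns
    -------
    dict with keys ``"between"`` (group means/SDs, t, p for both variance
    assumptions, significance marker) and ``"within"`` (per group: mean
    change, SD, paired t of the change against zero).
    """
    variables = list(
        dict.fromkeys(list(g1_records.columns) + list(g2_records.columns))
    )
    rows = []
    for var in variables:
        row: dict = {"variable": var}
        a = g1_records[var].dropna().to_numpy() if var in g1_records else np.array([])
        b = g2_records[var].dropna().to_numpy() if var in g2_records else np.array([])
        if a.size:
            row.update(g1_mean=a.mean(), g1_sd=a.std(ddof=1), g1_n=a.size)
        if b.size:
            row.update(g2_mean=b.mean(), g2_sd=b.std(ddof=1), g2_n=b.size)
        if a.size >= 2 and b.size >= 2:
            try:
                primary = two_sample_t(a, b, method)
                other = "welch" if method == "pooled" else "pooled"
                secondary = two_sample_t(a, b, other)
                row.update(
                    t=primary.t,
                    df=primary.df,
                    p=primary.p,
                    **{f"p_{other}": secondary.p},
                    sig=_sig_marker(primary.p, alphas),
                )
            except DegenerateTestError:
                row["note"] = "degenerate"
        else:
            row["note"] = "absent in one group"
        rows.append(row)
    between = pd.DataFrame(rows).set_index("variable")

    within = {}
    for label, rec in (("G1", g1_records), ("G2", g2_records)):
        wrows = []
        for var in rec.columns:
            vals = rec[var].dropna().to_numpy()
            wrow: dict = {"variable": var, "mean": vals.mean() if vals.size else np.nan}
            if vals.size >= 2:
                wrow["sd"] = vals.std(ddof=1)
                try:
                    res = paired_t(vals)
                    wrow.update(t=res.t, df=res.df, p=res.p, sig=_sig_marker(res.p, alphas))
                except DegenerateTestError:
                    wrow["note"] = "degenerate"
            wrows.append(wrow)
        within[label] = pd.DataFrame(wrows).set_index("variable")
    return {"between": between, "within": within}
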