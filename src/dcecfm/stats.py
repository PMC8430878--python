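"""Cohort statistics: rank-sum comparisons, Spearman correlation, percent
changes and the per-timepoint summary table.

Time points are compared with the two-sample Wilcoxon rank-sum (Mann-Whitney)
test — exams are missing for some subjects, so the comparison is unpaired —
and tumor-volume relationships are quantified with Spearman's rho, labeled
weak (|rho| <= 0.3), moderate (0.3, 0.7] or strong (0.7, 1].  No
multiple-testing correction is applied; the report footer says so.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .solver import TimepointSummary
from .synthetic import TIMEPOINTS

__all__ = [
    "CorrelationResult", "wilcoxon_compare", "spearman_corr",
    "percent_change", "cohort_table", "null_rejection_rate",
]

EXACT_MAX_N = 10  # exact rank-sum distribution up to this group size


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    category: str
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and not (-1.0 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("rho outside [-1, 1]")


def _categorize(rho: float) -> str:
    if not np.isfinite(rho):
        return "undefined"
    a = abs(rho)
    if a <= 0.3:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


def wilcoxon_compare(a: Sequence[float], b: Sequence[float],
                     method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``method`` is ``"exact"``, ``"asymptotic"`` or ``"auto"`` (exact when both
    groups have at most 10 observations and there are no ties, the normal
    approximation otherwise).  Returns (U statistic of the first group,
    p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "auto":
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "asymptotic" if (ties or max(a.size, b.size) > EXACT_MAX_N) else "exact"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    Pairs containing NaN are dropped; at least 3 complete pairs are required.
    A constant input vector leaves rho undefined (NaN, category "undefined").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(rho=np.nan, p_value=np.nan,
                                 category="undefined", n=int(x.size))
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p),
                             category=_categorize(float(rho)), n=int(x.size))


def percent_change(reference: float, comparison: float) -> float:
    """Percent change of ``comparison`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (comparison - reference) / reference


def cohort_table(summaries: Iterable[TimepointSummary]) -> tuple[pd.DataFrame, str]:
    """Build the cohort table and a formatted report.

    One row per subject x time point with V_t, mean Ktrans, mean IFP and mean
    IFV; the report gives per-timepoint mean +/- SD, all pairwise rank-sum
    p-values, and per-timepoint Spearman correlations of tumor volume with
    IFP and IFV.  Missing exams are simply absent rows and are excluded
    pairwise.  Output is independent of input order.
    """
    rows = [
        {"subject": s.subject, "timepoint": s.label, "vt_cm3": s.vt_cm3,
         "ktrans_min": s.mean_ktrans, "ifp_kpa": s.mean_ifp_kpa,
         "ifv_m_s": s.mean_ifv}
        for s in summaries
    ]
    if not rows:
        raise ValueError("no summaries provided")
    df = pd.DataFrame(rows)
    bad = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad:
        raise ValueError(f"unknown time point labels: {sorted(bad)}")
    df = df.sort_values(["timepoint", "subject"], key=lambda c: c.map(
        {t: i for i, t in enumerate(TIMEPOINTS)}) if c.name == "timepoint" else c)
    df = df.reset_index(drop=True)

    metrics = [("ktrans_min", "Ktrans (min^-1)"), ("ifp_kpa", "IFP (kPa)"),
               ("ifv_m_s", "IFV (m/s)")]
    lines = ["Cohort summary (mean +/- SD per time point)", ""]
    present = [t for t in TIMEPOINTS if (df["timepoint"] == t).any()]
    for col, name in metrics:
        parts = []
        for t in present:
            v = df.loc[df["timepoint"] == t, col]
            parts.append(f"{t}: {v.mean():.3g} +/- {v.std(ddof=0):.3g} (N={v.size})")
        lines.append(f"{name}  " + " | ".join(parts))
    lines.append("")

    enough = {t: (df["timepoint"] == t).sum() >= 2 for t in present}
    lines.append("Pairwise Wilcoxon rank-sum p-values:")
    for i, ta in enumerate(present):
        for tb in present[i + 1:]:
            for col, name in metrics:
                va = df.loc[df["timepoint"] == ta, col].to_numpy()
                vb = df.loc[df["timepoint"] == tb, col].to_numpy()
                if enough[ta] and enough[tb]:
                    _, p = wilcoxon_compare(va, vb)
                    lines.append(f"  {name}: {ta} vs {tb}  p = {p:.3g}")
                else:
                    lines.append(f"  {name}: {ta} vs {tb}  skipped "
                                 "(fewer than 2 subjects in a group)")
    lines.append("")
    lines.append("Spearman correlations with tumor volume:")
    for t in present:
        sub = df[df["timepoint"] == t]
        for col, name in (("ifp_kpa", "IFP"), ("ifv_m_s", "IFV")):
            if len(sub) >= 3:
                r = spearman_corr(sub["vt_cm3"], sub[col])
                lines.append(f"  {t}: V_t vs {name}  rho = {r.rho:.2f} "
                             f"({r.category}), p = {r.p_value:.3g}")
            else:
                lines.append(f"  {t}: V_t vs {name}  skipped (N < 3)")
    lines.append("")
    lines.append("Note: p-values are not corrected for multiple comparisons.")
    return df, "\n".join(lines)


def null_rejection_rate(n_a: int, n_b: int, n_sims: int, alpha: float = 0.05,
                        seed: int = 0, method: str = "exact") -> float:
    """Empirical type-I error of the rank-sum test under a shared null.

    Draws both groups from one continuous distribution ``n_sims`` times and
    returns the fraction of two-sided p-values at or below ``alpha``.  The
    p-values are computed from the exact Mann-Whitney null distribution
    (evaluated once), matching :func:`wilcoxon_compare` in exact mode.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n_a + n_b))
    ranks = sps.rankdata(x, axis=1)
    u = ranks[:, :n_a].sum(axis=1) - n_a * (n_a + 1) / 2.0

    if method == "exact":
        pmf = _mwu_null_pmf(n_a, n_b)
        cdf = np.cumsum(pmf)
        sf = np.cumsum(pmf[::-1])[::-1]
        ui = np.rint(u).astype(int)
        p = np.minimum(1.0, 2.0 * np.minimum(cdf[ui], sf[ui]))
    else:
        mu = n_a * n_b / 2.0
        sd = np.sqrt(n_a * n_b * (n_a + n_b + 1) / 12.0)
        z = (np.abs(u - mu) - 0.5) / sd
        p = 2.0 * sps.norm.sf(z)
    return float(np.mean(p <= alpha))


def _mwu_null_pmf(n: int, m: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic (no ties).

    Coefficients of the Gaussian binomial [n+m choose n]_q, i.e. the number
    of partitions of u into at most n parts each at most m, computed by
    iterated polynomial multiplication by (1 - q^(m+k)) and exact power-
    series division by (1 - q^k).
    """
    size = n * m + 1
    c = np.zeros(size)
    c[0] = 1.0
    for k in range(1, n + 1):
        d = c.copy()
        if m + k < size:
            d[m + k:] -= c[: size - (m + k)]
        for u in range(k, size):  # divide by (1 - q^k)
            d[u] += d[u - k]
        c = d
    return c / c.sum()
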