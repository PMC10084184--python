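"""Group-level statistics for fibrosis studies.

Implements the comparisons used in small-animal fibrosis cohorts:
Welch's unequal-variance t-test between treatment and control, paired
t-tests across timepoints, one-sided tests against ordinal inflammation
scores, and Pearson correlation between imaging parameters and
quantitative histology with 95% prediction bands. Per-test alpha = 0.05,
no multiple-testing correction. Group summaries are mean +/- SD across
animals; fitted parameters carry mean +/- CI95 from the fit itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "PearsonBandResult",
    "welch_t_test",
    "paired_t_test",
    "one_sided_t_test",
    "pearson_with_prediction_band",
    "percent_change",
    "group_report",
]

#: Columns of a group table (one row per animal x timepoint).
GROUP_TABLE_COLUMNS = (
    "animal_id", "group", "timepoint_weeks", "F", "T1_ms",
    "high_f_percent", "histology_percent", "inflammation_score",
)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def _as_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise ValueError(f"{name} must be 1D with at least {min_n} values")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite degrees of freedom."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 0.0, float(na + nb - 2)  # both constant: t=0 by convention
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def welch_t_test(a, b) -> TTestResult:
    """Two-sided Welch's t-test (unequal variances).

    Degenerate zero-variance samples with equal means return t = 0, p = 1.
    """
    a, b = _as_sample(a, "a"), _as_sample(b, "b")
    t, df = _welch(a, b)
    if a.var(ddof=1) == b.var(ddof=1) == 0.0 and a.mean() != b.mean():
        return TTestResult(t=np.inf * np.sign(a.mean() - b.mean()), df=df, p=0.0)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=float(p))


def one_sided_t_test(a, b, alternative: str = "greater") -> TTestResult:
    """One-sided Welch's t-test; ``alternative`` is 'greater' or 'less' (a vs b)."""
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a, b = _as_sample(a, "a"), _as_sample(b, "b")
    t, df = _welch(a, b)
    p = sps.t.sf(t, df) if alternative == "greater" else sps.t.cdf(t, df)
    return TTestResult(t=t, df=df, p=float(p))


def paired_t_test(pre, post) -> TTestResult:
    """Paired t-test on differences post - pre, df = n - 1."""
    pre, post = _as_sample(pre, "pre"), _as_sample(post, "post")
    if pre.size != post.size:
        raise ValueError("paired samples must have equal length")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("paired differences have zero variance; test degenerate")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=float(n - 1), p=float(p))


@dataclass
class PearsonBandResult:
    """Pearson correlation with OLS line and per-x 95% prediction band."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int
    level: float
    _s: float
    _x_mean: float
    _sxx: float

    def prediction_band(self, x_new) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper prediction bounds for a new observation at x_new."""
        x_new = np.asarray(x_new, dtype=float)
        fit = self.intercept + self.slope * x_new
        tq = sps.t.ppf(0.5 + self.level / 2.0, self.n - 2)
        half = self._s * tq * np.sqrt(
            1.0 + 1.0 / self.n + (x_new - self._x_mean) ** 2 / self._sxx
        )
        return fit - half, fit + half


def pearson_with_prediction_band(x, y, level: float = 0.95) -> PearsonBandResult:
    """Pearson r with OLS regression line and prediction interval.

    p is two-sided from t = r*sqrt((n-2)/(1-r^2)); the band half-width at x
    is s * t_{n-2} * sqrt(1 + 1/n + (x - xbar)^2 / Sxx) with s the residual
    standard error of the OLS fit.
    """
    x = _as_sample(x, "x", min_n=3)
    y = _as_sample(y, "y", min_n=3)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant; correlation undefined")
    r, p = sps.pearsonr(x, y)
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    n = x.size
    s = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else np.nan
    return PearsonBandResult(
        r=float(r), p=float(p), slope=slope, intercept=intercept,
        n=n, level=level, _s=s, _x_mean=float(x.mean()), _sxx=sxx,
    )


def percent_change(reference_mean: float, other_mean: float) -> float:
    """100 * (other - reference) / reference."""
    if reference_mean == 0:
        raise ValueError("reference mean is zero; percent change undefined")
    return 100.0 * (other_mean - reference_mean) / reference_mean


def group_report(table: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Run the standard comparison battery on a group table.

    Expects columns ``group`` ('control'/'fibrosis'), ``F``, ``T1_ms`` and
    optionally ``histology_percent``, ``high_f_percent``,
    ``inflammation_score``. Returns a tidy results frame and a
    human-readable text report.
    """
    rows: list[dict] = []
    lines: list[str] = ["Group statistics report", "=" * 24]

    ctrl = table[table["group"] == "control"]
    fib = table[table["group"] == "fibrosis"]

    for col, label in (("F", "F"), ("T1_ms", "T1 (ms)")):
        if len(ctrl) >= 2 and len(fib) >= 2:
            res = welch_t_test(fib[col], ctrl[col])
            change = percent_change(ctrl[col].mean(), fib[col].mean())
            rows.append({
                "comparison": f"{label}: fibrosis vs control (Welch)",
                "statistic": res.t, "df": res.df, "p": res.p,
                "percent_change": change,
            })
            lines.append(
                f"{label}: fibrosis {fib[col].mean():.4g} +/- {fib[col].std(ddof=1):.2g} "
                f"vs control {ctrl[col].mean():.4g} +/- {ctrl[col].std(ddof=1):.2g} "
                f"({change:+.1f}%), Welch t={res.t:.3f}, df={res.df:.2f}, p={res.p:.4g}"
            )

    if "histology_percent" in table and table["histology_percent"].notna().all():
        for col, label in (("F", "F"), ("high_f_percent", "high-F %")):
            if col in table:
                res = pearson_with_prediction_band(
                    table[col], table["histology_percent"]
                )
                rows.append({
                    "comparison": f"Pearson {label} vs histology %",
                    "statistic": res.r, "df": float(res.n - 2), "p": res.p,
                    "percent_change": np.nan,
                })
                lines.append(
                    f"Pearson {label} vs histology%: R={res.r:.3f}, p={res.p:.4g} "
                    f"(slope {res.slope:.4g}, intercept {res.intercept:.4g})"
                )

    if "inflammation_score" in table and table["inflammation_score"].notna().all():
        scores = sorted(table["inflammation_score"].unique())
        for lo, hi in zip(scores, scores[1:]):
            a = table.loc[table["inflammation_score"] == hi, "T1_ms"]
            b = table.loc[table["inflammation_score"] == lo, "T1_ms"]
            if len(a) >= 2 and len(b) >= 2:
                res = one_sided_t_test(a, b, alternative="greater")
                rows.append({
                    "comparison": f"T1: inflammation {hi} > {lo} (one-sided)",
                    "statistic": res.t, "df": res.df, "p": res.p,
                    "percent_change": percent_change(b.mean(), a.mean()),
                })
                lines.append(
                    f"T1 inflammation {hi} vs {lo}: one-sided t={res.t:.3f}, "
                    f"df={res.df:.2f}, p={res.p:.4g}"
                )

    return pd.DataFrame(rows), "\n".join(lines) + "\n"
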