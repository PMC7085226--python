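"""Two-group summaries and t-tests for the pre-/post-therapy comparison.

Each sample contributes one value per metric (mean nuclear area in px^2,
collagen content in %); groups are summarized as mean +/- sample SD and
compared with a two-sample t-test. The pooled ("Student") variant is the
default; Welch's unequal-variance variant is available and both are
reported in machine-readable outputs. With equal group sizes the two t
statistics coincide (their degrees of freedom differ).

Pooled:  t = (mean_b - mean_a) / (s_p * sqrt(1/n_a + 1/n_b)),
         s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2),
         df = n_a + n_b - 2.
Welch:   t = (mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b),
         Satterthwaite df.

Degenerate inputs follow a documented convention: zero variance with equal
means gives t = 0, p = 1; zero variance with unequal means gives an
infinite t with p = 0, flagged via ``zero_variance``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import InsufficientDataError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "t_test_from_summary",
    "t_test_from_values",
    "compare_groups",
    "p_value_bin",
]

ALPHA_DEFAULT = 0.05

METRICS = ("nuclear_area_px2", "collagen_content_pct")


@dataclass
class GroupSummary:
    group: str
    metric: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(
                f"group {self.group!r}: n={self.n} but the SD needs n >= 2"
            )
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f} (n={self.n})"


@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    variant: str
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")


def summarize(values, group: str = "", metric: str = "") -> GroupSummary:
    """Mean and sample SD (n-1 denominator) of per-sample metric values."""
    arr = np.asarray(list(values), dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 finite values, got {arr.size}"
        )
    return GroupSummary(
        group=group,
        metric=metric,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
    )


def _two_sided_p(t: float, df: float) -> float:
    return float(2.0 * t_dist.sf(abs(t), df))


def t_test_from_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: str = "pooled",
    alpha: float = ALPHA_DEFAULT,
) -> TTestResult:
    """Two-sided two-sample t-test from summary statistics.

    The statistic is oriented as (b - a): positive when group b's mean
    exceeds group a's.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    diff = b.mean - a.mean
    if variant == "pooled":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        if va + vb > 0:
            df = (va + vb) ** 2 / (
                va**2 / (a.n - 1) + vb**2 / (b.n - 1)
            )
        else:
            df = float(a.n + b.n - 2)

    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, False, variant, zero_variance=True)
        t = math.inf if diff > 0 else -math.inf
        return TTestResult(t, df, 0.0, True, variant, zero_variance=True)

    t = diff / se
    p = _two_sided_p(t, df)
    return TTestResult(t, df, p, p < alpha, variant)


def t_test_from_values(
    a, b, variant: str = "pooled", alpha: float = ALPHA_DEFAULT
) -> TTestResult:
    """Two-sample t-test from raw per-sample values (via :func:`summarize`)."""
    return t_test_from_summary(
        summarize(a, group="a"), summarize(b, group="b"), variant=variant, alpha=alpha
    )


def p_value_bin(p: float) -> str:
    """Reporting-style bin for a p-value: <0.001, <0.01, <0.05 or ns."""
    for cut, label in ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05")):
        if p < cut:
            return label
    return "ns"


def compare_groups(
    pre_metrics: pd.DataFrame,
    post_metrics: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    variant: str = "pooled",
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Per-metric group comparison table (one row per metric).

    Both inputs need one column per metric with one row per sample. The
    output mirrors the usual two-group summary layout: n/mean/SD for each
    group, the requested t-test, its Welch counterpart, exact p-values and
    a reporting bin.
    """
    rows = []
    for metric in metrics:
        for name, df in (("pre", pre_metrics), ("post", post_metrics)):
            if metric not in df.columns:
                raise KeyError(f"{name} table lacks column {metric!r}")
        pre = summarize(pre_metrics[metric], group="pre", metric=metric)
        post = summarize(post_metrics[metric], group="post", metric=metric)
        main = t_test_from_summary(pre, post, variant=variant, alpha=alpha)
        welch = t_test_from_summary(pre, post, variant="welch", alpha=alpha)
        rows.append(
            dict(
                metric=metric,
                n_pre=pre.n,
                mean_pre=pre.mean,
                sd_pre=pre.sd,
                n_post=post.n,
                mean_post=post.mean,
                sd_post=post.sd,
                variant=main.variant,
                t_statistic=main.t_statistic,
                degrees_of_freedom=main.degrees_of_freedom,
                p_value=main.p_value,
                p_bin=p_value_bin(main.p_value),
                significant=main.significant,
                welch_t=welch.t_statistic,
                welch_df=welch.degrees_of_freedom,
                welch_p=welch.p_value,
            )
        )
    return pd.DataFrame(rows)
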