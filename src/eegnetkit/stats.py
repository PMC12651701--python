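"""Pre/post paired comparisons, significance coding, cohort summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    """Outcome of one paired pre/post test.

    ``degenerate`` is set when the paired differences have zero variance;
    such results are reported as-is, never converted to significance.
    """

    t: float
    p: float
    df: int
    stars: str
    mean_pre: float
    mean_post: float
    effect_direction: int  # sign of mean(post - pre)
    degenerate: bool = False


def significance_stars(p: float) -> str:
    """Star coding: '***' p<0.001, '**' p<0.01, '*' p<0.05, '' otherwise (strict)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_t(pre, post) -> StatResult:
    """Two-sided paired-samples t-test on d = post - pre.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample (ddof=1) standard
    deviation; p from the t distribution with n-1 degrees of freedom.
    Zero-variance differences take a degenerate path: t = 0, p = 1 when all
    differences vanish, |t| = inf, p = 0 for a perfectly constant non-zero
    shift — flagged, never silently dropped.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("paired test needs at least 2 subjects")
    d = post - pre
    mean_d = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    direction = int(np.sign(mean_d))
    if sd == 0:
        if mean_d == 0:
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p, degenerate = float(np.sign(mean_d)) * np.inf, 0.0, True
    else:
        t = mean_d / (sd / np.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), df))
        degenerate = False
    return StatResult(
        t=float(t), p=float(p), df=df, stars=significance_stars(p),
        mean_pre=float(pre.mean()), mean_post=float(post.mean()),
        effect_direction=direction, degenerate=degenerate,
    )


def improvement_proportion(pre_scores, post_scores) -> dict:
    """Counts of improved/stable/declined subjects and % improved (1 decimal)."""
    pre = np.asarray(pre_scores)
    post = np.asarray(post_scores)
    if pre.shape != post.shape:
        raise ValueError("pre and post score lists must have equal length")
    d = post - pre
    n = len(d)
    improved = int((d > 0).sum())
    stable = int((d == 0).sum())
    declined = int((d < 0).sum())
    return {
        "improved": improved,
        "stable": stable,
        "declined": declined,
        "pct_improved": round(100.0 * improved / n, 1),
    }


def multiple_testing_adjust(p_values, method: str = "none") -> np.ndarray:
    """Optionally adjust a family of p-values ('none' = identity, 'bh' = FDR)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r} (use 'none' or 'bh')")


def compare_conditions(
    table: pd.DataFrame,
    value_col: str = "value",
    group_cols: tuple[str, ...] = ("band", "order", "metric", "scope"),
    adjust: str = "none",
) -> pd.DataFrame:
    """Paired pre/post test for every metric group in a tidy table.

    ``table`` needs columns ``subject``, ``condition`` ('pre'/'post'),
    ``value_col`` and the grouping columns. Returns one row per group with
    n, means, t, p, adjusted p, and stars.
    """
    rows = []
    for keys, grp in table.groupby(list(group_cols), dropna=False, sort=True):
        wide = grp.pivot_table(index="subject", columns="condition", values=value_col)
        if not {"pre", "post"}.issubset(wide.columns):
            continue
        wide = wide.dropna(subset=["pre", "post"])
        if len(wide) < 2:
            continue
        res = paired_t(wide["pre"].to_numpy(), wide["post"].to_numpy())
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row.update(
            n=len(wide), mean_pre=res.mean_pre, mean_post=res.mean_post,
            t=res.t, p=res.p, degenerate=res.degenerate,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multiple_testing_adjust(out["p"].to_numpy(), method=adjust)
        out["stars"] = [
            significance_stars(p) if np.isfinite(p) else "" for p in out["p_adjusted"]
        ]
        out["adjust_method"] = adjust
    return out
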