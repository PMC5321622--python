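"""Intraclass correlation reliability of landmark annotations.

Inter- and intra-rater reliability of frame-by-frame coordinate annotation
is quantified with the two-way random-effects, absolute-agreement,
single-measure intraclass correlation, ICC(2,1): targets (video-frames) and
raters are both random samples, and a rater's systematic offset counts
against agreement. From the two-way ANOVA mean squares (rows MSR, columns
MSC, error MSE) of an n-targets x k-raters matrix,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the standard F-based 95% confidence interval (Shrout-Fleiss /
McGraw-Wong) using the Satterthwaite degrees of freedom for the lower/upper
bounds.

Targets are pooled video-frames of one coordinate axis (e.g. landmark 11's
x), on raw pixel coordinates — annotation reliability precedes Procrustes
alignment. :func:`reliability_report` assembles one ICC per
(rater/trial comparison x landmark x axis) from a compiled table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CoverageError, RatingSizeError

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class RatingMatrix:
    """n targets x k raters/trials of one coordinate axis."""

    values: np.ndarray = field(repr=False)
    axis_label: str = ""
    comparison_label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise RatingSizeError(f"rating matrix must be 2-D, got {vals.ndim}-D")
        n, k = vals.shape
        if n < 2 or k < 2:
            raise RatingSizeError(
                f"need >= 2 targets and >= 2 raters, got {n} x {k}"
            )
        if not np.all(np.isfinite(vals)):
            raise RatingSizeError("rating matrix has missing/non-finite cells")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) estimate with its 95% confidence interval and mean squares."""

    estimate: float
    ci_lower: float
    ci_upper: float
    n: int
    k: int
    alpha: float = 0.05
    msr: float = 0.0
    msc: float = 0.0
    mse: float = 0.0
    degenerate: bool = False
    axis_label: str = ""
    comparison_label: str = ""


def _anova_mean_squares(vals: np.ndarray) -> tuple[float, float, float]:
    """Two-way (targets x raters) ANOVA mean squares: MSR, MSC, MSE."""
    n, k = vals.shape
    grand = vals.mean()
    row_means = vals.mean(axis=1)
    col_means = vals.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    # residual SS computed definitionally (not by subtraction): exact zero
    # for e.g. duplicated columns, where sst - ssr - ssc leaves rounding noise
    resid = vals - row_means[:, None] - col_means[None, :] + grand
    sse = (resid**2).sum()
    return (
        ssr / (n - 1),
        ssc / (k - 1),
        sse / ((n - 1) * (k - 1)),
    )


def icc_2_1(matrix: RatingMatrix, alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    All-equal (zero-total-variance) input is degenerate: perfect agreement
    is reported (estimate 1, CI collapsed to 1) with the ``degenerate`` flag
    set, rather than dividing 0/0. An exact column-duplicate matrix is not
    degenerate and yields exactly 1.0 through the formula (MSE = MSC = 0).
    """
    vals = matrix.values
    n, k = vals.shape
    sst = ((vals - vals.mean()) ** 2).sum()
    if sst < _DEGENERATE_TOL:
        return ICCResult(
            estimate=1.0, ci_lower=1.0, ci_upper=1.0, n=n, k=k, alpha=alpha,
            degenerate=True, axis_label=matrix.axis_label,
            comparison_label=matrix.comparison_label,
        )
    msr, msc, mse = _anova_mean_squares(vals)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    est = (msr - mse) / denom

    if 1.0 - est < 1e-12:
        lower = upper = est  # perfect agreement: F interval undefined
    else:
        # Satterthwaite df for the ICC(2,1) confidence bounds
        a = (k * est) / (n * (1.0 - est))
        b = 1.0 + (k * est * (n - 1.0)) / (n * (1.0 - est))
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if v_den > 0 else (n - 1.0)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
        lower = min(lower, est)
        upper = max(upper, est)
    return ICCResult(
        estimate=float(est),
        ci_lower=float(lower),
        ci_upper=float(upper),
        n=n,
        k=k,
        alpha=alpha,
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
        axis_label=matrix.axis_label,
        comparison_label=matrix.comparison_label,
    )


Comparison = tuple[tuple[str, str], tuple[str, str]]


def _axis_series(
    table: pd.DataFrame,
    rater_id: str,
    trial_id: str,
    landmark_id: int,
    axis: str,
) -> pd.Series:
    sub = table[
        (table["rater_id"] == rater_id)
        & (table["trial_id"] == trial_id)
        & (table["landmark_id"] == landmark_id)
    ]
    if sub.empty:
        raise CoverageError(
            f"no data for rater={rater_id!r} trial={trial_id!r} "
            f"landmark={landmark_id}"
        )
    sub = sub.sort_values(["video_id", "frame_index"], kind="mergesort")
    return sub.set_index(["video_id", "frame_index"])[axis]


def comparison_label(comparison: Comparison) -> str:
    (ra, ta), (rb, tb) = comparison
    return f"{ra}/{ta} vs {rb}/{tb}"


def reliability_report(
    table: pd.DataFrame,
    comparisons: Sequence[Comparison],
    landmark_ids: Sequence[int] = (11, 12),
    axes: Sequence[str] = ("x", "y"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One ICC(2,1) per (comparison x landmark x axis) from a compiled table.

    ``comparisons`` are pairs of (rater_id, trial_id) tuples, e.g.
    ``((("R1", "T1"), ("R2", "T1")))`` for inter-rater agreement at trial 1.
    Both members must cover the identical (video, frame) targets, otherwise
    :class:`CoverageError` lists the mismatch. Returns a tidy table with
    columns comparison, landmark_id, axis, icc, ci_lower, ci_upper, n, k,
    degenerate.
    """
    rows = []
    for comp in comparisons:
        (ra, ta), (rb, tb) = comp
        label = comparison_label(comp)
        for lm in landmark_ids:
            for axis in axes:
                s_a = _axis_series(table, ra, ta, lm, axis)
                s_b = _axis_series(table, rb, tb, lm, axis)
                if not s_a.index.equals(s_b.index):
                    missing = s_a.index.symmetric_difference(s_b.index)
                    raise CoverageError(
                        f"{label}: targets differ for landmark {lm}{axis}; "
                        f"mismatched keys {missing[:5].tolist()}"
                    )
                res = icc_2_1(
                    RatingMatrix(
                        np.column_stack([s_a.to_numpy(), s_b.to_numpy()]),
                        axis_label=f"{lm}{axis}",
                        comparison_label=label,
                    ),
                    alpha=alpha,
                )
                rows.append(
                    {
                        "comparison": label,
                        "landmark_id": lm,
                        "axis": axis,
                        "icc": res.estimate,
                        "ci_lower": res.ci_lower,
                        "ci_upper": res.ci_upper,
                        "n": res.n,
                        "k": res.k,
                        "degenerate": res.degenerate,
                    }
                )
    return pd.DataFrame(rows)


def report_to_wide(report: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy report to the comparison x {11x, 11y, 12x, 12y} layout.

    Rows: (comparison, statistic in {icc, lower, upper}); columns: one per
    landmark-axis — the layout of a published reliability table.
    """
    long = report.assign(
        coordinate=report["landmark_id"].astype(str) + report["axis"]
    )
    blocks = {}
    for stat, col in (("icc", "icc"), ("lower", "ci_lower"), ("upper", "ci_upper")):
        blocks[stat] = long.pivot(
            index="comparison", columns="coordinate", values=col
        )
    wide = pd.concat(blocks, names=["statistic"]).swaplevel().sort_index(
        level="comparison", sort_remaining=False
    )
    return wide


def write_report_csv(report: pd.DataFrame, sink: TextIO | str) -> None:
    """Write the wide (published-table layout) report as CSV."""
    report_to_wide(report).to_csv(sink)
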