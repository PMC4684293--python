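"""Response statistics: RMR curves, Response Time, End Point HSD, GLM beta.

Downstream of the imaging pipeline every well is a short time series of WI
values on the assay's sampling grid (0, 5, 10, 15, 30, 45, 60, 120, 240
minutes; t = 0 is filmed immediately before dosing).  Three summaries are
derived per treatment group:

* **RMR** (relative movement ratio): each well's WI divided by its own
  pre-treatment WI, so RMR = 1 means "moving as before dosing" regardless
  of how motile the larvae were to begin with.
* **Response Time**: the earliest sampled time at which the group mean RMR
  is significantly below 1 (95% CI entirely under 1) and stays so at every
  later sample — "significantly and irreversibly" slowed.
* **End Point RMR**: the RMR at the final sample (240 min), compared
  between groups with Tukey's HSD.

A per-well regression of WI on time (or log10(t+1) time, chosen by
adjusted R²) condenses each well's whole trajectory into a slope; its
negation, beta, is a per-well dose–response magnitude that groups are
compared on with Student's t tests against a control group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TimeCourse",
    "RMRSeries",
    "GroupSummary",
    "GLMFit",
    "ComparisonResult",
    "ResponseTime",
    "BaselineZeroError",
    "compute_rmr",
    "summarize_group",
    "response_time",
    "endpoint_rmr",
    "fit_glm",
    "compare_beta",
    "timecourses_from_table",
]

log = logging.getLogger(__name__)


class BaselineZeroError(ValueError):
    """The pre-treatment WI is zero, so RMR normalization is undefined."""


@dataclass
class TimeCourse:
    """WI values of one well over the sampling schedule (t = 0 included)."""

    well_id: str
    group: str
    times: np.ndarray
    wi_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wi_values = np.asarray(self.wi_values, dtype=float)
        if self.times.shape != self.wi_values.shape or self.times.ndim != 1:
            raise ValueError("times and wi_values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must strictly increase for well {self.well_id}")


@dataclass
class RMRSeries:
    """One well's WI time course normalized to its own t = 0 baseline."""

    well_id: str
    group: str
    times: np.ndarray
    rmr: np.ndarray
    baseline_wi: float


@dataclass
class GroupSummary:
    """Per-time-point mean RMR and 95% CI half-width across a group's wells.

    ``ci_half`` is NaN where fewer than two wells contribute (a mean is
    still reported, an interval is not).
    """

    group: str
    times: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    ci_half: np.ndarray
    conf_level: float = 0.95


@dataclass(frozen=True)
class ResponseTime:
    """Earliest irreversible significant slowdown, or censored at the grid end."""

    minutes: float | None
    censored: bool
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class GLMFit:
    """Per-well least-squares fit of WI against (transformed) time."""

    well_id: str
    group: str
    transform: str  # "identity" | "log10p1"
    slope: float
    intercept: float
    beta: float
    adjusted_r2: float
    n_points: int


@dataclass
class ComparisonResult:
    """One pairwise group comparison (Tukey HSD family or Student t)."""

    group_a: str
    group_b: str
    statistic: float | None
    p_value: float | None
    significant: bool | None
    method: str
    alpha: float = 0.05


def compute_rmr(tc: TimeCourse) -> RMRSeries:
    """Normalize a WI time course to its own pre-treatment baseline.

    rmr(t) = WI(t) / WI(0).  Requires a t = 0 sample with WI(0) > 0; a zero
    baseline (motionless well before dosing) raises
    :class:`BaselineZeroError` so the caller can exclude and log the well.
    """
    if tc.times[0] != 0:
        raise ValueError(f"well {tc.well_id}: no t = 0 baseline sample")
    baseline = float(tc.wi_values[0])
    if baseline <= 0:
        raise BaselineZeroError(
            f"well {tc.well_id}: baseline WI is {baseline}; RMR undefined"
        )
    return RMRSeries(
        well_id=tc.well_id,
        group=tc.group,
        times=tc.times.copy(),
        rmr=tc.wi_values / baseline,
        baseline_wi=baseline,
    )


def summarize_group(series: Sequence[RMRSeries], conf_level: float = 0.95) -> GroupSummary:
    """Mean RMR and Student-t CI across wells, per time point.

    Wells may miss individual time points; each time point is summarized
    over the wells that have it.  With a single well the mean is reported
    and the CI is marked unavailable (NaN).
    """
    if not series:
        raise ValueError("no RMR series to summarize")
    groups = {s.group for s in series}
    if len(groups) != 1:
        raise ValueError(f"mixed groups in one summary: {sorted(groups)}")
    rows = [
        (t, r) for s in series for t, r in zip(s.times, s.rmr)
    ]
    df = pd.DataFrame(rows, columns=["time", "rmr"])
    out_t, out_n, out_m, out_h = [], [], [], []
    for tval, sub in df.groupby("time"):
        vals = sub["rmr"].to_numpy()
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            sem = vals.std(ddof=1) / math.sqrt(n)
            tcrit = sps.t.ppf(0.5 + conf_level / 2, n - 1)
            half = float(tcrit * sem)
        else:
            half = math.nan
        out_t.append(tval), out_n.append(n), out_m.append(mean), out_h.append(half)
    return GroupSummary(
        group=series[0].group,
        times=np.asarray(out_t),
        n=np.asarray(out_n),
        mean=np.asarray(out_m),
        ci_half=np.asarray(out_h),
        conf_level=conf_level,
    )


def response_time(summary: GroupSummary) -> ResponseTime:
    """Earliest sampled time with the mean RMR significantly below 1, irreversibly.

    A time point qualifies when mean + CI half-width < 1 (the whole 95% CI
    sits under 1); the Response Time is the earliest post-treatment sample
    that qualifies *and* whose successors all qualify.  Time points without
    a CI (single well) never qualify.  If no such time exists the result is
    censored as ``> t_max``: no significant irreversible slowdown was seen
    within the sampling window.
    """
    post = summary.times > 0
    times = summary.times[post]
    upper = summary.mean[post] + summary.ci_half[post]
    if times.size == 0:
        raise ValueError("summary has no post-treatment time points")
    below = np.isfinite(upper) & (upper < 1.0)
    # suffix scan: qualifies iff below here and at every later sample
    irreversible = np.logical_and.accumulate(below[::-1])[::-1]
    idx = np.nonzero(irreversible)[0]
    if idx.size == 0:
        tmax = times[-1]
        return ResponseTime(minutes=None, censored=True, label=f">{tmax:g}")
    t_star = float(times[idx[0]])
    return ResponseTime(minutes=t_star, censored=False, label=f"{t_star:g}")


def endpoint_rmr(
    series_by_group: Mapping[str, Sequence[RMRSeries]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """End Point RMR (final sample) per well, compared across groups by Tukey HSD.

    Wells missing the final time point (the maximum sampled time across all
    wells) are excluded with a log entry.  Returns a tidy per-well frame
    (group, well_id, endpoint_rmr) and the pairwise HSD comparisons (empty
    when fewer than two groups survive).
    """
    t_end = max(
        float(s.times[-1]) for group in series_by_group.values() for s in group
    )
    rows = []
    for group, series in series_by_group.items():
        for s in series:
            if s.times[-1] != t_end:
                log.warning(
                    "well %s (%s) lacks the %g min endpoint; excluded",
                    s.well_id, group, t_end,
                )
                continue
            rows.append((group, s.well_id, float(s.rmr[-1])))
    df = pd.DataFrame(rows, columns=["group", "well_id", "endpoint_rmr"])
    comparisons: list[ComparisonResult] = []
    if df["group"].nunique() >= 2:
        res = pairwise_tukeyhsd(df["endpoint_rmr"], df["group"], alpha=alpha)
        tbl = res.summary().data[1:]
        for g1, g2, meandiff, p_adj, lower, upper, reject in tbl:
            comparisons.append(
                ComparisonResult(
                    group_a=str(g1),
                    group_b=str(g2),
                    statistic=float(meandiff),
                    p_value=float(p_adj),
                    significant=bool(reject),
                    method="tukey_hsd",
                    alpha=alpha,
                )
            )
    return df, comparisons


def _transform_time(times: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return times
    if transform == "log10p1":
        return np.log10(times + 1.0)
    raise ValueError(f"unknown transform {transform!r}")


def _ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, adjusted R² of a simple least-squares line.

    A constant response (zero variance in y) fits exactly with slope 0; its
    R² is taken as 0 by convention (no variance to explain).
    """
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("time values have zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 0.0, float(y.mean()), 0.0
    ssr = float(((y - (slope * x + intercept)) ** 2).sum())
    r2 = 1.0 - ssr / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), float(adj)


def fit_glm(
    tc: TimeCourse,
    transform: str = "auto",
    beta_convention: str = "negate",
) -> GLMFit:
    """Least-squares fit of WI on g(time), condensing a well into one beta.

    ``transform`` is ``"identity"`` (g(t) = t), ``"log10p1"``
    (g(t) = log10(t + 1), which keeps the t = 0 baseline point), or
    ``"auto"``, which fits both and keeps the transform with the larger
    adjusted R² (= 1 − (1 − R²)(n − 1)/(n − 2); ties favour identity).

    beta is the additive inverse of the slope by default, so stronger
    motility declines give larger positive beta.  ``beta_convention=
    "reciprocal"`` gives 1/slope instead, for sensitivity analyses.
    """
    if tc.times.size < 3:
        raise ValueError(f"well {tc.well_id}: need >= 3 time points to fit")
    y = tc.wi_values
    if transform == "auto":
        fits = {
            tr: _ols_fit(_transform_time(tc.times, tr), y)
            for tr in ("identity", "log10p1")
        }
        transform = max(fits, key=lambda tr: (fits[tr][2], tr == "identity"))
        slope, intercept, adj = fits[transform]
    else:
        slope, intercept, adj = _ols_fit(_transform_time(tc.times, transform), y)
    if beta_convention == "negate":
        beta = -slope
    elif beta_convention == "reciprocal":
        beta = math.inf if slope == 0 else 1.0 / slope
    else:
        raise ValueError(f"unknown beta convention {beta_convention!r}")
    return GLMFit(
        well_id=tc.well_id,
        group=tc.group,
        transform=transform,
        slope=slope,
        intercept=intercept,
        beta=beta,
        adjusted_r2=adj,
        n_points=int(tc.times.size),
    )


def compare_beta(
    fits_by_group: Mapping[str, Sequence[GLMFit]],
    control_group: str,
    alpha: float = 0.05,
    holm: bool = False,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Student's t test of each group's beta values against the control's.

    Returns per-group beta summaries (n, mean, 95% CI half-width) and the
    two-sample comparisons.  When both groups have zero beta variance the
    statistic is reported as unavailable (None) unless the means are equal,
    in which case t = 0, p = 1 (comparing a group with itself).  ``holm``
    optionally applies a Holm correction across the reported tests.
    """
    if control_group not in fits_by_group:
        raise ValueError(f"control group {control_group!r} missing")
    betas = {
        g: np.array([f.beta for f in fits], dtype=float)
        for g, fits in fits_by_group.items()
    }
    rows = []
    for g, b in betas.items():
        n = b.size
        half = (
            float(sps.t.ppf(0.975, n - 1) * b.std(ddof=1) / math.sqrt(n))
            if n >= 2
            else math.nan
        )
        rows.append((g, n, float(b.mean()), half))
    summary = pd.DataFrame(rows, columns=["group", "n", "mean_beta", "ci_half"])
    ctrl = betas[control_group]
    comparisons: list[ComparisonResult] = []
    for g, b in betas.items():
        if g == control_group:
            continue
        if b.size < 2 or ctrl.size < 2:
            comparisons.append(
                ComparisonResult(g, control_group, None, None, None, "student_t", alpha)
            )
            continue
        pooled_var = b.var(ddof=1) + ctrl.var(ddof=1)
        if pooled_var == 0:
            if b.mean() == ctrl.mean():
                stat, p = 0.0, 1.0
            else:
                comparisons.append(
                    ComparisonResult(
                        g, control_group, None, None, None, "student_t", alpha
                    )
                )
                continue
        else:
            stat, p = sps.ttest_ind(b, ctrl, equal_var=True)
            stat, p = float(stat), float(p)
        comparisons.append(
            ComparisonResult(g, control_group, stat, p, p <= alpha, "student_t", alpha)
        )
    if holm:
        tested = [c for c in comparisons if c.p_value is not None]
        order = np.argsort([c.p_value for c in tested])
        m = len(tested)
        prev = 0.0
        for rank, i in enumerate(order):
            c = tested[i]
            padj = min(1.0, max(prev, (m - rank) * c.p_value))
            prev = padj
            c.p_value = padj
            c.significant = padj <= alpha
    return summary, comparisons


def timecourses_from_table(df: pd.DataFrame) -> list[TimeCourse]:
    """Group a WI results table (see io.RESULTS_COLUMNS) into per-well courses.

    Wells are keyed by (genotype, insecticide, dose_ppm, well_id); the group
    label is genotype|insecticide|dose.  Wells without a t = 0 row are
    excluded with a log entry (RMR would be undefined).
    """
    out: list[TimeCourse] = []
    keys = ["genotype", "insecticide", "dose_ppm", "well_id"]
    for (geno, insec, dose, wid), sub in df.groupby(keys, dropna=False):
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(dtype=float)
        if times[0] != 0:
            log.warning("well %s (%s, %g ppm): no t = 0 row; excluded", wid, insec, dose)
            continue
        group = f"{geno}|{insec}|{dose:g}ppm"
        out.append(
            TimeCourse(
                well_id=str(wid),
                group=group,
                times=times,
                wi_values=sub["wi_value"].to_numpy(dtype=float),
            )
        )
    return out
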