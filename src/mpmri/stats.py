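"""Cohort statistics: ROI medians, percent change, test-retest CV, multiple
t-tests with two-stage adaptive FDR, one-way ANOVA with post-hoc
comparisons, and Pearson correlation matrices with exact p-values.

The two-stage FDR procedure (Benjamini, Krieger & Yekutieli) is implemented
literally: stage one runs linear step-up at level q/(1+q) to estimate the
number of true nulls m0 = m - r1, stage two reruns step-up with m0 in the
thresholds.  q-values are defined as the smallest nominal FDR level at which
a hypothesis is rejected and computed by bisection, which is well defined
because the rejection rule is monotone in the level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import ParametricMap

#: the quantitative parameters carried by a cohort table, in report order
MRI_PARAMETERS = (
    "volume_mm3", "t1_ms", "t2_ms", "mtr_pct", "adc", "r2star_s", "gd_kpa", "gl_kpa",
)

HISTOLOGY_COVARIATES = (
    "percent_ha", "nuclear_density", "percent_collagen", "vessel_density",
)


# --------------------------------------------------------------------------
# scalars


def roi_median(pmap: ParametricMap, roi: np.ndarray) -> float:
    """Median map value over the ROI intersected with the validity mask.

    The ROI is the viable-tumour mask (necrosis excluded); the even-count
    median is the mean of the middle pair (numpy convention).
    """
    roi = np.asarray(roi).astype(bool)
    if roi.shape != pmap.values.shape:
        raise ValueError("roi shape must match the map")
    sel = roi & pmap.valid_mask
    if not sel.any():
        raise ValueError("ROI contains no valid voxels")
    return float(np.median(pmap.values[sel]))


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre."""
    if pre == 0:
        raise ValueError("pre value must be nonzero")
    return 100.0 * (post - pre) / pre


def water_content(wet_g: float, dry_g: float) -> float:
    """Percent tissue water: 100 * (wet - dry) / wet."""
    if wet_g <= 0:
        raise ValueError("wet weight must be positive")
    if dry_g < 0 or dry_g > wet_g:
        raise ValueError("dry weight must lie in [0, wet]")
    return 100.0 * (wet_g - dry_g) / wet_g


# --------------------------------------------------------------------------
# test-retest repeatability


@dataclass(frozen=True)
class CVwsResult:
    """Within-subject test-retest coefficient of variation."""

    parameter: str
    cv_percent: float
    n_pairs: int


def cv_ws(pairs, parameter: str = "", variant: str = "grand_mean") -> CVwsResult:
    """Within-subject CV from paired repeat measurements.

    ``variant='grand_mean'`` (default): CV% = 100 * sqrt(sum(d_i^2) / (2n)) / m
    with m the grand mean of all 2n values -- the form stated with the symbol
    definitions used here.  ``variant='pair_mean'`` normalises each squared
    difference by its own pair mean before pooling:
    CV% = 100 * sqrt(sum((d_i/m_i)^2) / (2n)).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (pre, post) values")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 1] - arr[:, 0]
    if variant == "grand_mean":
        m = arr.mean()
        if m == 0:
            raise ValueError("grand mean is zero")
        cv = 100.0 * np.sqrt((d**2).sum() / (2.0 * n)) / m
    elif variant == "pair_mean":
        m_i = arr.mean(axis=1)
        if np.any(m_i == 0):
            raise ValueError("a pair mean is zero")
        cv = 100.0 * np.sqrt(((d / m_i) ** 2).sum() / (2.0 * n))
    else:
        raise ValueError("variant must be 'grand_mean' or 'pair_mean'")
    return CVwsResult(parameter=parameter, cv_percent=float(abs(cv)), n_pairs=n)


# --------------------------------------------------------------------------
# two-stage adaptive FDR (Benjamini-Krieger-Yekutieli)


def _step_up_count(p_sorted: np.ndarray, thresholds: np.ndarray) -> int:
    """Number rejected by linear step-up: largest k with p_(k) <= thr_k."""
    ok = np.nonzero(p_sorted <= thresholds)[0]
    return int(ok[-1] + 1) if ok.size else 0


def bky_reject(pvals, alpha: float) -> np.ndarray:
    """Literal two-stage adaptive step-up decision at FDR level ``alpha``.

    Stage 1: linear step-up at alpha' = alpha/(1+alpha); if it rejects none,
    stop; if it rejects all m, reject everything.  Otherwise set
    m0 = m - r1 and rerun step-up with thresholds i*alpha'/m0.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    a1 = alpha / (1.0 + alpha)
    i = np.arange(1, m + 1)
    r1 = _step_up_count(p_sorted, i * a1 / m)
    reject_sorted = np.zeros(m, dtype=bool)
    if r1 == 0:
        pass
    elif r1 == m:
        reject_sorted[:] = True
    else:
        m0 = m - r1
        r2 = _step_up_count(p_sorted, i * a1 / m0)
        reject_sorted[:r2] = True
    out = np.zeros(m, dtype=bool)
    out[order] = reject_sorted
    return out


def bky_qvalues(pvals, tol: float = 1e-10) -> np.ndarray:
    """q-values for the two-stage procedure: smallest level of rejection.

    Computed by bisection on the (monotone) rejection rule; capped at 1.
    NaN p-values yield NaN q-values and are excluded from the family.
    """
    p = np.asarray(pvals, dtype=float)
    nan = ~np.isfinite(p)
    if nan.all():
        return np.full(p.shape, np.nan)
    p_ok = p[~nan]
    m = p_ok.size
    q = np.ones(m)
    for idx in range(m):
        if not bky_reject(p_ok, 1.0)[idx]:
            q[idx] = 1.0
            continue
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2.0
            if bky_reject(p_ok, mid)[idx]:
                hi = mid
            else:
                lo = mid
        q[idx] = hi
    out = np.full(p.shape, np.nan)
    out[~nan] = q
    return out


# --------------------------------------------------------------------------
# Pearson correlation


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with exact two-sided p-value."""

    pair: tuple[str, str]
    r: float
    n: int
    p: float
    flagged: bool = False  # zero variance or too few complete pairs


def pearson_p_from_summary(r: float, n: int) -> float:
    """Two-sided p from summary statistics (r, n).

    Uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
    freedom; this is the entry point for checking correlations reported only
    as printed (r, n) pairs.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def pearson_with_p(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson r with exact two-sided p on pairwise-complete rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return CorrelationResult(pair, np.nan, n, np.nan, flagged=True)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(pair, np.nan, n, np.nan, flagged=True)
    res = sps.pearsonr(x, y)
    return CorrelationResult(pair, float(res.statistic), n, float(res.pvalue))


def correlation_matrix(
    table: pd.DataFrame,
    columns: list[str],
    stratum: str = "all",
    timepoint: str = "post",
    ha_exclusion_threshold: float = 2.0,
) -> pd.DataFrame:
    """All pairwise Pearson correlations for one cohort stratum.

    Rows are restricted to ``timepoint`` and, unless ``stratum='all'``, to
    one treatment arm.  Pairwise-complete deletion gives each pair its own n.
    In the treated stratum, percent HA is excluded when its mean falls below
    ``ha_exclusion_threshold`` (%): after enzymatic HA degradation only
    negligible HA remains and the column carries no usable variance.

    Returns a tidy frame with columns (a, b, r, n, p, flagged).
    """
    if stratum not in ("all", "saline", "treated"):
        raise ValueError("stratum must be 'all', 'saline' or 'treated'")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"columns absent from table: {missing}")
    df = table[table["timepoint"] == timepoint]
    if stratum != "all":
        df = df[df["arm"] == stratum]
    cols = list(columns)
    if (
        stratum == "treated"
        and "percent_ha" in cols
        and np.nanmean(df["percent_ha"].to_numpy(dtype=float)) < ha_exclusion_threshold
    ):
        cols.remove("percent_ha")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if a == b:
                n = int(np.isfinite(df[a].to_numpy(dtype=float)).sum())
                rows.append({"a": a, "b": b, "r": 1.0, "n": n, "p": 0.0, "flagged": False})
            else:
                res = pearson_with_p(df[a], df[b], pair=(a, b))
                rows.append(
                    {"a": a, "b": b, "r": res.r, "n": res.n, "p": res.p, "flagged": res.flagged}
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort-level tests


def percent_change_table(table: pd.DataFrame, parameters=MRI_PARAMETERS) -> pd.DataFrame:
    """Per-subject percent change (pre -> post) for each parameter.

    Expects a cohort table with one row per (subject, timepoint) and columns
    subject/group/arm/timepoint plus parameter columns; returns one row per
    subject with percent-change columns.
    """
    parameters = [p for p in parameters if p in table.columns]
    pre = table[table["timepoint"] == "pre"].set_index("subject")
    post = table[table["timepoint"] == "post"].set_index("subject")
    common = pre.index.intersection(post.index)
    if len(common) < len(pre.index) or len(common) < len(post.index):
        raise ValueError("every subject needs matching pre and post rows")
    out = pre.loc[common, ["group", "arm"]].copy()
    for p in parameters:
        a = pre.loc[common, p].to_numpy(dtype=float)
        b = post.loc[common, p].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[p] = 100.0 * (b - a) / a
    return out.reset_index()


def multi_ttest_fdr(
    table: pd.DataFrame,
    parameters=MRI_PARAMETERS,
    group: str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Unpaired t-tests on percent change per parameter, with BKY q-values.

    One classic Student's t-test (Welch behind ``equal_var=False``) of
    treated vs saline percent-change values per parameter; q-values are
    computed across the parameter family (per model group when ``group`` is
    given).  Parameters with degenerate variance in both arms are flagged
    and excluded from the family.
    """
    df = table if group is None else table[table["group"] == group]
    changes = percent_change_table(df, parameters)
    arms = set(changes["arm"])
    if not {"saline", "treated"} <= arms:
        raise ValueError("both arms must be present")
    rows = []
    for p in [c for c in parameters if c in changes.columns]:
        x = changes.loc[changes["arm"] == "treated", p].dropna().to_numpy()
        y = changes.loc[changes["arm"] == "saline", p].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            raise ValueError(f"parameter {p!r}: need >= 2 subjects per arm")
        degenerate = np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean()
        if degenerate:
            t_stat, p_val = np.nan, np.nan
        else:
            t_stat, p_val = sps.ttest_ind(x, y, equal_var=equal_var)
        rows.append(
            {
                "parameter": p,
                "mean_change_treated": x.mean(),
                "mean_change_saline": y.mean(),
                "n_treated": x.size,
                "n_saline": y.size,
                "t": float(t_stat),
                "p": float(p_val),
                "degenerate": bool(degenerate),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bky_qvalues(out["p"].to_numpy())
    return out


def anova_multi(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA plus pairwise post-hoc comparisons with FDR control.

    Returns the ANOVA F-test p-value and a frame of pairwise Welch
    comparisons with BKY q-values across the comparison family.  The
    post-hoc choice (pairwise Welch + two-stage FDR) is recorded in the
    output metadata rather than claimed to match any particular software.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if np.ptp(values) == 0:  # all observations identical: F is 0/0, report null
        f_p = 1.0
    else:
        _, f_p = sps.f_oneway(*samples)
        f_p = float(f_p)
    rows = []
    for i in range(labels.size):
        for j in range(i + 1, labels.size):
            a, b = samples[i], samples[j]
            if np.ptp(np.concatenate([a, b])) == 0:
                t_stat, p_val = 0.0, 1.0
            else:
                t_stat, p_val = sps.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "t": float(t_stat),
                    "p": float(p_val),
                }
            )
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = bky_qvalues(pairwise["p"].to_numpy())
    pairwise["significant"] = pairwise["q"] <= alpha
    pairwise.attrs["posthoc"] = "pairwise Welch t-tests with two-stage adaptive FDR"
    return f_p, pairwise


def round_p_for_report(p: float) -> str:
    """Report-style p formatting: one significant figure, '<0.0001' floor."""
    if not np.isfinite(p):
        return "nan"
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.1g}"
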