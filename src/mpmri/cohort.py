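"""Cohort tables and summary-level synthetic cohorts.

A cohort table has one row per (subject, timepoint) with columns
``subject, group, arm, timepoint`` plus ROI-median parameter columns and
optional histology covariates.  Two generators live here:

* :func:`simulate_summary_cohort` draws pre/post ROI medians directly from a
  between/within-subject variance model -- cheap enough for the thousands of
  replicate cohorts the null-calibration studies need.
* :func:`simulate_correlated_cohort` draws post-treatment covariate vectors
  from a known correlation structure, the round-trip oracle for the
  correlation-matrix machinery.

The image-level closed loop (phantom -> signals -> maps -> medians) lives in
:mod:`mpmri.study`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import MRI_PARAMETERS

REQUIRED_COLUMNS = ("subject", "group", "arm", "timepoint")

#: baseline ROI-median magnitudes used by the summary generator: viable
#: breast-tumour tissue at high field (T1/T2 ms, MTR %, ADC 1e-6 mm^2/s,
#: R2* 1/s, G kPa, volume mm^3)
DEFAULT_BASELINE = {
    "volume_mm3": 350.0,
    "t1_ms": 1900.0,
    "t2_ms": 55.0,
    "mtr_pct": 35.0,
    "adc": 800.0,
    "r2star_s": 60.0,
    "gd_kpa": 5.0,
    "gl_kpa": 2.0,
}

#: between-subject spread (fractional sd of the subject baseline)
DEFAULT_BETWEEN_SD = 0.10

#: within-subject test-retest spread (fractional sd per measurement), set to
#: reproduce test-retest CVs in the few-to-mid-teens percent range reported
#: for repeat small-animal acquisitions (lower for T1)
DEFAULT_WITHIN_SD = {
    "volume_mm3": 0.05,
    "t1_ms": 0.022,
    "t2_ms": 0.066,
    "mtr_pct": 0.05,
    "adc": 0.16,
    "r2star_s": 0.16,
    "gd_kpa": 0.13,
    "gl_kpa": 0.16,
}

#: saline-arm tumour growth between the paired scans (percent, mean)
DEFAULT_SALINE_GROWTH_PCT = 34.0


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table contract; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    for subject, sub in table.groupby("subject"):
        tps = set(sub["timepoint"])
        if tps != {"pre", "post"}:
            raise ValueError(f"subject {subject!r} lacks matching pre/post rows")
        if sub["arm"].nunique() != 1 or sub["group"].nunique() != 1:
            raise ValueError(f"subject {subject!r} changes arm or group")
    return table


def simulate_summary_cohort(
    n_per_arm: int,
    seed: int,
    group: str = "A",
    baseline: dict | None = None,
    between_sd: float = DEFAULT_BETWEEN_SD,
    within_sd: dict | None = None,
    effects_pct: dict | None = None,
    saline_growth_pct: float = DEFAULT_SALINE_GROWTH_PCT,
    treated_growth_pct: float = 5.0,
) -> pd.DataFrame:
    """Draw a two-arm cohort of pre/post ROI medians at summary level.

    Each subject gets a lognormal-ish baseline (multiplicative between-subject
    noise), each measurement adds multiplicative within-subject noise, and
    treated-arm post values are scaled by ``1 + effect/100`` per parameter.
    Tumour volume additionally grows between scans in both arms.
    """
    baseline = {**DEFAULT_BASELINE, **(baseline or {})}
    within = {**DEFAULT_WITHIN_SD, **(within_sd or {})}
    effects = {k: 0.0 for k in baseline}
    effects.update(effects_pct or {})
    rng = np.random.default_rng(seed)
    rows = []
    for arm in ("saline", "treated"):
        growth = saline_growth_pct if arm == "saline" else treated_growth_pct
        for i in range(n_per_arm):
            subject = f"{group}-{arm}-{i:02d}"
            base = {
                k: v * (1.0 + between_sd * rng.standard_normal()) for k, v in baseline.items()
            }
            for timepoint in ("pre", "post"):
                row = {"subject": subject, "group": group, "arm": arm, "timepoint": timepoint}
                for k, v in base.items():
                    val = v
                    if timepoint == "post":
                        if k == "volume_mm3":
                            val *= 1.0 + growth / 100.0
                        elif arm == "treated":
                            val *= 1.0 + effects[k] / 100.0
                    val *= 1.0 + within[k] * rng.standard_normal()
                    row[k] = max(val, 1e-9)
                rows.append(row)
    return validate_cohort_table(pd.DataFrame(rows))


def simulate_correlated_cohort(
    columns: list[str],
    correlation: np.ndarray,
    n: int,
    seed: int,
    means: dict | None = None,
    sds: dict | None = None,
    group: str = "A",
    arm: str = "saline",
) -> pd.DataFrame:
    """Post-treatment cohort rows with a known correlation structure.

    Draws multivariate normal covariates; the empirical correlation matrix of
    the result converges to ``correlation`` as n grows, which is the oracle
    the correlation-matrix tests rely on.  Pre rows duplicate post rows so
    the table still satisfies the pre/post contract.
    """
    corr = np.asarray(correlation, dtype=float)
    k = len(columns)
    if corr.shape != (k, k):
        raise ValueError("correlation matrix shape must match columns")
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    means = means or {}
    sds = sds or {}
    mu = np.array([means.get(c, 0.0) for c in columns])
    sd = np.array([sds.get(c, 1.0) for c in columns])
    cov = corr * np.outer(sd, sd)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    rows = []
    for i in range(n):
        for timepoint in ("pre", "post"):
            row = {
                "subject": f"{group}-{arm}-{i:03d}",
                "group": group,
                "arm": arm,
                "timepoint": timepoint,
            }
            row.update({c: draws[i, j] for j, c in enumerate(columns)})
            rows.append(row)
    return validate_cohort_table(pd.DataFrame(rows))
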