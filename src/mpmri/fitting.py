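"""Voxelwise reconstruction of T1, T2, MTR, ADC and R2* parametric maps.

Every fitter shares the closed-form signal model of its simulator
(:mod:`mpmri.models`), so a noiseless simulate -> fit round trip recovers the
phantom fields to numerical precision.  Voxels whose signal sits below the
noise floor (3x the acquisition noise sd) or whose fit is degenerate are
masked invalid rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .grid import Grid
from .simulate import SignalStack

#: voxels below FLOOR_FACTOR * noise sd are masked (Rician bias dominates there)
FLOOR_FACTOR = 3.0

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class ParametricMap:
    """One reconstructed quantitative map with units and a validity mask."""

    values: np.ndarray
    units: str
    valid_mask: np.ndarray
    grid: Grid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite wherever valid")


def _signal_floor(stack: SignalStack) -> float:
    sigma = float(stack.provenance.get("noise_sigma_abs", 0.0) or 0.0)
    return FLOOR_FACTOR * sigma


# --------------------------------------------------------------------------
# IR-TrueFISP: variable-projection fit of y = a + b * exp(-t / tau)


def _varpro_sse(y, sy, syy, t, tau):
    """Least-squares (a, b) and SSE for y = a + b*exp(-t/tau), vectorised.

    ``y`` is (V, T); ``tau`` is scalar or (V,).  Returns (sse, a, b).
    """
    tau = np.asarray(tau, dtype=float)
    e = np.exp(-t[None, :] / tau[..., None]) if tau.ndim else np.exp(-t / tau)[None, :]
    n = y.shape[1]
    se = e.sum(axis=-1)
    see = (e * e).sum(axis=-1)
    sye = (y * e).sum(axis=-1)
    det = n * see - se * se
    det = np.where(np.abs(det) < 1e-30, np.nan, det)
    a = (sy * see - sye * se) / det
    b = (n * sye - se * sy) / det
    sse = syy - a * sy - b * sye
    return sse, a, b


def _fit_offset_exponential(y, t_ms, tau_bounds=(5.0, 8000.0), n_grid=48, n_golden=60):
    """Per-voxel best (tau, a, b) for y = a + b*exp(-t/tau).

    Coarse log-spaced grid over tau followed by golden-section refinement of
    the 1-D variable-projection objective; everything vectorised over voxels.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t_ms, dtype=float)
    sy = y.sum(axis=1)
    syy = (y * y).sum(axis=1)

    taus = np.geomspace(tau_bounds[0], tau_bounds[1], n_grid)
    sse_grid = np.empty((y.shape[0], n_grid))
    for j, tau in enumerate(taus):
        sse_grid[:, j], _, _ = _varpro_sse(y, sy, syy, t, tau)
    best = np.nanargmin(sse_grid, axis=1)

    log_taus = np.log(taus)
    lo = log_taus[np.maximum(best - 1, 0)]
    hi = log_taus[np.minimum(best + 1, n_grid - 1)]
    c = hi - _INVPHI * (hi - lo)
    d = lo + _INVPHI * (hi - lo)
    fc, _, _ = _varpro_sse(y, sy, syy, t, np.exp(c))
    fd, _, _ = _varpro_sse(y, sy, syy, t, np.exp(d))
    for _ in range(n_golden):
        take_c = fc < fd
        lo = np.where(take_c, lo, c)
        hi = np.where(take_c, d, hi)
        c = hi - _INVPHI * (hi - lo)
        d = lo + _INVPHI * (hi - lo)
        fc, _, _ = _varpro_sse(y, sy, syy, t, np.exp(c))
        fd, _, _ = _varpro_sse(y, sy, syy, t, np.exp(d))
    tau = np.exp((lo + hi) / 2.0)
    sse, a, b = _varpro_sse(y, sy, syy, t, tau)
    return tau, a, b, sse


def fit_t1_t2(stack: SignalStack) -> tuple[ParametricMap, ParametricMap]:
    """Joint T1/T2 maps from an IR-TrueFISP magnitude stack.

    Magnitude data lose the sign of the early (inverted) frames, so for each
    voxel the polarity is restored at the two candidate flip points around
    the minimum-magnitude frame and the lower-residual restoration wins.  The
    fitted apparent parameters (S_ss, INV, T1*) are then inverted in closed
    form to (T1, T2).
    """
    if stack.protocol.modality != "IR_TRUEFISP":
        raise ValueError("stack modality must be IR_TRUEFISP")
    t = np.asarray(stack.frame_values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 inversion times for a 3-parameter fit")
    shape = stack.frames.shape[1:]
    y_abs = stack.frames.reshape(t.size, -1).T  # (V, T)
    j0 = np.argmin(y_abs, axis=1)

    best = None
    for offset in (0, 1):
        flip_count = np.clip(j0 + offset, 0, t.size)
        signs = np.where(np.arange(t.size)[None, :] < flip_count[:, None], -1.0, 1.0)
        y = y_abs * signs
        tau, a, b, sse = _fit_offset_exponential(y, t)
        if best is None:
            best = [tau, a, b, sse]
        else:
            better = sse < best[3]
            for i, new in enumerate((tau, a, b, sse)):
                best[i] = np.where(better, new, best[i])
    tau, a, b, sse = best

    # model: S(t) = S_ss * (1 - INV * exp(-t/T1*))  =>  a = S_ss, b = -S_ss*INV
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = -b / a
    t1, t2 = models.invert_ir_truefisp(a, inv, tau, stack.protocol.flip_deg)

    floor = _signal_floor(stack)
    amplitude = y_abs.max(axis=1)
    valid = (
        np.isfinite(t1)
        & np.isfinite(t2)
        & (t1 > 0)
        & (t2 > 0)
        & (a > 0)
        & (inv > 1.0)
        & (amplitude > floor)
    )
    t1 = np.where(valid, t1, np.nan).reshape(shape)
    t2 = np.where(valid, t2, np.nan).reshape(shape)
    valid = valid.reshape(shape)
    prov = {"fit": "varpro+golden", "flip_deg": stack.protocol.flip_deg, "floor": floor}
    return (
        ParametricMap(t1, "ms", valid, stack.grid, {**prov, "parameter": "T1"}),
        ParametricMap(t2, "ms", valid, stack.grid, {**prov, "parameter": "T2"}),
    )


# --------------------------------------------------------------------------


def compute_mtr(stack: SignalStack) -> ParametricMap:
    """Magnetisation transfer ratio MTR% = 100 * (S_off - S_on) / S_off."""
    if stack.protocol.modality != "MT_RARE":
        raise ValueError("stack modality must be MT_RARE")
    labels = list(stack.frame_values)
    if "off" not in labels or "on" not in labels:
        raise ValueError("MT stack must contain 'off' and 'on' frames")
    s_off = stack.frames[labels.index("off")].astype(float)
    s_on = stack.frames[labels.index("on")].astype(float)
    floor = max(_signal_floor(stack), np.finfo(float).tiny)
    valid = s_off > floor
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = 100.0 * (s_off - s_on) / s_off
    mtr = np.where(valid, mtr, np.nan)
    return ParametricMap(mtr, "%", valid, stack.grid, {"parameter": "MTR", "floor": floor})


def _loglinear_slope(log_s, x, weights):
    """Weighted per-voxel least-squares slope of log-signal vs x."""
    w = weights.astype(float)
    sw = w.sum(axis=0)
    sx = (w * x[:, None]).sum(axis=0)
    sxx = (w * x[:, None] ** 2).sum(axis=0)
    sy = (w * log_s).sum(axis=0)
    sxy = (w * x[:, None] * log_s).sum(axis=0)
    det = sw * sxx - sx * sx
    det = np.where(np.abs(det) < 1e-30, np.nan, det)
    return (sw * sxy - sx * sy) / det


def fit_adc(stack: SignalStack) -> ParametricMap:
    """ADC map (1e-6 mm^2/s) by log-linear least squares over the b-values.

    With exactly two b-values the estimator reduces to the two-point formula
    ln(S1/S2) / (b2 - b1).  Voxels with any non-positive or sub-floor frame
    are masked invalid.
    """
    if stack.protocol.modality != "DWI":
        raise ValueError("stack modality must be DWI")
    b = np.asarray(stack.frame_values, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 b-values")
    if np.any(np.diff(b) <= 0):
        raise ValueError("b-values must be strictly increasing")
    s = stack.frames.reshape(b.size, -1)
    floor = _signal_floor(stack)
    valid = np.all(s > max(floor, 0.0), axis=0) & np.all(s > 0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_s = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), np.nan)
    slope = _loglinear_slope(log_s, b, np.ones_like(s, dtype=bool))
    adc = -slope * 1e6  # mm^2/s -> 1e-6 mm^2/s
    valid &= np.isfinite(adc)
    adc = np.where(valid, adc, np.nan).reshape(stack.frames.shape[1:])
    valid = valid.reshape(stack.frames.shape[1:])
    return ParametricMap(
        adc, "1e-6 mm^2/s", valid, stack.grid, {"parameter": "ADC", "floor": floor}
    )


def fit_r2star(stack: SignalStack, method: str = "loglinear") -> ParametricMap:
    """R2* map (1/s) from the multi-echo train.

    Default is log-linear least squares over echoes above the noise floor
    (late echoes that have decayed into the floor are excluded per voxel);
    ``method='nonlinear'`` instead fits S0*exp(-R2**TE) by 1-D variable
    projection, which is more robust very near the floor.
    """
    if stack.protocol.modality != "MGE":
        raise ValueError("stack modality must be MGE")
    te = np.asarray(stack.frame_values, dtype=float)
    if te.size < 3:
        raise ValueError("need at least 3 echoes")
    s = stack.frames.reshape(te.size, -1)
    floor = _signal_floor(stack)
    include = s > max(floor, 0.0)
    enough = include.sum(axis=0) >= 3

    if method == "loglinear":
        with np.errstate(divide="ignore", invalid="ignore"):
            log_s = np.where(include, np.log(np.where(s > 0, s, 1.0)), 0.0)
        slope = _loglinear_slope(log_s, te * 1e-3, include)
        r2 = -slope
    elif method == "nonlinear":
        # offset-exponential fit on the untruncated train; the offset absorbs
        # the Rician magnitude floor instead of excluding late echoes
        tau, _, _, _ = _fit_offset_exponential(s.T, te, tau_bounds=(0.5, 1e5))
        r2 = 1e3 / tau
    else:
        raise ValueError("method must be 'loglinear' or 'nonlinear'")

    valid = enough & np.isfinite(r2)
    r2 = np.where(valid, r2, np.nan).reshape(stack.frames.shape[1:])
    valid = valid.reshape(stack.frames.shape[1:])
    return ParametricMap(
        r2, "1/s", valid, stack.grid,
        {"parameter": "R2*", "floor": floor, "method": method},
    )
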