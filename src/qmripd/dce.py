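"""Dynamic contrast-enhanced MRI: concentration conversion, AIF handling,
iAUC, and extended Tofts tracer-kinetic modelling.

Pipeline per voxel: the SPGR signal equation is inverted frame by frame
to T1(t) using the pre-contrast T1 map and the pre-injection signal
level, gadolinium concentration follows from the relaxivity relation
R1(t) = R1_pre + r1*C(t), and the concentration curve is either
integrated over the first 90 s after bolus arrival (iAUC) or fitted with
the extended Tofts model

    C_t(t) = v_p*C_p(t) + ktrans * int_0^t C_p(tau) exp(-(ktrans/v_e)(t-tau)) dtau

to yield the transfer constant ktrans (1/min), the extravascular
extracellular fraction v_e and the plasma fraction v_p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import ParameterMap
from .t1 import spgr_signal

log = logging.getLogger(__name__)

#: default gadolinium longitudinal relaxivity, s^-1 mM^-1 (1.5 T chelate)
DEFAULT_RELAXIVITY = 4.5

#: extended-Tofts fit bounds: ktrans 1/min, ve fraction, vp fraction
TOFTS_BOUNDS = ((0.0, 1e-3, 0.0), (5.0, 1.0, 0.5))
#: multi-start initial points (ktrans, ve, vp)
TOFTS_STARTS = ((0.05, 0.2, 0.01), (0.3, 0.3, 0.05), (1.0, 0.5, 0.1))


@dataclass
class Aif:
    """Arterial input function: plasma gadolinium concentration vs time."""

    times: np.ndarray
    cp: np.ndarray
    arrival_frame: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape:
            raise ValueError("times and cp must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DceSeries:
    """4-D DCE signal (x, y, z, t) with frame times and SPGR settings."""

    frames: np.ndarray
    times: np.ndarray
    flip_angle: float
    tr: float
    injection_frame: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4-D (x, y, z, t)")
        n = self.frames.shape[-1]
        if n < 10:
            raise ValueError(f"need >= 10 frames, got {n}")
        if self.times.shape != (n,):
            raise ValueError("times length must match frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.injection_frame < n):
            raise ValueError("injection_frame must lie inside the series")


@dataclass
class ConcentrationSeries:
    """Voxelwise gadolinium concentration (mM) over time."""

    conc: np.ndarray  # (x, y, z, t)
    times: np.ndarray
    valid: np.ndarray | None = None  # per voxel per frame

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.conc)


@dataclass
class ToftsMaps:
    ktrans: ParameterMap
    ve: ParameterMap
    vp: ParameterMap
    rss: np.ndarray
    valid: np.ndarray


def signal_to_concentration(
    series: DceSeries,
    t1_pre: ParameterMap | np.ndarray,
    r1: float = DEFAULT_RELAXIVITY,
) -> ConcentrationSeries:
    """Invert the SPGR signal equation frame by frame.

    M0 per voxel is implied by the mean pre-injection signal together
    with the pre-contrast T1; then each frame's signal gives E1(t),
    T1(t) and C(t) = (1/T1(t) - 1/T1_pre)/r1. Frames whose signal falls
    outside the attainable SPGR range (E1 outside (0, 1)) are flagged
    invalid for that voxel.
    """
    if r1 <= 0:
        raise ValueError("relaxivity must be positive")
    if isinstance(t1_pre, ParameterMap):
        t1_map = t1_pre.values
        t1_valid = t1_pre.valid
    else:
        t1_map = np.asarray(t1_pre, dtype=float)
        t1_valid = np.isfinite(t1_map) & (t1_map > 0)
    if t1_map.shape != series.frames.shape[:3]:
        raise ValueError(
            f"t1_pre grid {t1_map.shape} does not match DCE grid "
            f"{series.frames.shape[:3]}"
        )
    if series.injection_frame < 4:
        raise ValueError("need >= 4 pre-injection frames to anchor M0")

    alpha = np.deg2rad(series.flip_angle)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    t1_flat = t1_map.reshape(-1)
    frames = series.frames.reshape(-1, series.frames.shape[-1])

    pre = frames[:, : series.injection_frame].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1_pre = np.exp(-series.tr / t1_flat)
        shape_pre = sin_a * (1 - e1_pre) / (1 - cos_a * e1_pre)
        m0 = pre / shape_pre

    # invert S = M0 sin(a)(1-E1)/(1-cos(a)E1)  =>  E1 = (1 - y)/(1 - y cos a),
    # y = S/(M0 sin a)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = frames / (m0 * sin_a)[:, None]
        e1 = (1.0 - y) / (1.0 - y * cos_a)
        ok = (e1 > 0) & (e1 < 1) & np.isfinite(e1)
        t1_t = np.where(ok, -series.tr / np.log(np.where(ok, e1, 0.5)), np.nan)
        conc = (1.0 / t1_t - 1.0 / t1_flat[:, None]) / r1

    voxel_ok = t1_valid.reshape(-1) & np.isfinite(m0) & (m0 > 0)
    ok &= voxel_ok[:, None]
    conc[~voxel_ok] = np.nan
    n_bad = int((~ok[voxel_ok]).sum())
    if n_bad:
        log.info("signal_to_concentration: %d voxel-frames outside the "
                 "attainable SPGR range", n_bad)
    shape4 = series.frames.shape
    return ConcentrationSeries(conc.reshape(shape4), series.times,
                               valid=ok.reshape(shape4))


def extract_aif(conc: ConcentrationSeries, artery_mask: np.ndarray) -> Aif:
    """Average the concentration curves of arterial voxels."""
    artery_mask = np.asarray(artery_mask, dtype=bool)
    if not artery_mask.any():
        raise ValueError("artery mask is empty")
    if artery_mask.shape != conc.conc.shape[:3]:
        raise ValueError("artery mask grid does not match concentration grid")
    curves = conc.conc[artery_mask]
    cp = np.nanmean(curves, axis=0)
    aif = Aif(conc.times, cp)
    aif.arrival_frame = detect_bolus_arrival(aif)
    return aif


def detect_bolus_arrival(aif: Aif, n_baseline: int = 4) -> int:
    """First frame where cp exceeds baseline by a robust margin.

    The threshold is the pre-injection mean plus the larger of 5 baseline
    standard deviations and 10% of the peak-over-baseline excursion;
    deterministic, no smoothing.
    """
    cp = aif.cp
    if len(cp) < n_baseline + 1:
        raise ValueError("too few frames for arrival detection")
    base = cp[:n_baseline]
    mu, sd = float(base.mean()), float(base.std(ddof=0))
    peak = float(cp.max())
    margin = max(5.0 * sd, 0.1 * (peak - mu))
    if margin <= 0 or peak <= mu:
        raise ValueError("flat concentration curve: no bolus detected")
    above = np.nonzero(cp > mu + margin)[0]
    if len(above) == 0:
        raise ValueError("no frame exceeds the arrival threshold")
    return int(above[0])


def compute_iauc(
    conc: ConcentrationSeries,
    arrival: int,
    window: float = 90.0,
    mask: np.ndarray | None = None,
) -> ParameterMap:
    """Initial area under the concentration curve after bolus arrival.

    Trapezoidal integration of C(t) from the arrival time to arrival
    time + ``window`` seconds, with linear interpolation at the window
    end when it falls between frames. Negative noise excursions are
    integrated as-is. If the series ends before the window closes, the
    integral runs to the last frame with a warning.
    """
    times = conc.times
    if not (0 <= arrival < len(times)):
        raise ValueError(f"arrival frame {arrival} outside the series")
    t0 = times[arrival]
    t_end = t0 + window
    if times[-1] < t_end:
        log.warning("compute_iauc: series ends %.1f s before the %g s window; "
                    "integrating to the last frame", t_end - times[-1], window)
        t_end = times[-1]

    data = conc.conc
    shape3 = data.shape[:3]
    flat = data.reshape(-1, data.shape[-1])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        flat = flat[mask.reshape(-1)]

    sel = (times >= t0) & (times <= t_end)
    t_sel = times[sel]
    c_sel = flat[:, sel]
    if t_sel[-1] < t_end:  # interpolate the partial last segment
        j = np.searchsorted(times, t_end)
        w = (t_end - times[j - 1]) / (times[j] - times[j - 1])
        c_end = flat[:, j - 1] * (1 - w) + flat[:, j] * w
        t_sel = np.append(t_sel, t_end)
        c_sel = np.concatenate([c_sel, c_end[:, None]], axis=1)
    vals = np.trapezoid(c_sel, t_sel, axis=1)

    if mask is not None:
        out = np.full(int(np.prod(shape3)), np.nan)
        out[mask.reshape(-1)] = vals
        vals = out
    return ParameterMap("iauc", vals.reshape(shape3), units="mM*s")


def tofts_forward(aif: Aif, times: np.ndarray, ktrans, ve, vp) -> np.ndarray:
    """Extended-Tofts tissue concentration on the AIF time grid.

    The convolution integral is evaluated by the exponential-kernel
    recursion that is exact for a piecewise-linear C_p, so no
    oversampling is needed at ~8 s frame spacing. ktrans is in 1/min;
    times in seconds. Parameters may be scalars or 1-D arrays over
    voxels; the result has shape (n_voxels, n_times) for array input,
    (n_times,) for scalars.
    """
    times = np.asarray(times, dtype=float)
    if times.shape != aif.times.shape or not np.allclose(times, aif.times):
        raise ValueError("times must match the AIF time grid")
    scalar = np.isscalar(ktrans) and np.isscalar(ve) and np.isscalar(vp)
    kt = np.atleast_1d(np.asarray(ktrans, dtype=float))
    ve_a = np.atleast_1d(np.asarray(ve, dtype=float))
    vp_a = np.atleast_1d(np.asarray(vp, dtype=float))
    kt, ve_a, vp_a = np.broadcast_arrays(kt, ve_a, vp_a)
    if np.any((kt > 0) & (ve_a <= 0)):
        raise ValueError("ve must be positive where ktrans > 0")

    cp = aif.cp
    n_t = len(times)
    kt_s = kt / 60.0  # 1/s
    with np.errstate(divide="ignore", invalid="ignore"):
        kep = np.where(ve_a > 0, kt_s / ve_a, 0.0)  # 1/s

    # per-segment integrals of the piecewise-linear C_p against the
    # exponential kernel, evaluated at each segment's end time:
    # int_0^dt exp(-kep(dt-s)) (c0 + (c1-c0) s/dt) ds
    dt = np.diff(times)
    c0, c1 = cp[:-1], cp[1:]
    x = kep[:, None] * dt[None, :]
    e = np.exp(-x)
    small = x < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        i0 = np.where(small, dt * (1 - x / 2), -np.expm1(-x) / np.where(small, 1, kep[:, None]))
        i1 = np.where(small, dt * dt * (0.5 - x / 6),
                      (x - 1 + e) * (dt * dt) / np.where(small, 1, x * x))
    seg = c0 * i0 + (c1 - c0) / dt * i1  # (n_vox, n_t-1)

    integral = np.zeros((kt.size, n_t))
    if kt.size == 1:
        # small problems: closed-form decay matrix, no Python loop
        lag = times[1:, None] - times[None, 1:]  # t_k - t_(j+1), k,j over segments
        decay = np.where(lag >= 0, np.exp(-kep[0] * np.maximum(lag, 0.0)), 0.0)
        integral[0, 1:] = decay @ seg[0]
    else:
        acc = np.zeros(kt.size)
        for k in range(1, n_t):
            acc = acc * e[:, k - 1] + seg[:, k - 1]
            integral[:, k] = acc

    ct = vp_a[:, None] * cp[None, :] + kt_s[:, None] * integral
    return ct[0] if scalar else ct


def _tofts_model_factory(cp: np.ndarray, times: np.ndarray):
    """Closure computing the extended-Tofts curve and its analytic Jacobian.

    Shares the piecewise-linear segment algebra of :func:`tofts_forward`
    so fitted and forward curves agree to machine precision, and returns
    d(Ct)/d(ktrans, ve, vp) in closed form to spare finite differences.
    """
    dt = np.diff(times)
    c0, c1 = cp[:-1], cp[1:]
    slope = (c1 - c0) / dt
    lag = times[1:, None] - times[None, 1:]
    pos = lag >= 0
    lag_pos = np.maximum(lag, 0.0)

    def curve_and_grad(p):
        kt, ve, vp = p
        kep = kt / (60.0 * ve)  # 1/s
        x = kep * dt
        e = np.exp(-x)
        small = x < 1e-6
        with np.errstate(divide="ignore", invalid="ignore"):
            i0 = np.where(small, dt * (1 - x / 2), -np.expm1(-x) / np.where(small, 1, kep))
            i1 = np.where(small, dt * dt * (0.5 - x / 6),
                          (x - 1 + e) / np.where(small, 1, kep * kep))
            di0 = np.where(small, dt * dt * (-0.5 + x / 3),
                           dt * e / np.where(small, 1, kep)
                           + np.expm1(-x) / np.where(small, 1, kep * kep))
            di1 = np.where(small, dt**3 * (-1.0 / 6 + x / 12),
                           dt * (1 - e) / np.where(small, 1, kep * kep)
                           - 2 * (x - 1 + e) / np.where(small, 1, kep**3))
        seg = c0 * i0 + slope * i1
        dseg = c0 * di0 + slope * di1
        decay = np.where(pos, np.exp(-kep * lag_pos), 0.0)
        integral = decay @ seg
        d_integral = (-lag_pos * decay) @ seg + decay @ dseg

        kt_s = kt / 60.0
        ct = vp * cp
        ct[1:] += kt_s * integral
        jac = np.zeros((len(cp), 3))
        # dkep/dkt = 1/(60 ve); dkep/dve = -kep/ve
        jac[1:, 0] = integral / 60.0 + kt_s * d_integral / (60.0 * ve)
        jac[1:, 1] = kt_s * d_integral * (-kep / ve)
        jac[:, 2] = cp
        return ct, jac

    return curve_and_grad


def fit_extended_tofts(
    conc: ConcentrationSeries,
    aif: Aif,
    mask: np.ndarray,
    bounds=TOFTS_BOUNDS,
    starts=TOFTS_STARTS,
    rss_ceiling: float | None = None,
) -> ToftsMaps:
    """Bounded voxelwise nonlinear least squares of the extended Tofts model.

    Each masked voxel is fitted independently from three starting points
    spanning low/medium/high exchange regimes; the best residual sum of
    squares wins, so the result does not depend on start order. Voxels
    pinned to a bound or exceeding ``rss_ceiling`` are flagged.
    All-zero curves short-circuit to the degenerate (0, ve_min, 0).
    """
    if aif.arrival_frame is None:
        raise ValueError("AIF has no arrival frame; run detect_bolus_arrival")
    n_post = (conc.times > aif.times[aif.arrival_frame]).sum()
    if n_post < 10:
        raise ValueError(f"need >= 10 post-arrival frames, got {n_post}")
    mask = np.asarray(mask, dtype=bool)
    shape3 = conc.conc.shape[:3]
    if mask.shape != shape3:
        raise ValueError("mask grid does not match concentration grid")

    times = conc.times
    lb, ub = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    curves = conc.conc[mask]
    n_vox = curves.shape[0]

    kt_out = np.full(n_vox, np.nan)
    ve_out = np.full(n_vox, np.nan)
    vp_out = np.full(n_vox, np.nan)
    rss_out = np.full(n_vox, np.nan)
    ok_out = np.zeros(n_vox, dtype=bool)

    model = _tofts_model_factory(aif.cp, times)

    scale = float(np.nanmax(np.abs(aif.cp))) or 1.0
    for i in range(n_vox):
        ct = curves[i]
        finite = np.isfinite(ct)
        if finite.sum() < 10:
            continue
        ct_f = ct[finite]
        if np.allclose(ct_f, 0.0):
            kt_out[i], ve_out[i], vp_out[i], rss_out[i] = 0.0, lb[1], 0.0, 0.0
            ok_out[i] = False  # degenerate: nothing to identify
            continue

        def fun(p):
            return model(p)[0][finite] - ct_f

        def jac(p):
            return model(p)[1][finite]

        best = None
        for p0 in starts:
            try:
                res = least_squares(fun, p0, jac=jac, bounds=(lb, ub),
                                    method="trf", xtol=1e-10, ftol=1e-10)
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            continue
        kt_out[i], ve_out[i], vp_out[i] = best.x
        rss_out[i] = 2 * best.cost
        at_bound = np.any(
            (np.abs(best.x - lb) < 1e-9 * np.maximum(1, np.abs(lb)))
            | (np.abs(best.x - ub) < 1e-9 * np.abs(ub))
        )
        # ktrans=0 and vp=0 are legitimate interior-physiology values
        benign = (np.abs(best.x[0] - lb[0]) < 1e-9) or (np.abs(best.x[2] - lb[2]) < 1e-9)
        flagged = at_bound and not benign
        if rss_ceiling is not None and rss_out[i] > rss_ceiling * scale**2:
            flagged = True
        ok_out[i] = not flagged

    def unmask(v):
        out = np.full(shape3, np.nan)
        out[mask] = v
        return out

    valid = np.zeros(shape3, dtype=bool)
    valid[mask] = ok_out
    return ToftsMaps(
        ktrans=ParameterMap("ktrans", unmask(kt_out), units="1/min", valid=valid),
        ve=ParameterMap("ve", unmask(ve_out), valid=valid),
        vp=ParameterMap("vp", unmask(vp_out), valid=valid),
        rss=unmask(rss_out),
        valid=valid,
    )
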