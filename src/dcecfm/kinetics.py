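"""Tracer-kinetic modeling for dynamic contrast-enhanced MRI.

Implements the extended Tofts model (ETM)

    C_t(t) = Ktrans * int_0^t exp(-kep (t - tau)) C_p(tau) dtau + v_p C_p(t),

with kep = Ktrans / v_e, the SPGR signal <-> concentration conversion, the
two-compartment diffusive/convective flux model

    v_e dC_e/dt = (PS/V) (C_p - C_e) + (Jv/V) (1 - sigma_T) C_p,

and the rescaling of fitted Jv/V into a spatially varying capillary hydraulic
conductivity Lp*(S/V).

Conventions: times are in seconds; rate constants Ktrans and kep are reported
in min^-1 (the clinical convention) and converted to s^-1 internally; PS/V and
Jv/V are in s^-1; concentrations in mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import LP0_RESCALE, S_OVER_V_RESCALE

__all__ = [
    "ConcentrationSeries",
    "ETMParams",
    "FluxParams",
    "LpScalingField",
    "exp_conv",
    "etm_forward",
    "fit_etm",
    "fit_etm_map",
    "derive_ce",
    "fit_flux_model",
    "flux_forward",
    "rescale_lp",
    "spgr_signal",
    "concentration_from_signal",
]

SEC_PER_MIN = 60.0

#: Default contrast-agent longitudinal relaxivity, L mmol^-1 s^-1
#: (gadobutrol-like at 3 T).
DEFAULT_RELAXIVITY = 4.5

# Bounded-fit box and the fixed multi-start grid for the ETM fit
# (Ktrans [min^-1], v_e [-], v_p [-]).
ETM_LOWER = np.array([0.0, 1e-3, 0.0])
ETM_UPPER = np.array([5.0, 1.0, 0.5])
ETM_STARTS = (
    (0.05, 0.2, 0.02),
    (0.3, 0.4, 0.05),
    (1.0, 0.7, 0.1),
)


@dataclass
class ConcentrationSeries:
    """Tissue concentration curve(s) on a common timebase.

    ``ct`` has shape (..., n_t): a single curve or any stack of voxel curves.
    ``clipped`` flags samples where the SPGR inversion left its valid range.
    """

    times: np.ndarray
    ct: np.ndarray
    ce: np.ndarray | None = None
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape[-1] != self.times.shape[-1]:
            raise ValueError("ct and times length mismatch")
        if not np.all(np.isfinite(self.ct)):
            raise ValueError("ct must be finite")


@dataclass
class ETMParams:
    """Extended Tofts parameters for one voxel/ROI.

    ktrans and kep in min^-1, ve and vp as volume fractions; kep is always
    ktrans/ve.  ``converged`` is False for flagged voxels, whose parameters
    are NaN sentinels.
    """

    ktrans: float
    ve: float
    vp: float
    kep: float
    residual_norm: float = 0.0
    converged: bool = True

    @classmethod
    def from_fit(cls, ktrans: float, ve: float, vp: float,
                 residual_norm: float = 0.0, converged: bool = True) -> "ETMParams":
        return cls(ktrans=ktrans, ve=ve, vp=vp, kep=ktrans / ve,
                   residual_norm=residual_norm, converged=converged)

    def __post_init__(self) -> None:
        if self.converged:
            if self.ktrans < 0:
                raise ValueError("ktrans must be >= 0")
            if not (0 < self.ve <= 1):
                raise ValueError("ve must lie in (0, 1]")
            if not (0 <= self.vp < 1):
                raise ValueError("vp must lie in [0, 1)")
            if self.ve + self.vp > 1 + 1e-9:
                raise ValueError("ve + vp must not exceed 1")
            if abs(self.kep - self.ktrans / self.ve) > 1e-9 * max(self.kep, 1e-30):
                raise ValueError("kep must equal ktrans/ve")


@dataclass
class FluxParams:
    """Diffusive/convective flux parameters: PS/V and Jv/V in s^-1."""

    ve: float
    ps_over_v: float
    jv_over_v: float
    residual_norm: float = 0.0
    identifiable: bool = True


@dataclass
class LpScalingField:
    """Spatially varying Lp*(S/V) map (Pa^-1 s^-1) from rescaled Jv/V."""

    lp_sv: np.ndarray
    mean_jv_over_v: float
    lp0: float = LP0_RESCALE
    s_over_v: float = S_OVER_V_RESCALE


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def exp_conv(rate_s: np.ndarray | float, times: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Convolution int_0^t exp(-rate (t - tau)) cp(tau) dtau.

    Evaluated with the exponential-kernel recursion that is exact for a
    piecewise-linear ``cp``; this is the standard deconvolution-free way to
    evaluate Tofts-type models on coarse clinical sampling.

    Parameters
    ----------
    rate_s : float or array, shape (...,)
        Decay rate in s^-1 (>= 0); broadcasts against voxel axes.
    times : array, shape (n_t,)
        Sample times, s, strictly increasing.
    cp : array, shape (n_t,)
        Plasma concentration at ``times``.

    Returns
    -------
    array, shape (..., n_t)
    """
    times = np.asarray(times, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if times.ndim != 1 or times.shape != cp.shape:
        raise ValueError("times and cp must be 1-D and the same length")
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rate = np.atleast_1d(np.asarray(rate_s, dtype=float))
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    if np.isscalar(rate_s) or np.ndim(rate_s) == 0:
        return _exp_conv_scalar(float(rate[0]), times, cp)

    n_t = times.size
    out = np.zeros(rate.shape + (n_t,), dtype=float)
    acc = np.zeros(rate.shape, dtype=float)
    for n in range(1, n_t):
        dt = times[n] - times[n - 1]
        x = rate * dt
        e = np.exp(-x)
        small = x < 1e-6
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(small, dt * (1.0 - 0.5 * x), -np.expm1(-x) / np.where(rate > 0, rate, 1.0))
            b = np.where(
                small,
                dt * (0.5 - x / 6.0),
                np.where(rate > 0, 1.0 / np.where(rate > 0, rate, 1.0), 0.0)
                + np.expm1(-x) / np.where(rate > 0, rate**2 * dt, 1.0),
            )
        # segment integral of exp kernel against the linear interpolant of cp
        acc = acc * e + cp[n - 1] * (a - b) + cp[n] * b
        out[..., n] = acc
    return out


def _exp_conv_scalar(rate: float, times: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Scalar-rate fast path of :func:`exp_conv` (plain-float recursion)."""
    n_t = times.size
    out = np.empty(n_t)
    out[0] = 0.0
    acc = 0.0
    t = times.tolist()
    c = cp.tolist()
    for n in range(1, n_t):
        dt = t[n] - t[n - 1]
        x = rate * dt
        if x < 1e-6:
            a = dt * (1.0 - 0.5 * x)
            b = dt * (0.5 - x / 6.0)
        else:
            em = math.expm1(-x)
            a = -em / rate
            b = 1.0 / rate + em / (rate * rate * dt)
        acc = acc * math.exp(-x) + c[n - 1] * (a - b) + c[n] * b
        out[n] = acc
    return out


def etm_forward(params: ETMParams | Sequence[float], times: np.ndarray,
                cp: np.ndarray) -> np.ndarray:
    """Tissue concentration predicted by the extended Tofts model.

    ``params`` may be an :class:`ETMParams` or a (ktrans_min, ve, vp) triple
    (rates in min^-1).  Ktrans/kep may be voxel arrays for a vectorized
    evaluation.
    """
    if isinstance(params, ETMParams):
        ktrans, ve, vp = params.ktrans, params.ve, params.vp
    else:
        ktrans, ve, vp = params
    ktrans = np.asarray(ktrans, dtype=float)
    ve = np.asarray(ve, dtype=float)
    vp = np.asarray(vp, dtype=float)
    kep_s = np.where(ve > 0, ktrans / np.where(ve > 0, ve, 1.0), 0.0) / SEC_PER_MIN
    conv = exp_conv(kep_s, times, cp)
    kt_s = ktrans / SEC_PER_MIN
    return kt_s[..., None] * conv + vp[..., None] * np.asarray(cp, dtype=float)


def flux_forward(ve: float, ps_over_v: float, jv_over_v: float, sigma_t: float,
                 times: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """EES concentration from the diffusive+convective flux model.

    Solves v_e dCe/dt = PS/V (Cp - Ce) + Jv/V (1 - sigma_T) Cp with Ce(0)=0.
    The solution is ((PS/V + Jv/V(1-sigma_T))/v_e) * exp(-PS/(V v_e) t) (*) Cp,
    evaluated with the same exact piecewise-linear recursion as the ETM.
    """
    if ve <= 0:
        raise ValueError("ve must be positive")
    kd = ps_over_v / ve  # s^-1 decay rate of the EES pool
    amp = (ps_over_v + jv_over_v * (1.0 - sigma_t)) / ve
    return amp * exp_conv(kd, times, cp)


# ---------------------------------------------------------------------------
# SPGR signal model
# ---------------------------------------------------------------------------

def spgr_signal(conc_mM: np.ndarray, t10_s: np.ndarray | float, tr_s: float,
                flip_angle_deg: float, relaxivity: float = DEFAULT_RELAXIVITY,
                m0: float = 1000.0) -> np.ndarray:
    """Steady-state spoiled gradient-echo signal for a given CA concentration.

    S = M0 sin(a) (1 - E1) / (1 - cos(a) E1), E1 = exp(-TR * R1) with
    R1 = 1/T10 + r1 * C.  The TE-dependent T2* factor is constant over the
    dynamic series and is absorbed into ``m0``.
    """
    conc = np.asarray(conc_mM, dtype=float)
    t10 = np.asarray(t10_s, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("T10 must be positive")
    a = np.deg2rad(flip_angle_deg)
    r1 = 1.0 / t10 + relaxivity * conc
    e1 = np.exp(-tr_s * r1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def concentration_from_signal(signal: np.ndarray, t10_s: np.ndarray | float,
                              tr_s: float, flip_angle_deg: float,
                              relaxivity: float = DEFAULT_RELAXIVITY,
                              baseline_frames: int = 3,
                              times: np.ndarray | None = None) -> ConcentrationSeries:
    """Invert the SPGR steady-state equation to a concentration series.

    The baseline signal S0 is the mean of the first ``baseline_frames``
    pre-bolus frames.  For each sample the relative enhancement is mapped back
    through the SPGR saturation curve to E1 and then to concentration; samples
    whose enhancement exceeds the SPGR-attainable range are clamped to the
    asymptote and flagged in ``clipped``.

    Parameters
    ----------
    signal : array, shape (..., n_t)
    t10_s : pre-contrast T1, s (scalar or broadcastable to the voxel axes)
    """
    signal = np.asarray(signal, dtype=float)
    if not (0.0 < flip_angle_deg < 90.0):
        raise ValueError("flip angle must lie in (0, 90) degrees")
    if baseline_frames < 1 or baseline_frames > signal.shape[-1]:
        raise ValueError("invalid baseline frame count")
    t10 = np.asarray(t10_s, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("T10 must be positive")

    cos_a = np.cos(np.deg2rad(flip_angle_deg))
    e10 = np.exp(-tr_s / t10)
    s0 = signal[..., :baseline_frames].mean(axis=-1)
    # baseline saturation factor; S/S0 * b == (1-E1)/(1-cos(a) E1)
    b = ((1.0 - e10) / (1.0 - cos_a * e10))[..., None] if np.ndim(e10) else (1.0 - e10) / (1.0 - cos_a * e10)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s0[..., None] > 0, signal / np.where(s0[..., None] > 0, s0[..., None], 1.0), 0.0)
    y = ratio * b  # target value of (1-E1)/(1-cos(a) E1), in [0, 1/(1-cos a))
    y_max = 1.0 / (1.0 - cos_a)
    clipped = y >= y_max
    y = np.clip(y, None, y_max * (1.0 - 1e-12))
    e1 = (1.0 - y) / (1.0 - cos_a * y)
    e1 = np.clip(e1, 1e-300, 1.0)
    r1 = -np.log(e1) / tr_s
    r10 = 1.0 / t10
    conc = (r1 - (r10[..., None] if np.ndim(r10) else r10)) / relaxivity
    if times is None:
        times = np.arange(signal.shape[-1], dtype=float)
    return ConcentrationSeries(times=np.asarray(times, dtype=float), ct=conc,
                               clipped=clipped)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_etm(ct: np.ndarray, times: np.ndarray, cp: np.ndarray) -> ETMParams:
    """Fit the extended Tofts model to one concentration curve.

    Bounded nonlinear least squares (trust-region reflective) from a fixed
    3-point multi-start grid; the winner is the lowest residual with ties
    broken by the lower Ktrans, which makes the fit deterministic.
    Non-convergent voxels are flagged with NaN sentinels.
    """
    ct = np.asarray(ct, dtype=float)
    times = np.asarray(times, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if times.size < 10:
        raise ValueError("at least 10 time points are required")
    if not np.any(np.abs(cp) > 0):
        raise ValueError("AIF must be nonzero")

    if np.max(np.abs(ct)) < 1e-12:
        return ETMParams.from_fit(0.0, 0.5, 0.0, residual_norm=0.0)

    def residuals(x: np.ndarray) -> np.ndarray:
        return etm_forward((x[0], x[1], x[2]), times, cp) - ct

    best: tuple[float, float, np.ndarray] | None = None
    ok = False
    for start in ETM_STARTS:
        try:
            res = least_squares(residuals, np.asarray(start, dtype=float),
                                bounds=(ETM_LOWER, ETM_UPPER), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.success:
            ok = True
        key = (res.cost, res.x[0])
        if best is None or key < (best[0], best[1]):
            best = (res.cost, res.x[0], res.x)
    if best is None or not ok:
        return ETMParams(ktrans=np.nan, ve=np.nan, vp=np.nan, kep=np.nan,
                         residual_norm=np.nan, converged=False)
    kt, ve, vp = best[2]
    return ETMParams.from_fit(float(kt), float(ve), float(vp),
                              residual_norm=float(np.sqrt(2.0 * best[0])))


def fit_etm_map(ct_stack: np.ndarray, times: np.ndarray, cp: np.ndarray,
                mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Voxel-by-voxel ETM fit over a (..., n_t) stack of curves.

    Returns maps of ``ktrans``/``ve``/``vp``/``kep`` (NaN outside ``mask`` and
    for flagged voxels) plus a boolean ``converged`` map.
    """
    ct_stack = np.asarray(ct_stack, dtype=float)
    spatial = ct_stack.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    out = {k: np.full(spatial, np.nan) for k in ("ktrans", "ve", "vp", "kep")}
    out["converged"] = np.zeros(spatial, dtype=bool)
    for idx in np.argwhere(mask):
        p = fit_etm(ct_stack[tuple(idx)], times, cp)
        t = tuple(idx)
        out["ktrans"][t], out["ve"][t], out["vp"][t], out["kep"][t] = (
            p.ktrans, p.ve, p.vp, p.kep)
        out["converged"][t] = p.converged
    return out


def derive_ce(ct: np.ndarray, cp: np.ndarray, ve: float, vp: float) -> np.ndarray:
    """EES concentration from the compartmental identity Ct = ve*Ce + vp*Cp.

    Negative transients (noise-driven) are floored at zero.
    """
    if ve <= 0:
        raise ValueError("ve must be positive")
    ce = (np.asarray(ct, dtype=float) - vp * np.asarray(cp, dtype=float)) / ve
    return np.maximum(ce, 0.0)


def fit_flux_model(ce: np.ndarray, times: np.ndarray, cp: np.ndarray,
                   sigma_t: float, ve: float) -> FluxParams:
    """Fit PS/V and Jv/V of the diffusive/convective flux model to a Ce curve.

    ``ve`` is held fixed (taken from the ETM fit of the same voxel); the two
    remaining rates are fit by bounded least squares on the closed-form ODE
    solution.  With a zero AIF the rates are unidentifiable and the result is
    rejected.
    """
    ce = np.asarray(ce, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if not (0.0 <= sigma_t <= 1.0):
        raise ValueError("sigma_t must lie in [0, 1]")
    if ve <= 0:
        raise ValueError("ve must be positive")
    if not np.any(np.abs(cp) > 0):
        raise ValueError("degenerate AIF: flux parameters are unidentifiable")

    def residuals(x: np.ndarray) -> np.ndarray:
        return flux_forward(ve, x[0], x[1], sigma_t, times, cp) - ce

    starts = ((1e-3, 1e-4), (1e-4, 1e-5), (1e-2, 1e-3))
    best = None
    for s in starts:
        res = least_squares(residuals, np.asarray(s), bounds=([0.0, 0.0], [1.0, 1.0]),
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        key = (res.cost, res.x[0])
        if best is None or key < (best[0], best[1]):
            best = (res.cost, res.x[0], res.x)
    psv, jvv = best[2]
    return FluxParams(ve=ve, ps_over_v=float(psv), jv_over_v=float(jvv),
                      residual_norm=float(np.sqrt(2.0 * best[0])))


def rescale_lp(jv_over_v: np.ndarray, tumor_mask: np.ndarray,
               lp0: float = LP0_RESCALE,
               s_over_v: float = S_OVER_V_RESCALE) -> LpScalingField:
    """Rescale a Jv/V map into a spatially varying Lp*(S/V) field.

    lp_sv = lp0 * (S/V) * (Jv/V) / <Jv/V>, with the mean taken over the tumor
    mask, so the tumor mean of lp_sv is exactly lp0*(S/V).
    """
    jv = np.asarray(jv_over_v, dtype=float)
    mask = np.asarray(tumor_mask, dtype=bool)
    if not mask.any():
        raise ValueError("tumor mask is empty")
    mean_jv = float(jv[mask].mean())
    if mean_jv <= 0:
        raise ValueError("mean Jv/V over the tumor must be positive")
    lp_sv = np.where(mask, lp0 * s_over_v * jv / mean_jv, 0.0)
    return LpScalingField(lp_sv=lp_sv, mean_jv_over_v=mean_jv, lp0=lp0,
                          s_over_v=s_over_v)
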