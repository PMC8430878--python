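"""Stationary interstitial-fluid-pressure solve and Darcy velocity maps.

The continuity equation for incompressible flow in porous tissue, with a
Starling transcapillary source and a lymphatic sink, is

    -K_H lap(p_i) = f * [L_p S/V (p_V - p_i - sigma_T (pi_V - pi_i))]
                    - L_pL S_L/V (p_i - p_L),

where f = Ktrans/<Ktrans> conveys relative vascular leakiness inside the
tumor (f = 1 in normal tissue) and the lymphatic term is active only in
normal tissue.  The equation is discretized with a 7-point finite-difference
stencil on the labeled isotropic voxel domain, with harmonic-mean K_H on
faces between unlike tissues and a homogeneous Neumann (no-flux) condition on
the outer domain surface, and solved with a preconditioned conjugate-gradient
sparse solver.  The Darcy velocity is u = -K_H grad(p_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

from .constants import TissueConstants
from .domain import LABEL_NORMAL, LABEL_TUMOR, DomainGrid

__all__ = [
    "Coefficients", "PressureField", "VelocityField", "TimepointSummary",
    "assemble_coefficients", "solve_ifp", "compute_ifv", "summarize_fields",
]

SCALING_MODES = ("ktrans_scaling", "lp_field", "both")


@dataclass
class Coefficients:
    """Per-voxel PDE coefficients on the full grid (NaN/0 outside domain).

    g_v is the effective source conductance f*L_p*(S/V) [Pa^-1 s^-1], g_l the
    lymphatic sink conductance, p_eq the local Starling equilibrium pressure
    [Pa] and kh the tissue hydraulic conductivity [m^2 Pa^-1 s^-1].
    """

    g_v: np.ndarray
    g_l: np.ndarray
    p_eq: np.ndarray
    kh: np.ndarray
    f: np.ndarray
    constants: TissueConstants


@dataclass
class PressureField:
    """Interstitial fluid pressure p_i [Pa], NaN outside the domain."""

    p: np.ndarray
    spacing_mm: float
    residual: float
    iterations: int
    method: str
    conservation_ratio: float = np.nan

    def tumor_stats_kpa(self, tumor_mask: np.ndarray) -> tuple[float, float]:
        vals = self.p[tumor_mask] / 1000.0
        return float(vals.mean()), float(vals.std())


@dataclass
class VelocityField:
    """Darcy velocity u = -K_H grad(p_i) [m/s] and its magnitude."""

    u: np.ndarray  # (3, nx, ny, nz)
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        if self.u.shape[0] != 3:
            raise ValueError("u must stack 3 components on axis 0")


@dataclass
class TimepointSummary:
    """Tumor-label summary of one exam for the cohort table."""

    label: str
    mean_ifp_kpa: float
    sd_ifp_kpa: float
    mean_ifv: float
    sd_ifv: float
    mean_ktrans: float
    sd_ktrans: float
    vt_cm3: float
    subject: str = ""


def assemble_coefficients(domain: DomainGrid, constants: TissueConstants | None = None,
                          scaling_mode: str = "ktrans_scaling",
                          lp_field: np.ndarray | None = None) -> Coefficients:
    """Assemble per-voxel source/sink conductances and equilibrium pressures.

    scaling_mode selects how vascular heterogeneity enters the source term:
    ``ktrans_scaling`` multiplies the constant L_p,0*(S/V) by the normalized
    Ktrans (default), ``lp_field`` uses a spatially varying Lp*(S/V) map (from
    :func:`dcecfm.kinetics.rescale_lp`), and ``both`` applies the Ktrans
    factor on top of that map.  Outside the tumor f = 1 and the normal-tissue
    constant table applies.
    """
    if constants is None:
        constants = TissueConstants()
    if scaling_mode not in SCALING_MODES:
        raise ValueError(f"scaling_mode must be one of {SCALING_MODES}")
    labels = domain.labels
    tumor = labels == LABEL_TUMOR
    normal = labels == LABEL_NORMAL

    f = np.ones(labels.shape, dtype=float)
    if scaling_mode in ("ktrans_scaling", "both"):
        kt = domain.ktrans
        if np.any(~np.isfinite(kt[tumor])):
            raise ValueError("Ktrans is missing on tumor voxels")
        if not domain.ktrans_mean > 0:
            raise ValueError("<Ktrans> over the tumor must be positive")
        f[tumor] = kt[tumor] / domain.ktrans_mean

    base_gv = np.zeros(labels.shape, dtype=float)
    if scaling_mode in ("lp_field", "both"):
        src = lp_field if lp_field is not None else domain.lp_sv
        if src is None:
            raise ValueError("scaling_mode %r needs an Lp*(S/V) field" % scaling_mode)
        base_gv[tumor] = np.asarray(src)[tumor]
    else:
        base_gv[tumor] = constants.tumor.lp0 * constants.tumor.s_over_v
    base_gv[normal] = constants.normal.lp0 * constants.normal.s_over_v

    g_v = f * base_gv
    g_l = np.zeros(labels.shape, dtype=float)
    g_l[normal] = constants.normal.lymph_coeff

    p_eq = np.full(labels.shape, np.nan)
    p_eq[tumor] = constants.equilibrium_pressure("tumor")
    p_eq[normal] = constants.equilibrium_pressure("normal")

    kh = np.zeros(labels.shape, dtype=float)
    kh[tumor] = constants.tumor.kh
    kh[normal] = constants.normal.kh
    return Coefficients(g_v=g_v, g_l=g_l, p_eq=p_eq, kh=kh, f=f,
                        constants=constants)


def _face_links(in_domain: np.ndarray, kh: np.ndarray, h_m: float):
    """Index pairs and harmonic-mean conductances for all interior faces."""
    idx = np.full(in_domain.shape, -1, dtype=np.int64)
    idx[in_domain] = np.arange(int(in_domain.sum()))
    rows, cols, w = [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a, b = tuple(sl_a), tuple(sl_b)
        both = in_domain[a] & in_domain[b]
        ka, kb = kh[a][both], kh[b][both]
        k_face = 2.0 * ka * kb / (ka + kb)
        rows.append(idx[a][both])
        cols.append(idx[b][both])
        w.append(k_face / h_m**2)
    return idx, np.concatenate(rows), np.concatenate(cols), np.concatenate(w)


def solve_ifp(domain: DomainGrid, constants: TissueConstants | None = None,
              scaling_mode: str = "ktrans_scaling", tol: float = 1e-10,
              lp_field: np.ndarray | None = None) -> PressureField:
    """Solve the stationary pressure PDE on the labeled domain.

    7-point finite differences with harmonic-mean K_H across unlike-tissue
    faces and a no-flux outer boundary; the symmetric positive-definite
    system is solved by diagonally preconditioned conjugate gradients to a
    relative residual of ``tol`` (direct sparse fallback if CG stalls).

    Raises if every source and sink conductance vanishes (the Neumann system
    is then singular).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    coeff = assemble_coefficients(domain, constants, scaling_mode, lp_field)
    in_domain = domain.domain_mask
    n = int(in_domain.sum())
    if n == 0:
        raise ValueError("empty simulation domain")
    gv = coeff.g_v[in_domain]
    gl = coeff.g_l[in_domain]
    if not np.any(gv + gl > 0):
        raise ValueError("all sources and sinks vanish: pressure is undetermined "
                         "(pure-Neumann singular system)")
    peq = np.nan_to_num(coeff.p_eq[in_domain])
    pl = (coeff.constants or TissueConstants()).pl

    h_m = domain.spacing_mm * 1e-3
    idx, rows, cols, w = _face_links(in_domain, coeff.kh, h_m)
    diag = np.zeros(n)
    np.add.at(diag, rows, w)
    np.add.at(diag, cols, w)
    diag += gv + gl
    A = sparse.coo_matrix(
        (np.concatenate([-w, -w, diag]),
         (np.concatenate([rows, cols, np.arange(n)]),
          np.concatenate([cols, rows, np.arange(n)]))),
        shape=(n, n)).tocsr()
    b = gv * peq + gl * pl

    x0 = np.full(n, float(np.mean(peq)))
    M = sparse.diags(1.0 / diag)
    it = [0]

    def count(_):
        it[0] += 1

    x, info = cg(A, b, x0=x0, rtol=tol, atol=0.0, maxiter=20000, M=M,
                 callback=count)
    method = "cg"
    if info != 0:
        x = spsolve(A.tocsc(), b)
        method = "spsolve"
    res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))

    p = np.full(domain.labels.shape, np.nan)
    p[in_domain] = x
    # discrete conservation: with no-flux walls the net volumetric source must
    # balance the net sink at the solution
    phi_v = gv * (peq - x)
    phi_l = gl * (x - pl)
    gross = float(np.sum(np.abs(phi_v)))
    ratio = float(abs(np.sum(phi_v - phi_l)) / gross) if gross > 0 else np.nan
    return PressureField(p=p, spacing_mm=domain.spacing_mm, residual=res,
                         iterations=it[0], method=method,
                         conservation_ratio=ratio)


def compute_ifv(pressure: PressureField, kh: np.ndarray,
                domain_mask: np.ndarray) -> VelocityField:
    """Darcy velocity u = -K_H grad(p_i) from the solved pressure.

    Central differences where both axial neighbors are inside the domain,
    one-sided differences at the domain surface, zero where a voxel has no
    in-domain neighbor along an axis.  Units: m/s (spacing converted to m).
    """
    p = pressure.p
    h_m = pressure.spacing_mm * 1e-3
    grad = np.zeros((3,) + p.shape)
    inm = domain_mask
    for axis in range(3):
        fwd = np.roll(inm, -1, axis=axis) & inm
        fwd[tuple(slice(-1, None) if a == axis else slice(None) for a in range(3))] = False
        bwd = np.roll(inm, 1, axis=axis) & inm
        bwd[tuple(slice(0, 1) if a == axis else slice(None) for a in range(3))] = False
        p_f = np.roll(p, -1, axis=axis)
        p_b = np.roll(p, 1, axis=axis)
        g = np.zeros(p.shape)
        central = fwd & bwd
        g[central] = (p_f[central] - p_b[central]) / (2.0 * h_m)
        only_f = fwd & ~bwd
        g[only_f] = (p_f[only_f] - p[only_f]) / h_m
        only_b = bwd & ~fwd
        g[only_b] = (p[only_b] - p_b[only_b]) / h_m
        grad[axis] = np.where(inm, g, 0.0)
    u = -np.asarray(kh) * grad
    u = np.where(inm, u, 0.0)
    mag = np.sqrt((u**2).sum(axis=0))
    return VelocityField(u=u, magnitude=mag)


def summarize_fields(pressure: PressureField, velocity: VelocityField,
                     domain: DomainGrid, label: str = "pre-TX",
                     subject: str = "") -> TimepointSummary:
    """Tumor-label mean/SD of IFP (kPa), IFV magnitude (m/s) and Ktrans."""
    tumor = domain.tumor_mask
    if not tumor.any():
        raise ValueError("empty tumor label")
    p_kpa = pressure.p[tumor] / 1000.0
    v = velocity.magnitude[tumor]
    kt = domain.ktrans[tumor]
    vt = float(tumor.sum()) * (domain.spacing_mm**3) / 1000.0
    return TimepointSummary(
        label=label, subject=subject,
        mean_ifp_kpa=float(p_kpa.mean()), sd_ifp_kpa=float(p_kpa.std()),
        mean_ifv=float(v.mean()), sd_ifv=float(v.std()),
        mean_ktrans=float(np.nanmean(kt)), sd_ktrans=float(np.nanstd(kt)),
        vt_cm3=vt)
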