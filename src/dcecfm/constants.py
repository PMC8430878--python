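"""Physiological constants for the porous-media fluid model.

All values are SI (Pa, m, s) and are literature values for solid tumors and
normal surrounding tissue.  They parameterize the Starling source, lymphatic
sink and Darcy conduction terms of the stationary interstitial-pressure PDE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["TissueParams", "TissueConstants", "LP0_RESCALE", "S_OVER_V_RESCALE"]

#: Literature capillary hydraulic conductivity used when rescaling Jv/V into a
#: spatially varying Lp*(S/V) field, m Pa^-1 s^-1.
LP0_RESCALE = 2.1e-11

#: Literature capillary surface-to-volume ratio for the same rescaling, m^-1.
S_OVER_V_RESCALE = 2.0e4


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue physical parameters.

    Attributes
    ----------
    lp0 : float
        Vessel-wall hydraulic conductivity L_p,0, m Pa^-1 s^-1.
    s_over_v : float
        Capillary surface area per unit tissue volume S/V, m^-1.
    lymph_coeff : float
        Lymphatic filtration coefficient L_pL*S_L/V, Pa^-1 s^-1 (zero inside
        tumor: lymphatics are nonfunctional there).
    kh : float
        Tissue hydraulic conductivity K_H = K/mu, m^2 Pa^-1 s^-1.
    pi_i : float
        Interstitial osmotic pressure pi_i, Pa.
    sigma_t : float
        Osmotic reflection coefficient sigma_T, dimensionless in [0, 1].
    """

    lp0: float
    s_over_v: float
    lymph_coeff: float
    kh: float
    pi_i: float
    sigma_t: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sigma_t <= 1.0):
            raise ValueError(f"sigma_t must lie in [0, 1], got {self.sigma_t}")
        for name in ("lp0", "s_over_v", "kh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lymph_coeff < 0:
            raise ValueError("lymph_coeff must be >= 0")


@dataclass(frozen=True)
class TissueConstants:
    """Tumor/normal parameter pairs plus shared vascular pressures.

    Defaults are the literature values for solid tumors embedded in normal
    tissue: microvascular pressure p_V = 2300 Pa, lymphatic pressure
    p_L = 0 Pa, plasma osmotic pressure pi_V = 2670 Pa, and the per-tissue
    table (tumor/normal): L_p,0 = 2e-11 / 3e-12 m Pa^-1 s^-1,
    S/V = 2e4 / 7e3 m^-1, L_pL*S_L/V = 0 / 1e-7 Pa^-1 s^-1,
    K_H = 1.9e-12 / 3.8e-13 m^2 Pa^-1 s^-1, pi_i = 3230 / 1330 Pa,
    sigma_T = 0.82 / 0.91.
    """

    tumor: TissueParams = field(
        default_factory=lambda: TissueParams(
            lp0=2.0e-11,
            s_over_v=2.0e4,
            lymph_coeff=0.0,
            kh=1.9e-12,
            pi_i=3230.0,
            sigma_t=0.82,
        )
    )
    normal: TissueParams = field(
        default_factory=lambda: TissueParams(
            lp0=3.0e-12,
            s_over_v=7.0e3,
            lymph_coeff=1.0e-7,
            kh=3.8e-13,
            pi_i=1330.0,
            sigma_t=0.91,
        )
    )
    pv: float = 2300.0  # microvascular pressure, Pa
    pl: float = 0.0  # lymphatic pressure, Pa
    pi_v: float = 2670.0  # plasma osmotic pressure, Pa

    def __post_init__(self) -> None:
        if self.tumor.lymph_coeff != 0.0:
            raise ValueError("lymphatic drainage must be zero on tumor tissue")

    def equilibrium_pressure(self, tissue: str) -> float:
        """Local Starling equilibrium p_V - sigma_T*(pi_V - pi_i), Pa.

        This is the pressure at which the transcapillary flux vanishes; with
        no lymphatic sink an isolated region relaxes exactly to it.
        """
        p = getattr(self, tissue)
        return self.pv - p.sigma_t * (self.pi_v - p.pi_i)

    def mixed_equilibrium_pressure(self, tissue: str) -> float:
        """Pointwise balance of Starling source against the lymphatic sink, Pa.

        Root of g_v*(p_eq - p) = g_L*(p - p_L); reduces to the Starling
        equilibrium where the lymphatic coefficient is zero.
        """
        p = getattr(self, tissue)
        gv = p.lp0 * p.s_over_v
        gl = p.lymph_coeff
        return (gv * self.equilibrium_pressure(tissue) + gl * self.pl) / (gv + gl)

    def to_dict(self) -> dict:
        return asdict(self)
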