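"""Characterization of artificial reference leaves.

Covers the conductance index I_g, the theoretical pore conductance of a
perforated film from its pore geometry (with end-correction factors for the
vapor shells at pore mouths), and two independent estimators of the
boundary-layer conductance g_bw: from the dry/wet reference pair's
steady-state energy balance, and from lysimetric (gravimetric) water loss of
the wet reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physics import (
    CONSTANTS,
    EnvironmentState,
    MoistAirState,
    PhysicalConstants,
    moist_air_state,
    saturation_vapor_pressure,
)
from .ebalance import SurfaceProperties, AL_SURFACE

__all__ = [
    "PoreGeometry",
    "IgRecord",
    "conductance_index",
    "conductance_index_series",
    "theoretical_gpw",
    "invert_end_correction",
    "gbw_from_dry_wet",
    "gbw_lysimetric",
    "N_ONE_END",
    "N_TWO_END",
    "N_NONE",
]

#: end-correction factors: vapor shell at the outer pore mouth only,
#: no correction, or shells at both ends of the pore.
N_ONE_END = math.pi / 4.0
N_NONE = 1.0
N_TWO_END = math.pi / 2.0

DEFAULT_DENOM_TOL = 0.05  # K; ~1.7x the camera NETD


@dataclass(frozen=True)
class PoreGeometry:
    """Perforation geometry of an AL film.

    PA: average pore area (m² pore⁻¹); PD: pore density (pores m⁻²);
    l: film thickness (m); n: end-correction factor.
    """

    PA: float
    PD: float
    l: float
    n: float = N_ONE_END

    def __post_init__(self):
        for name in ("PA", "PD", "l", "n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.PA * self.PD >= 1.0:
            raise ValueError(
                f"porosity PA*PD = {self.PA * self.PD:.3f} must be < 1")

    @property
    def pore_radius(self) -> float:
        """Circular-equivalent pore radius √(PA/π), m."""
        return math.sqrt(self.PA / math.pi)


@dataclass(frozen=True)
class IgRecord:
    """Conductance index at one timepoint; ``valid`` is False whenever a
    denominator guard triggered (flagged, never raised, so time series
    survive transients)."""

    time: float
    object_id: str
    Ig: float
    valid: bool


def conductance_index(T_leaf: float, T_dry: float, T_wet: float,
                      denom_tol: float = DEFAULT_DENOM_TOL,
                      time: float = 0.0, object_id: str = "") -> IgRecord:
    """Conductance index I_g = (T_dry − T_leaf) / (T_leaf − T_wet).

    Locates a leaf's temperature between the non-transpiring (dry) and
    freely evaporating (wet) references. Records are flagged invalid when
    T_leaf − T_wet or T_dry − T_wet falls below ``denom_tol`` (pole guard)
    or when the index comes out negative (leaf hotter than the dry
    reference).
    """
    denom = T_leaf - T_wet
    if denom < denom_tol or (T_dry - T_wet) < denom_tol:
        return IgRecord(time=time, object_id=object_id, Ig=np.nan, valid=False)
    ig = (T_dry - T_leaf) / denom
    return IgRecord(time=time, object_id=object_id, Ig=ig, valid=ig >= 0.0)


def conductance_index_series(T_leaf, T_dry, T_wet,
                             denom_tol: float = DEFAULT_DENOM_TOL):
    """Vectorized I_g over aligned arrays; returns (Ig, valid) arrays."""
    T_leaf = np.asarray(T_leaf, dtype=float)
    T_dry = np.asarray(T_dry, dtype=float)
    T_wet = np.asarray(T_wet, dtype=float)
    denom = T_leaf - T_wet
    guard = (denom >= denom_tol) & ((T_dry - T_wet) >= denom_tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        ig = np.where(guard, (T_dry - T_leaf) / denom, np.nan)
    valid = guard & (ig >= 0.0)
    return ig, valid


def theoretical_gpw(geom: PoreGeometry,
                    constants: PhysicalConstants = CONSTANTS) -> float:
    """Theoretical anatomical maximum pore conductance, mol m⁻² s⁻¹.

    Pore-diffusion model with end correction:

        g_pw = PD·D·PA / (V·(l + n·√(PA/π)))

    where D is water-vapor diffusivity and V the molar volume of air.
    Strictly decreasing in the end-correction factor n, increasing in pore
    density and area.
    """
    r = geom.pore_radius
    return (geom.PD * constants.D_wv * geom.PA
            / (constants.V_mol * (geom.l + geom.n * r)))


def invert_end_correction(g_a: float, g_b: float, n_a: float = N_ONE_END,
                          n_b: float = N_TWO_END, n_target: float = N_NONE,
                          ) -> float:
    """Predict the pore conductance under a different end correction.

    Given the same film evaluated at two correction factors,
    g(n) = N/(l + n·r) shares N and r, so the ratio g_a/g_b fixes
    x = r/l (film thickness cancels):

        x = (g_a/g_b − 1) / (n_b − (g_a/g_b)·n_a)

    after which g(n_target) = g_a·(1 + n_a·x)/(1 + n_target·x). Exposed as
    a documented utility for cross-checking published end-correction
    triples.
    """
    if g_a <= 0 or g_b <= 0:
        raise ValueError("conductances must be positive")
    if n_a >= n_b:
        raise ValueError("n_a must be the smaller correction factor")
    ratio = g_a / g_b
    denom = n_b - ratio * n_a
    if ratio <= 1.0 or denom <= 0:
        raise ValueError(
            f"inconsistent pair: g({n_a:.3f})={g_a}, g({n_b:.3f})={g_b} "
            "does not admit a positive pore radius")
    x = (ratio - 1.0) / denom
    return g_a * (1.0 + n_a * x) / (1.0 + n_target * x)


def _dry_wet_terms(T_dry, T_wet, env: EnvironmentState,
                   surface: SurfaceProperties, air: MoistAirState):
    """Per-unit-conductance latent and sensible terms and the radiative
    imbalance of the dry/wet pair (all W m⁻², conductance in molar units)."""
    c = CONSTANTS
    eps_sum = surface.eps_top + surface.eps_bottom
    radiative = c.sigma * (np.asarray(T_dry, dtype=float) ** 4
                           - np.asarray(T_wet, dtype=float) ** 4) * eps_sum
    es_wet = saturation_vapor_pressure(np.clip(T_wet, 243.0, 333.0))
    latent_per_g = air.lambda_v * c.M_w * (es_wet - air.e_a) / env.P_atm
    # 2 faces x 0.92 x cp_molar; cp_molar == rho_air*Cp*(R*T/P) evaluated
    # consistently, so the m/s <-> molar conversion temperature cancels
    sensible_per_g = 2.0 * 0.92 * air.cp_molar * (
        np.asarray(T_dry, dtype=float) - np.asarray(T_wet, dtype=float))
    return latent_per_g, sensible_per_g, radiative


def gbw_from_dry_wet(T_dry, T_wet, env: EnvironmentState,
                     surface: SurfaceProperties = AL_SURFACE,
                     min_separation: float = DEFAULT_DENOM_TOL):
    """Boundary-layer conductance from the dry/wet reference pair,
    mol m⁻² s⁻¹.

    Subtracting the steady-state energy balances of the dry and the
    one-side-wet AL (identical optics, shared shortwave load) leaves the
    wet reference's latent flux balanced against the pair's sensible and
    long-wave emission differences:

        λ·0.018·g_bw·(e_s(T_wet) − e_a)/P_atm
            = 2·ρ_air·C_p·0.92·g_bw·(R·T/P_atm)·(T_dry − T_wet)
              + σ·(T_dry⁴ − T_wet⁴)·(ε_B + ε_F)

    Both conductance-scaled terms are linear in g_bw; the g_bw-independent
    radiative difference pins its magnitude. Accepts scalars or aligned
    arrays.
    """
    T_dry = np.asarray(T_dry, dtype=float)
    T_wet = np.asarray(T_wet, dtype=float)
    if np.any(T_dry - T_wet < min_separation):
        raise ValueError(
            "T_dry must exceed T_wet by at least "
            f"{min_separation} K (got min separation "
            f"{float(np.min(T_dry - T_wet)):.4f} K)")
    air = moist_air_state(env)
    latent_per_g, sensible_per_g, radiative = _dry_wet_terms(
        T_dry, T_wet, env, surface, air)
    net = latent_per_g - sensible_per_g
    if np.any(net <= 0):
        raise ValueError(
            "non-physical dry/wet pair: latent cooling per unit conductance "
            "does not exceed the sensible exchange "
            f"(latent {float(np.min(latent_per_g)):.3g} <= sensible "
            f"{float(np.max(sensible_per_g)):.3g} J mol-1)")
    out = radiative / net
    return float(out) if out.ndim == 0 else out


def gbw_lysimetric(E, T_wet, env: EnvironmentState):
    """Boundary-layer conductance from gravimetric water loss of the wet
    reference, mol m⁻² s⁻¹.

    With the wet reference's surface conductance effectively infinite, the
    measured evaporation E (kg m⁻² s⁻¹) passes through g_bw alone:

        g_bw = E / (0.018·(e_s(T_wet) − e_a)/P_atm)
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("evaporation rate must be >= 0")
    air = moist_air_state(env)
    es_wet = saturation_vapor_pressure(T_wet)
    grad = es_wet - air.e_a
    if np.any(np.asarray(grad) <= 0):
        raise ValueError(
            "condensing conditions: e_s(T_wet) <= e_a, lysimetric inversion "
            "undefined")
    out = E / (CONSTANTS.M_w * grad / env.P_atm)
    return float(out) if out.ndim == 0 else out
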