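"""Psychrometric and radiative property computations shared by all modules.

All formulas operate on temperatures in kelvin and pressures in pascal.
Public helpers accept degrees Celsius where noted (thermal cameras and
environment loggers usually report °C); conversion happens at the boundary.

Saturation vapor pressure follows Buck (1981) over liquid water:

    e_s(T) = 611.21 exp(17.502 t / (240.97 + t))   [Pa],  t = T - 273.15 °C

The formula is isolated behind :func:`saturation_vapor_pressure` /
:func:`svp_slope` so it can be swapped without touching the energy-balance
or retrieval code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "EnvironmentState",
    "MoistAirState",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "saturation_vapor_pressure",
    "svp_slope",
    "moist_air_state",
    "conductance_ms_to_molar",
    "conductance_molar_to_ms",
    "radiative_conductance",
    "g_HR",
]

T_KELVIN_MIN = 243.0
T_KELVIN_MAX = 333.0

# Buck (1981) coefficients for liquid water, e_s in Pa, t in °C.
_BUCK_A = 611.21
_BUCK_B = 17.502
_BUCK_C = 240.97

#: fraction of g_bw that transfers sensible heat (heat vs water-vapor
#: diffusivity ratio for laminar boundary layers)
HEAT_TO_VAPOR_RATIO = 0.92


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and reference gas properties.

    Attributes
    ----------
    sigma : Stefan–Boltzmann constant, W m⁻² K⁻⁴.
    R_gas : universal gas constant, J mol⁻¹ K⁻¹.
    M_w : molar mass of water, kg mol⁻¹.
    M_air : molar mass of dry air, kg mol⁻¹.
    D_wv : diffusivity of water vapor in air at ~20 °C, m² s⁻¹.
    cp_dry : specific heat of dry air, J kg⁻¹ K⁻¹.
    ref_T, ref_P : reference state at which ``V_mol`` is evaluated.
    """

    sigma: float = 5.670374419e-8
    R_gas: float = 8.3145
    M_w: float = 0.018
    M_air: float = 0.028964
    D_wv: float = 2.4e-5
    cp_dry: float = 1005.0
    ref_T: float = 293.15
    ref_P: float = 101325.0
    V_mol: float = field(default=0.0)

    def __post_init__(self):
        if self.V_mol == 0.0:
            object.__setattr__(self, "V_mol", self.R_gas * self.ref_T / self.ref_P)
        for name in ("sigma", "R_gas", "M_w", "M_air", "D_wv", "cp_dry", "V_mol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be strictly positive")
        if not (1e-5 <= self.D_wv <= 4e-5):
            raise ValueError(f"D_wv={self.D_wv} outside plausible [1e-5, 4e-5] m2/s")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class EnvironmentState:
    """One timestamped microclimate record.

    Parameters
    ----------
    time : seconds since series start.
    T_air : air temperature, K.
    RH_air : relative humidity, fraction in [0, 1].
    P_atm : atmospheric pressure, Pa.
    wind : wind speed, m s⁻¹ (optional).
    PPFD : photosynthetic photon flux density, µmol m⁻² s⁻¹ (optional).
    R_ni : net isothermal radiation, W m⁻² (optional; derived when absent).
    """

    time: float
    T_air: float
    RH_air: float
    P_atm: float = 101325.0
    wind: float | None = None
    PPFD: float | None = None
    R_ni: float | None = None

    def __post_init__(self):
        if not (T_KELVIN_MIN <= self.T_air <= T_KELVIN_MAX):
            raise ValueError(
                f"T_air={self.T_air} K outside [{T_KELVIN_MIN}, {T_KELVIN_MAX}] K"
            )
        if not (0.0 <= self.RH_air <= 1.0):
            raise ValueError(f"RH_air={self.RH_air} outside [0, 1]")
        if not (5e4 <= self.P_atm <= 1.2e5):
            raise ValueError(f"P_atm={self.P_atm} Pa outside [5e4, 1.2e5] Pa")
        if self.wind is not None and self.wind < 0:
            raise ValueError(f"wind={self.wind} must be >= 0")
        if self.PPFD is not None and self.PPFD < 0:
            raise ValueError(f"PPFD={self.PPFD} must be >= 0")

    @classmethod
    def from_celsius(cls, time, T_air_C, RH_air, P_atm=101325.0, wind=None,
                     PPFD=None, R_ni=None) -> "EnvironmentState":
        return cls(time=time, T_air=float(T_air_C) + 273.15, RH_air=RH_air,
                   P_atm=P_atm, wind=wind, PPFD=PPFD, R_ni=R_ni)


@dataclass(frozen=True)
class MoistAirState:
    """Derived psychrometric state of humid air at (T_air, P_atm, RH_air).

    ``cp_molar`` is ρ_air·C_p·R·T_air/P_atm, the molar-basis heat capacity
    that converts a molar conductance directly into a sensible-heat
    conductance; the product is independent of the temperature used in the
    m s⁻¹ ↔ molar conversion as long as density is evaluated at the same
    temperature (ideal gas), which keeps forward simulation and boundary
    layer retrieval algebraically consistent.
    """

    T_air: float
    P_atm: float
    RH_air: float
    rho_air: float   # kg m-3
    Cp: float        # J kg-1 K-1
    cp_molar: float  # J mol-1 K-1
    lambda_v: float  # J kg-1
    gamma: float     # Pa K-1
    s_slope: float   # Pa K-1
    e_s_air: float   # Pa
    e_a: float       # Pa
    VPD: float       # Pa


def _check_T(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T < T_KELVIN_MIN) or np.any(T > T_KELVIN_MAX):
        bad = T[(T < T_KELVIN_MIN) | (T > T_KELVIN_MAX)]
        raise ValueError(
            f"temperature {np.atleast_1d(bad)[0]:.2f} K outside "
            f"[{T_KELVIN_MIN}, {T_KELVIN_MAX}] K"
        )
    return T


def saturation_vapor_pressure(T):
    """Saturation vapor pressure over liquid water, Pa (Buck 1981).

    Parameters
    ----------
    T : float or array, temperature in K (243–333 K).
    """
    T = _check_T(T)
    t = T - 273.15
    out = _BUCK_A * np.exp(_BUCK_B * t / (_BUCK_C + t))
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def svp_slope(T):
    """Analytic derivative de_s/dT of :func:`saturation_vapor_pressure`, Pa K⁻¹."""
    T = _check_T(T)
    t = T - 273.15
    es = _BUCK_A * np.exp(_BUCK_B * t / (_BUCK_C + t))
    out = es * _BUCK_B * _BUCK_C / (_BUCK_C + t) ** 2
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def latent_heat_vaporization(T) -> float:
    """Latent heat of vaporization of water, J kg⁻¹ (linear in T)."""
    return 2.501e6 - 2361.0 * (np.asarray(T, dtype=float) - 273.15)


def moist_air_state(env: EnvironmentState,
                    constants: PhysicalConstants = CONSTANTS) -> MoistAirState:
    """Psychrometric state of humid air for one environment record.

    Air density uses the moist-air correction (water vapor is lighter than
    dry air); C_p uses the specific-humidity correction to the dry-air
    value. Both corrections are <1 % at the humidities this method targets.
    """
    es = saturation_vapor_pressure(env.T_air)
    ea = env.RH_air * es
    vpd = es - ea
    # moist-air density: (P - 0.378 e) M_d / (R T)
    rho = (env.P_atm - (1.0 - constants.M_w / constants.M_air) * ea) \
        * constants.M_air / (constants.R_gas * env.T_air)
    q = 0.622 * ea / (env.P_atm - 0.378 * ea)  # specific humidity
    cp = constants.cp_dry * (1.0 + 0.84 * q)
    lam = float(latent_heat_vaporization(env.T_air))
    gamma = cp * env.P_atm / (0.622 * lam)
    cp_molar = rho * cp * constants.R_gas * env.T_air / env.P_atm
    return MoistAirState(
        T_air=env.T_air, P_atm=env.P_atm, RH_air=env.RH_air,
        rho_air=rho, Cp=cp, cp_molar=cp_molar, lambda_v=lam, gamma=gamma,
        s_slope=float(svp_slope(env.T_air)), e_s_air=float(es),
        e_a=float(ea), VPD=float(vpd),
    )


def conductance_ms_to_molar(g_ms, T, P_atm):
    """Convert a conductance from m s⁻¹ to mol m⁻² s⁻¹ via P/(R·T)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive for unit conversion")
    return np.asarray(g_ms, dtype=float) * np.asarray(P_atm, dtype=float) / (
        CONSTANTS.R_gas * T)


def conductance_molar_to_ms(g_mol, T, P_atm):
    """Convert a conductance from mol m⁻² s⁻¹ to m s⁻¹ via R·T/P."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive for unit conversion")
    return np.asarray(g_mol, dtype=float) * CONSTANTS.R_gas * T / np.asarray(
        P_atm, dtype=float)


def radiative_conductance(T_air: float, emissivity: float, air: MoistAirState,
                          constants: PhysicalConstants = CONSTANTS) -> float:
    """Radiative transfer conductance g_R, mol m⁻² s⁻¹.

    Linearized long-wave exchange: g_R = 4 ε σ T_air³ / (ρ_air C_p) in
    m s⁻¹, then converted to molar units at (T_air, P_atm).
    """
    if not (0.0 <= emissivity <= 1.0):
        raise ValueError(f"emissivity={emissivity} outside [0, 1]")
    g_ms = 4.0 * emissivity * constants.sigma * T_air ** 3 / (air.rho_air * air.Cp)
    return float(conductance_ms_to_molar(g_ms, T_air, air.P_atm))


def g_HR(g_bw: float, g_R: float) -> float:
    """Boundary-layer conductance to heat and radiative transfer.

    g_HR = 0.92·g_bw + g_R (all molar); 0.92 rescales the water-vapor
    boundary layer conductance to heat transfer.
    """
    if g_bw < 0 or g_R < 0:
        raise ValueError("conductances must be non-negative")
    return HEAT_TO_VAPOR_RATIO * g_bw + g_R
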