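"""Steady-state leaf energy-balance forward model and scenario simulator.

Simulates surface temperatures of artificial reference leaves (ALs) and real
leaves under scripted step-change environments. The model balances, per unit
one-sided area:

* absorbed shortwave on the upper face (α_sw × irradiance),
* net long-wave exchange of both faces against an effective radiant
  temperature (defaults to T_air; the measurement enclosure is
  near-isothermal),
* sensible heat from both faces through a heat conductance 0.92·g_bw per
  face,
* latent heat from the evaporating face(s), each face's surface conductance
  in series with that face's boundary layer.

The root of this balance in surface temperature is the simulated steady
temperature. The same flux expressions are inverted by the retrieval code,
so round-trip recovery of known conductances is the package's primary
correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .physics import (
    CONSTANTS,
    EnvironmentState,
    MoistAirState,
    PhysicalConstants,
    moist_air_state,
    saturation_vapor_pressure,
)

__all__ = [
    "SurfaceProperties",
    "LeafSample",
    "ScenarioStep",
    "TemperatureSeries",
    "SimulationConfig",
    "wind_to_gbw",
    "energy_balance_residual",
    "solve_surface_temperature",
    "simulate_reference_set",
    "scenario_environment",
    "standard_reference_set",
    "standard_target_al",
]

# Surface finishes of the artificial leaves: black electrical tape on the
# upper face (shortwave absorptance 0.96, long-wave emissivity 0.97), filter
# paper (0.95) or perforated polyethylene film (0.97) on the lower face.
TAPE_EMISSIVITY = 0.97
TAPE_ABSORPTANCE = 0.96
FILTER_PAPER_EMISSIVITY = 0.95
FILM_EMISSIVITY = 0.97


@dataclass(frozen=True)
class SurfaceProperties:
    """Optical properties of one leaf: shortwave absorptance of the upper
    face and long-wave emissivity of each face (fractions in (0, 1])."""

    alpha_sw: float
    eps_top: float
    eps_bottom: float

    def __post_init__(self):
        for name in ("alpha_sw", "eps_top", "eps_bottom"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} must be in (0, 1]")


AL_SURFACE = SurfaceProperties(alpha_sw=TAPE_ABSORPTANCE,
                               eps_top=TAPE_EMISSIVITY,
                               eps_bottom=FILTER_PAPER_EMISSIVITY)
POROUS_AL_SURFACE = SurfaceProperties(alpha_sw=TAPE_ABSORPTANCE,
                                      eps_top=TAPE_EMISSIVITY,
                                      eps_bottom=FILM_EMISSIVITY)


@dataclass(frozen=True)
class LeafSample:
    """One real or artificial leaf in the thermal camera's field of view.

    Roles
    -----
    dry : non-transpiring reference (no evaporating face).
    wet : freely evaporating reference, wetted on the bottom face only.
    porous : AL with fixed pore conductance ``g_pw`` evaporating from the
        bottom face through a perforated film.
    real : a leaf with unknown stomatal conductance; ``g_sw_true`` is the
        simulator input, ``SR`` the adaxial:abaxial stomatal density ratio.
    """

    id: str
    role: str
    surface: SurfaceProperties
    g_pw: float | None = None
    g_sw_true: float | None = None
    SR: float | None = None
    evaporating_faces: str = ""

    def __post_init__(self):
        if self.role not in ("dry", "wet", "porous", "real"):
            raise ValueError(f"unknown role {self.role!r}")
        faces = self.evaporating_faces
        if not faces:
            faces = {"dry": "none", "wet": "bottom", "porous": "bottom",
                     "real": "both"}[self.role]
            object.__setattr__(self, "evaporating_faces", faces)
        if faces not in ("none", "bottom", "both"):
            raise ValueError(f"unknown evaporating_faces {faces!r}")
        if self.role == "dry" and (faces != "none" or self.g_pw is not None):
            raise ValueError("dry reference must not evaporate")
        if self.role == "wet" and faces != "bottom":
            raise ValueError("wet reference evaporates from the bottom face only")
        if self.role == "porous":
            if self.g_pw is None or self.g_pw <= 0:
                raise ValueError("porous AL requires g_pw > 0")
            if faces != "bottom":
                raise ValueError("porous AL evaporates from the bottom face only")
        if self.role == "real":
            if self.SR is None or self.SR < 0:
                raise ValueError("real leaf requires stomatal ratio SR >= 0")


@dataclass(frozen=True)
class ScenarioStep:
    """One constant-environment segment of a step-change protocol."""

    duration: float           # s
    wind: float               # m s-1
    PPFD: float = 0.0         # umol m-2 s-1
    T_air: float = 293.15     # K
    RH_air: float = 0.40      # fraction
    P_atm: float = 101325.0   # Pa
    noise_sd: float = 0.03    # K, camera noise (NETD-scale)

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("step duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TemperatureSeries:
    """Aligned per-object temperature kinetics.

    ``temperatures`` is (n_times, n_objects) in kelvin; ``quality`` holds
    'ok' / 'missing' / 'out_of_bounds' per record.
    """

    times: np.ndarray
    object_ids: list
    temperatures: np.ndarray
    quality: np.ndarray = None
    roles: dict = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.shape != (self.times.size, len(self.object_ids)):
            raise ValueError("temperatures must be (n_times, n_objects)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.quality is None:
            self.quality = np.full(self.temperatures.shape, "ok", dtype=object)

    def column(self, object_id: str) -> np.ndarray:
        return self.temperatures[:, self.object_ids.index(object_id)]

    def to_frame(self):
        """Tidy DataFrame: time_s, object_id, role, temperature_C, quality."""
        import pandas as pd

        n_t, n_o = self.temperatures.shape
        roles = self.roles or {}
        return pd.DataFrame({
            "time_s": np.repeat(self.times, n_o),
            "object_id": np.tile(np.asarray(self.object_ids, dtype=object), n_t),
            "role": [roles.get(o, "") for _ in range(n_t) for o in self.object_ids],
            "temperature_C": (self.temperatures - 273.15).ravel(),
            "quality": self.quality.ravel(),
        })


@dataclass(frozen=True)
class SimulationConfig:
    """Tunables of the radiative and aerodynamic environment.

    ``ppfd_to_wm2`` converts PPFD to shortwave irradiance (W m⁻² per
    µmol m⁻² s⁻¹; 0.22 suits a red/blue/white LED spectrum). ``T_rad``
    overrides the effective radiant temperature (None → T_air).
    ``char_length`` is the characteristic dimension for the boundary layer
    (m); ``g_free`` the free-convection floor of g_bw (mol m⁻² s⁻¹).
    """

    ppfd_to_wm2: float = 0.22
    T_rad: float | None = None
    char_length: float = 0.04
    g_free: float = 0.05
    constants: PhysicalConstants = field(default=CONSTANTS)


DEFAULT_CONFIG = SimulationConfig()

_BRACKET_BELOW = 20.0
_BRACKET_ABOVE = 30.0
_SOLVER_XTOL = 1e-8


def wind_to_gbw(wind: float, characteristic_length: float = 0.04,
                g_free: float = 0.05) -> float:
    """One-sided boundary-layer conductance to water vapor from wind speed.

    Forced-convection flat-plate relation g_bw ≈ 0.147·√(u/d) mol m⁻² s⁻¹
    (laminar, d in m) on top of a constant free-convection floor that keeps
    still air from shutting off exchange entirely.
    """
    if wind < 0:
        raise ValueError("wind must be >= 0")
    if characteristic_length <= 0:
        raise ValueError("characteristic_length must be positive")
    return g_free + 0.147 * np.sqrt(wind / characteristic_length)


def _face_conductances(sample: LeafSample, g_bw: float):
    """Surface conductance of each evaporating face (top, bottom); None if
    that face does not evaporate, inf for a free water surface."""
    if sample.role == "dry" or sample.evaporating_faces == "none":
        return None, None
    if sample.role == "wet":
        return None, np.inf
    if sample.role == "porous":
        return None, sample.g_pw
    # real leaf: partition g_sw across faces by the stomatal ratio
    sr = sample.SR
    g = sample.g_sw_true
    if g is None:
        raise ValueError(f"sample {sample.id}: real leaf needs g_sw_true to simulate")
    top = g * sr / (sr + 1.0)
    bottom = g / (sr + 1.0)
    if sample.evaporating_faces == "bottom":
        return None, g
    return (top if top > 0 else None), (bottom if bottom > 0 else None)


def _series(g_surf: float, g_bw: float) -> float:
    if np.isinf(g_surf):
        return g_bw
    return g_surf * g_bw / (g_surf + g_bw)


def energy_balance_residual(T_surf, sample: LeafSample, env: EnvironmentState,
                            g_bw: float, air: MoistAirState,
                            config: SimulationConfig = DEFAULT_CONFIG):
    """Net energy flux into the surface at temperature ``T_surf``, W m⁻².

    Zero exactly at the steady-state temperature; strictly decreasing in
    ``T_surf`` near the root (warmer surface sheds more heat). Accepts a
    scalar or array ``T_surf``.
    """
    c = config.constants
    T = np.asarray(T_surf, dtype=float)
    T_rad = config.T_rad if config.T_rad is not None else env.T_air
    sw = sample.surface.alpha_sw * config.ppfd_to_wm2 * (env.PPFD or 0.0)
    eps_sum = sample.surface.eps_top + sample.surface.eps_bottom
    lw = eps_sum * c.sigma * (T_rad ** 4 - T ** 4)
    sensible = 2.0 * 0.92 * g_bw * air.cp_molar * (T - env.T_air)
    latent = np.zeros_like(T)
    es_T = None
    for g_surf in _face_conductances(sample, g_bw):
        if g_surf is None:
            continue
        if es_T is None:
            es_T = saturation_vapor_pressure(np.clip(T, 243.0, 333.0))
        g_tot = _series(g_surf, g_bw)
        E = c.M_w * g_tot * (es_T - air.e_a) / env.P_atm  # kg m-2 s-1
        latent = latent + air.lambda_v * E
    out = sw + lw - sensible - latent
    return float(out) if out.ndim == 0 else out


def solve_surface_temperature(sample: LeafSample, env: EnvironmentState,
                              g_bw: float,
                              config: SimulationConfig = DEFAULT_CONFIG,
                              air: MoistAirState | None = None) -> float:
    """Steady-state surface temperature, K (bracketed Brent root).

    The bracket [T_air − 20, T_air + 30] K covers all realistic indoor
    setups; a missing sign change raises with both bracket residuals.
    """
    if air is None:
        air = moist_air_state(env, config.constants)
    lo, hi = env.T_air - _BRACKET_BELOW, env.T_air + _BRACKET_ABOVE

    def f(T):
        return energy_balance_residual(T, sample, env, g_bw, air, config)

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no steady state for {sample.id!r} in [{lo:.1f}, {hi:.1f}] K: "
            f"residuals {flo:.3g} / {fhi:.3g} W m-2"
        )
    return brentq(f, lo, hi, xtol=_SOLVER_XTOL)


def scenario_environment(scenario: list[ScenarioStep],
                         sampling_dt: float) -> list[EnvironmentState]:
    """Environment record at each sample time of a step-change protocol."""
    if sampling_dt <= 0:
        raise ValueError("sampling_dt must be positive")
    out, t0 = [], 0.0
    for step in scenario:
        times = np.arange(t0 + sampling_dt, t0 + step.duration + sampling_dt / 2,
                          sampling_dt)
        for t in times:
            out.append(EnvironmentState(time=float(t), T_air=step.T_air,
                                        RH_air=step.RH_air, P_atm=step.P_atm,
                                        wind=step.wind, PPFD=step.PPFD))
        t0 += step.duration
    return out


def simulate_reference_set(samples: list[LeafSample],
                           scenario: list[ScenarioStep],
                           sampling_dt: float = 1.0,
                           seed: int | None = None,
                           config: SimulationConfig = DEFAULT_CONFIG,
                           ) -> TemperatureSeries:
    """Simulate temperature kinetics of a set of leaves under a protocol.

    Per step, each sample's steady-state temperature is solved once for the
    step's environment (the model is steady-state: within-step kinetics are
    flat apart from seeded Gaussian camera noise of SD ``noise_sd``).
    Requires the sample set to include the dry and wet references.
    """
    roles = {s.role for s in samples}
    if not {"dry", "wet"} <= roles:
        raise ValueError("sample set must include dry and wet references")
    ids = [s.id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    rng = np.random.default_rng(seed)
    all_times, all_temps = [], []
    t0 = 0.0
    for step in scenario:
        env = EnvironmentState(time=t0, T_air=step.T_air, RH_air=step.RH_air,
                               P_atm=step.P_atm, wind=step.wind, PPFD=step.PPFD)
        air = moist_air_state(env, config.constants)
        g_bw = wind_to_gbw(step.wind, config.char_length, config.g_free)
        try:
            steady = np.array([
                solve_surface_temperature(s, env, g_bw, config, air)
                for s in samples
            ])
        except RuntimeError as err:
            raise RuntimeError(f"at t={t0:.1f} s: {err}") from err
        times = np.arange(t0 + sampling_dt, t0 + step.duration + sampling_dt / 2,
                          sampling_dt)
        temps = np.tile(steady, (times.size, 1))
        if step.noise_sd > 0:
            temps = temps + rng.normal(0.0, step.noise_sd, temps.shape)
        all_times.append(times)
        all_temps.append(temps)
        t0 += step.duration
    return TemperatureSeries(
        times=np.concatenate(all_times),
        object_ids=ids,
        temperatures=np.vstack(all_temps),
        roles={s.id: s.role for s in samples},
    )


def standard_reference_set(g_pw_low: float = 0.10, g_pw_medium: float = 0.20,
                           g_pw_high: float = 0.29) -> list[LeafSample]:
    """The five-AL reference set: dry + wet + three porous films.

    Default pore conductances are the gas-exchange characterization of the
    low/medium/high films (mol m⁻² s⁻¹).
    """
    return [
        LeafSample(id="dry", role="dry", surface=AL_SURFACE),
        LeafSample(id="wet", role="wet", surface=AL_SURFACE),
        LeafSample(id="low", role="porous", surface=POROUS_AL_SURFACE,
                   g_pw=g_pw_low),
        LeafSample(id="medium", role="porous", surface=POROUS_AL_SURFACE,
                   g_pw=g_pw_medium),
        LeafSample(id="high", role="porous", surface=POROUS_AL_SURFACE,
                   g_pw=g_pw_high),
    ]


def standard_target_al(g_pw: float = 0.31, id: str = "target") -> LeafSample:
    """A target AL built like the 'high' reference (benchmark conductance
    0.31 mol m⁻² s⁻¹ by gas exchange)."""
    return LeafSample(id=id, role="porous", surface=POROUS_AL_SURFACE, g_pw=g_pw)
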