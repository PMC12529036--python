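"""The DynG retrieval: dynamic calibration of the conductance index.

The conductance index I_g = (T_dry − T_leaf)/(T_leaf − T_wet) is linearly
related to conductance, I_g = g·G, but the scaling G drifts with wind,
temperature and humidity. DynG re-estimates G continuously as the slope of
I_g against the known pore conductances of at least three porous artificial
leaves imaged alongside the targets, so the I_g → conductance mapping tracks
the current microclimate.

Retrieval chain per timepoint:

1. I_g of every porous AL and target (refleaves.conductance_index);
2. g_bw from the dry/wet pair (refleaves.gbw_from_dry_wet);
3. DynG = through-origin slope of I_g vs g_pw (fit_dyng);
4. total conductance g_tw = 1/(DynG/I_g + 1/g_bw)   — series resistances;
5. stomatal conductance g_sw from g_tw via the two-sided stomatal-ratio
   inversion (gsw_from_gtw), which reduces to the closed form
   g_sw = 2·I_g·g_bw/(I_g + 2·DynG·g_bw) at SR = 1 and to the single-face
   series inversion at SR = 0 (one-sided evaporators such as ALs);
6. transpiration E = 0.018·(g_bw·g_sw/(g_bw + g_sw))·(e_s(T_leaf) − e_a)/P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .physics import (
    CONSTANTS,
    EnvironmentState,
    moist_air_state,
    saturation_vapor_pressure,
    svp_slope,
    latent_heat_vaporization,
)
from .ebalance import (
    DEFAULT_CONFIG,
    LeafSample,
    SimulationConfig,
    SurfaceProperties,
    TemperatureSeries,
    energy_balance_residual,
)
from .refleaves import DEFAULT_DENOM_TOL, conductance_index_series
from .ebalance import AL_SURFACE

__all__ = [
    "DynGFit",
    "ConductanceEstimate",
    "PipelineOptions",
    "fit_dyng",
    "gtw_from_ig",
    "gsw_from_gtw",
    "gsw_sr1",
    "gsw_ig_only",
    "gsw_full_energy_balance",
    "transpiration",
    "sensitivity_analysis",
    "estimate_pipeline",
]


@dataclass(frozen=True)
class DynGFit:
    """One calibration fit of I_g against the reference pore conductances."""

    slope: float
    intercept: float
    r2: float
    n_points: int
    time: float = 0.0
    window: float = 0.0
    valid: bool = True


@dataclass(frozen=True)
class ConductanceEstimate:
    """Retrieved conductances and transpiration for one object/timepoint.

    E is stored in SI (kg m⁻² s⁻¹); convenience properties report the field
    units g m⁻² s⁻¹ and mmol m⁻² s⁻¹.
    """

    time: float
    object_id: str
    method: str
    g_bw: float
    g_R: float
    g_HR: float
    g_tw: float
    g_sw: float
    E: float
    Ig: float = np.nan
    dyng: float = np.nan
    quality: str = "ok"

    @property
    def E_g_m2_s(self) -> float:
        return self.E * 1e3

    @property
    def E_mmol_m2_s(self) -> float:
        return self.E / CONSTANTS.M_w * 1e3


def fit_dyng(points, through_origin: bool = True, valid=None,
             time: float = 0.0, window: float = 0.0) -> DynGFit:
    """Least-squares DynG slope from (g_pw, I_g) pairs.

    ``points`` is a sequence of (g_pw, Ig) pairs or a (n, 2) array. The
    default is regression through the origin (the calibration line has no
    intercept: a leaf at the dry reference's temperature has zero
    conductance); ``through_origin=False`` adds an intercept for
    diagnostics. Flagged pairs (``valid`` mask) are dropped; fewer than two
    usable points invalidates the fit, fewer than three draws a warning
    because the calibration is then unconstrained against curvature.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): columns g_pw, Ig")
    mask = np.isfinite(pts).all(axis=1)
    if valid is not None:
        mask &= np.asarray(valid, dtype=bool)
    x, y = pts[mask, 0], pts[mask, 1]
    if x.size < 2 or np.unique(x).size < (1 if through_origin else 2):
        return DynGFit(slope=np.nan, intercept=np.nan, r2=np.nan,
                       n_points=int(x.size), time=time, window=window,
                       valid=False)
    if x.size < 3:
        warnings.warn(
            f"DynG fit with only {x.size} artificial leaves; at least three "
            "are recommended", stacklevel=2)
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    resid = y - (slope * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return DynGFit(slope=slope, intercept=intercept, r2=r2,
                   n_points=int(x.size), time=time, window=window,
                   valid=slope > 0)


def gtw_from_ig(Ig, fit: DynGFit, g_bw):
    """Total conductance to water vapor from the conductance index.

    g_tw = 1/(DynG/I_g + 1/g_bw): the calibrated index reads the surface
    conductance, which adds in series with the boundary layer.
    Non-positive I_g returns 0.
    """
    if fit.slope <= 0 or not np.isfinite(fit.slope):
        raise ValueError("DynG fit has non-positive slope")
    Ig = np.asarray(Ig, dtype=float)
    g_bw = np.asarray(g_bw, dtype=float)
    if np.any(g_bw <= 0):
        raise ValueError("g_bw must be positive")
    with np.errstate(divide="ignore"):
        out = np.where(Ig > 0, 1.0 / (fit.slope / Ig + 1.0 / g_bw), 0.0)
    return float(out) if out.ndim == 0 else out


def gsw_from_gtw(g_tw, g_bw, SR: float = 1.0, clip_ceiling: bool = False):
    """Stomatal conductance from total conductance for any stomatal ratio.

    Two-sided inversion (as used by the LI-6800 gas-exchange system): with
    a = 1/g_tw − 1/g_bw,

        g_sw = 2 / (a + √(a² + 4·SR/(SR+1)²·(2/g_tw − 1/g_bw)·(1/g_bw)))

    At SR = 1 this reduces to the closed form of :func:`gsw_sr1`; at SR = 0
    (all stomata on one face, matching the one-sided AL design) it reduces
    to the single-face series inversion 1/g_sw = 1/g_tw − 1/g_bw.

    ``g_tw >= g_bw`` is non-physical (total conductance cannot exceed the
    boundary-layer limit): raises unless ``clip_ceiling``, which returns
    the 2·g_bw ceiling so noisy series keep their continuity.
    """
    if SR < 0:
        raise ValueError("SR must be >= 0")
    g_tw = np.asarray(g_tw, dtype=float)
    g_bw = np.asarray(g_bw, dtype=float)
    bad = g_tw >= g_bw
    if np.any(bad):
        if not clip_ceiling:
            raise ValueError(
                "g_tw >= g_bw: total conductance exceeds the boundary-layer "
                "limit")
        g_tw = np.where(bad, np.nan, g_tw)
    with np.errstate(invalid="ignore"):
        a = 1.0 / g_tw - 1.0 / g_bw
        disc = a ** 2 + 4.0 * SR / (SR + 1.0) ** 2 * (
            2.0 / g_tw - 1.0 / g_bw) / g_bw
        out = 2.0 / (a + np.sqrt(disc))
        out = np.where(g_tw == 0, 0.0, out)
    if np.any(bad):
        out = np.where(bad, 2.0 * g_bw, out)
    return float(out) if out.ndim == 0 else out


def gsw_sr1(Ig, fit: DynGFit, g_bw):
    """Closed-form stomatal conductance for amphistomatous leaves (SR = 1):

        g_sw = 2·I_g·g_bw / (I_g + 2·DynG·g_bw)
    """
    if fit.slope <= 0 or not np.isfinite(fit.slope):
        raise ValueError("DynG fit has non-positive slope")
    Ig = np.asarray(Ig, dtype=float)
    g_bw = np.asarray(g_bw, dtype=float)
    if np.any(g_bw <= 0):
        raise ValueError("g_bw must be positive")
    out = np.where(Ig > 0,
                   2.0 * Ig * g_bw / (Ig + 2.0 * fit.slope * g_bw), 0.0)
    return float(out) if out.ndim == 0 else out


def gsw_ig_only(Ig):
    """Legacy baseline: the conductance index itself read as a conductance
    (g_sw := I_g). Biased whenever the microclimate drifts; provided for
    comparison against the calibrated estimate."""
    out = np.asarray(Ig, dtype=float)
    if np.any(out < 0):
        raise ValueError("Ig must be >= 0")
    return float(out) if out.ndim == 0 else out


_GSW_MAX = 50.0


def gsw_full_energy_balance(T_leaf: float, env: EnvironmentState, g_bw: float,
                            surface: SurfaceProperties, SR: float = 1.0,
                            config: SimulationConfig = DEFAULT_CONFIG) -> float:
    """Stomatal conductance by full energy-balance inversion, mol m⁻² s⁻¹.

    Finds the g_sw at which the steady-state energy balance closes at the
    observed leaf temperature, given the microclimate and radiation load
    (``env.R_ni`` if supplied, otherwise shortwave from ``env.PPFD`` and
    long-wave against the configured radiant temperature). Requires more
    environmental inputs than the DynG route; kept as an independent
    cross-check.
    """
    air = moist_air_state(env, config.constants)

    if env.R_ni is not None:
        c = config.constants
        eps_sum = surface.eps_top + surface.eps_bottom

        def residual(g):
            sample = LeafSample(id="_inv", role="real", surface=surface,
                                g_sw_true=g, SR=SR)
            lat_sens = energy_balance_residual(
                T_leaf, sample, env, g_bw, air, config)
            # replace the model's radiation terms with the supplied R_ni
            sw = surface.alpha_sw * config.ppfd_to_wm2 * (env.PPFD or 0.0)
            T_rad = config.T_rad if config.T_rad is not None else env.T_air
            lw = eps_sum * c.sigma * (T_rad ** 4 - T_leaf ** 4)
            iso = env.R_ni + eps_sum * c.sigma * (env.T_air ** 4 - T_leaf ** 4)
            return lat_sens - sw - lw + iso
    else:
        def residual(g):
            sample = LeafSample(id="_inv", role="real", surface=surface,
                                g_sw_true=g, SR=SR)
            return energy_balance_residual(T_leaf, sample, env, g_bw, air,
                                           config)

    f0 = residual(0.0)
    if f0 <= 0.0:
        # leaf at (or above) the non-transpiring equilibrium temperature
        return 0.0
    fmax = residual(_GSW_MAX)
    if fmax > 0.0:
        raise ValueError(
            f"leaf colder than achievable by evaporation alone "
            f"(residual {fmax:.3g} W m-2 at g_sw={_GSW_MAX})")
    return brentq(residual, 0.0, _GSW_MAX, xtol=1e-10, rtol=1e-12)


def transpiration(g_sw, g_bw, T_leaf, env: EnvironmentState):
    """Transpiration rate, kg m⁻² s⁻¹:

        E = 0.018·(g_bw·g_sw/(g_bw + g_sw))·(e_s(T_leaf) − e_a)/P_atm

    with e_s at leaf temperature (leaf-internal saturation). Condensing
    conditions (e_s(T_leaf) < e_a) return 0.
    """
    g_sw = np.asarray(g_sw, dtype=float)
    g_bw = np.asarray(g_bw, dtype=float)
    if np.any(g_sw < 0) or np.any(g_bw < 0):
        raise ValueError("conductances must be >= 0")
    air = moist_air_state(env)
    es_leaf = saturation_vapor_pressure(T_leaf)
    grad = np.maximum(es_leaf - air.e_a, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_tot = np.where(g_sw + g_bw > 0, g_bw * g_sw / (g_bw + g_sw), 0.0)
    out = CONSTANTS.M_w * g_tot * grad / env.P_atm
    return float(out) if out.ndim == 0 else out


def sensitivity_analysis(Ig: float, dyng: float, g_bw: float, SR: float = 1.0,
                         gbw_perturb=(-0.5, 0.5),
                         SR_range=(0.5, 0.75, 1.0, 1.25, 1.5)) -> pd.DataFrame:
    """Signed relative change of g_sw under g_bw and SR perturbations.

    The g_bw sweep recomputes the SR = 1 closed form with perturbed g_bw;
    the SR sweep re-runs the two-sided inversion on the same g_tw. Returns
    a tidy table (parameter, perturbation, g_sw, rel_change).
    """
    fit = DynGFit(slope=dyng, intercept=0.0, r2=1.0, n_points=3)
    base = gsw_sr1(Ig, fit, g_bw) if SR == 1.0 else gsw_from_gtw(
        gtw_from_ig(Ig, fit, g_bw), g_bw, SR)
    rows = []
    for p in gbw_perturb:
        g = gsw_sr1(Ig, fit, g_bw * (1.0 + p)) if SR == 1.0 else gsw_from_gtw(
            gtw_from_ig(Ig, fit, g_bw * (1.0 + p)), g_bw * (1.0 + p), SR)
        rows.append(("g_bw", p, g, (g - base) / base))
    g_tw = gtw_from_ig(Ig, fit, g_bw)
    for sr in SR_range:
        g = gsw_from_gtw(g_tw, g_bw, sr)
        rows.append(("SR", sr, g, (g - base) / base))
    return pd.DataFrame(rows,
                        columns=["parameter", "perturbation", "g_sw",
                                 "rel_change"])


# ---------------------------------------------------------------------------
# pipeline

@dataclass(frozen=True)
class PipelineOptions:
    """Knobs of :func:`estimate_pipeline`.

    window_s : rolling-median smoothing window applied to each object's
        temperature trace before any index is formed (tames camera noise).
    SR : stomatal ratio applied to targets whose sample carries none.
    target_ids : objects to retrieve; defaults to every 'real' sample plus
        any porous sample not used in the calibration fit.
    methods : estimates to emit; 'dyng' and/or 'ig_only'.
    """

    window_s: float = 30.0
    denom_tol: float = DEFAULT_DENOM_TOL
    through_origin: bool = True
    SR: float = 1.0
    target_ids: tuple = ()
    reference_ids: tuple = ()
    methods: tuple = ("dyng",)
    surface: SurfaceProperties = field(default=AL_SURFACE)


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    return (pd.DataFrame(values)
            .rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def _vector_air(T_air, RH, P):
    """Vectorized psychrometrics over aligned environment arrays; returns a
    duck-typed object with the fields the flux formulas use."""
    es = saturation_vapor_pressure(T_air)
    ea = RH * es
    lam = latent_heat_vaporization(T_air)
    c = CONSTANTS
    rho = (P - (1.0 - c.M_w / c.M_air) * ea) * c.M_air / (c.R_gas * T_air)
    q = 0.622 * ea / (P - 0.378 * ea)
    cp = c.cp_dry * (1.0 + 0.84 * q)

    class _Air:
        pass

    air = _Air()
    air.e_s_air = es
    air.e_a = ea
    air.lambda_v = lam
    air.rho_air = rho
    air.Cp = cp
    air.cp_molar = rho * cp * c.R_gas * T_air / P
    air.s_slope = svp_slope(T_air)
    return air


def estimate_pipeline(series: TemperatureSeries,
                      env_series: list[EnvironmentState],
                      samples: list[LeafSample],
                      options: PipelineOptions | None = None) -> pd.DataFrame:
    """Run the full DynG retrieval over an aligned temperature series.

    Per timepoint: I_g of every porous AL and target, g_bw from the
    dry/wet pair, the DynG calibration slope, then each target's g_tw,
    g_sw and E. Quality flags propagate end-to-end instead of raising, so
    transients and noise bursts do not sever the series.

    Returns a tidy DataFrame with one row per (timepoint, target, method):
    time_s, object_id, method, g_bw, DynG, r2, Ig, g_tw, g_sw,
    E_g_m2_s, quality.
    """
    opts = options or PipelineOptions()
    if series.times.size == 0:
        raise ValueError("empty temperature series")
    if not env_series:
        raise ValueError("empty environment series")
    by_id = {s.id: s for s in samples}
    missing = [s.id for s in samples if s.id not in series.object_ids]
    if missing:
        raise ValueError(f"samples absent from series: {missing}")

    dry = [s for s in samples if s.role == "dry"]
    wet = [s for s in samples if s.role == "wet"]
    porous = [s for s in samples if s.role == "porous"]
    if opts.target_ids:
        target_ids = list(opts.target_ids)
    else:
        target_ids = [s.id for s in samples if s.role == "real"]
        if opts.reference_ids:
            target_ids += [s.id for s in porous
                           if s.id not in opts.reference_ids]
    if opts.reference_ids:
        refs = [s for s in porous if s.id in opts.reference_ids]
    else:
        refs = [s for s in porous if s.id not in target_ids]
    absent = []
    if not dry:
        absent.append("dry")
    if not wet:
        absent.append("wet")
    if len(refs) < 3:
        absent.append(f"porous references (found {len(refs)}, need 3)")
    if not target_ids:
        absent.append("target")
    if absent:
        raise ValueError(f"pipeline requires missing roles: {absent}")

    # --- smoothing and alignment
    dt = float(np.median(np.diff(series.times))) if series.times.size > 1 else 1.0
    window = max(1, int(round(opts.window_s / dt)))
    temps = _rolling_median(series.temperatures, window)
    col = {oid: temps[:, series.object_ids.index(oid)]
           for oid in series.object_ids}

    env_t = np.array([e.time for e in env_series])
    idx = np.clip(np.searchsorted(env_t, series.times), 0, env_t.size - 1)
    left = np.clip(idx - 1, 0, env_t.size - 1)
    idx = np.where(np.abs(env_t[left] - series.times)
                   <= np.abs(env_t[idx] - series.times), left, idx)
    T_air = np.array([env_series[i].T_air for i in idx])
    RH = np.array([env_series[i].RH_air for i in idx])
    P = np.array([env_series[i].P_atm for i in idx])
    air = _vector_air(T_air, RH, P)

    T_dry, T_wet = col[dry[0].id], col[wet[0].id]

    # --- g_bw from the dry/wet pair (vectorized; failures flagged)
    eps_sum = opts.surface.eps_top + opts.surface.eps_bottom
    radiative = CONSTANTS.sigma * (T_dry ** 4 - T_wet ** 4) * eps_sum
    es_wet = saturation_vapor_pressure(np.clip(T_wet, 243.0, 333.0))
    latent_per_g = air.lambda_v * CONSTANTS.M_w * (es_wet - air.e_a) / P
    sensible_per_g = 2.0 * 0.92 * air.cp_molar * (T_dry - T_wet)
    net = latent_per_g - sensible_per_g
    gbw_ok = (T_dry - T_wet >= opts.denom_tol) & (net > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_bw = np.where(gbw_ok, radiative / np.where(gbw_ok, net, 1.0), np.nan)

    g_R = 4.0 * eps_sum / 2.0 * CONSTANTS.sigma * T_air ** 3 / air.cp_molar
    g_HR_arr = 0.92 * g_bw + g_R

    # --- DynG calibration per timepoint
    ref_gpw = np.array([s.g_pw for s in refs])
    ig_ref = np.empty((series.times.size, len(refs)))
    ok_ref = np.empty_like(ig_ref, dtype=bool)
    for j, s in enumerate(refs):
        ig_ref[:, j], ok_ref[:, j] = conductance_index_series(
            col[s.id], T_dry, T_wet, opts.denom_tol)
    w = ok_ref.astype(float)
    y = np.where(ok_ref, ig_ref, 0.0)
    if opts.through_origin:
        sxx = (w * ref_gpw ** 2).sum(axis=1)
        sxy = (y * ref_gpw).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(sxx > 0, sxy / sxx, np.nan)
        intercept = np.zeros_like(slope)
    else:
        n = w.sum(axis=1)
        sx = (w * ref_gpw).sum(axis=1)
        sy = y.sum(axis=1)
        sxx = (w * ref_gpw ** 2).sum(axis=1)
        sxy = (y * ref_gpw).sum(axis=1)
        det = n * sxx - sx ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (n * sxy - sx * sy) / det
            intercept = (sy - slope * sx) / n
    n_valid = ok_ref.sum(axis=1)
    pred = slope[:, None] * ref_gpw[None, :] + intercept[:, None]
    ss_res = (w * (ig_ref - pred) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.where(n_valid > 0, y.sum(axis=1) / np.maximum(n_valid, 1), 0.0)
        ss_tot = (w * (ig_ref - ybar[:, None]) ** 2).sum(axis=1)
        r2 = np.clip(np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0), 0.0, 1.0)
    fit_ok = (n_valid >= 2) & np.isfinite(slope) & (slope > 0)

    # --- per-target retrieval
    out = []
    for tid in target_ids:
        sample = by_id.get(tid)
        sr = (sample.SR if sample is not None and sample.SR is not None
              else (0.0 if sample is not None and sample.role == "porous"
                    else opts.SR))
        T_leaf = col[tid]
        ig, ig_ok = conductance_index_series(T_leaf, T_dry, T_wet,
                                             opts.denom_tol)
        usable = ig_ok & fit_ok & gbw_ok
        with np.errstate(divide="ignore", invalid="ignore"):
            g_tw = np.where(usable & (ig > 0),
                            1.0 / (slope / ig + 1.0 / g_bw), 0.0)
        ceiling = usable & (g_tw >= g_bw)
        g_tw_safe = np.where(ceiling, np.nan, g_tw)
        es_leaf = saturation_vapor_pressure(np.clip(T_leaf, 243.0, 333.0))
        vp_grad = np.maximum(es_leaf - air.e_a, 0.0)

        def _E(g_sw):
            with np.errstate(divide="ignore", invalid="ignore"):
                g_tot = g_bw * g_sw / (g_bw + g_sw)
            return CONSTANTS.M_w * np.where(np.isfinite(g_tot), g_tot, 0.0) \
                * vp_grad / P

        if "dyng" in opts.methods:
            g_sw = gsw_from_gtw(np.where(usable, g_tw_safe, np.nan), g_bw,
                                SR=sr, clip_ceiling=True)
            g_sw = np.where(ceiling, 2.0 * g_bw, g_sw)
            quality = np.where(usable,
                               np.where(ceiling, "ceiling", "ok"),
                               "invalid")
            out.append(pd.DataFrame({
                "time_s": series.times, "object_id": tid, "method": "dyng",
                "g_bw": g_bw, "g_R": g_R, "g_HR": g_HR_arr,
                "DynG": slope, "r2": r2, "Ig": ig, "g_tw": g_tw,
                "g_sw": g_sw, "E_kg_m2_s": _E(g_sw), "quality": quality,
            }))
        if "ig_only" in opts.methods:
            g_sw_ig = np.where(ig_ok, np.maximum(ig, 0.0), np.nan)
            out.append(pd.DataFrame({
                "time_s": series.times, "object_id": tid, "method": "ig_only",
                "g_bw": g_bw, "g_R": g_R, "g_HR": g_HR_arr,
                "DynG": slope, "r2": r2, "Ig": ig, "g_tw": np.nan,
                "g_sw": g_sw_ig, "E_kg_m2_s": _E(g_sw_ig),
                "quality": np.where(ig_ok, "ok", "invalid"),
            }))

    result = pd.concat(out, ignore_index=True)
    result["E_g_m2_s"] = result["E_kg_m2_s"] * 1e3
    return result
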