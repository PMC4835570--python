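"""Trace-gas flux estimation from microcosm headspace time series.

Soil microcosms act as a net sink for atmospheric H2 and CO (first-order
uptake toward a compensation point) and a net source of CO2 (linear
accumulation). Uptake rate constants come from log-linear regression of the
mole-fraction series; rates are referenced to the initial molar quantity in
the headspace (ideal gas law) and expressed per gram of dry soil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_GAS",
    "STANDARD_TEMPERATURE_K",
    "STANDARD_PRESSURE_PA",
    "GasTimeSeries",
    "FluxEstimate",
    "headspace_volume",
    "fit_first_order_uptake",
    "fit_linear_production",
    "coefficient_of_variation",
]

R_GAS = 8.314462618          # J mol^-1 K^-1
STANDARD_TEMPERATURE_K = 298.15  # incubation at 25 degC
STANDARD_PRESSURE_PA = 101_325.0

MIN_POINTS_UPTAKE = 5
MIN_POINTS_PRODUCTION = 4


class FluxFitError(ValueError):
    """Raised when a gas series cannot support the requested fit."""


def headspace_volume(
    bottle_volume_l: float = 0.5,
    soil_mass_g: float = 20.0,
    bulk_density_g_cm3: float = 1.0,
) -> float:
    """Headspace volume (L): nominal bottle volume minus the soil volume.

    Soil volume is mass / bulk density; the 1.0 g cm^-3 default gives 0.48 L
    for the standard 20 g microcosm in a 500 ml bottle.
    """
    if bulk_density_g_cm3 <= 0:
        raise ValueError("bulk density must be positive")
    soil_volume_l = soil_mass_g / bulk_density_g_cm3 / 1000.0
    if soil_volume_l >= bottle_volume_l:
        raise ValueError("soil volume exceeds bottle volume")
    return bottle_volume_l - soil_volume_l


@dataclass(frozen=True)
class GasTimeSeries:
    """One microcosm's headspace measurements with physical context."""

    gas: str                    # "H2" | "CO" | "CO2"
    times: np.ndarray           # hours, strictly increasing
    mixing_ratio: np.ndarray    # ppmv
    headspace_volume_l: float = 0.48
    dry_mass_g: float = 20.0
    temperature_k: float = STANDARD_TEMPERATURE_K
    pressure_pa: float = STANDARD_PRESSURE_PA

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        chi = np.asarray(self.mixing_ratio, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "mixing_ratio", chi)
        if times.shape != chi.shape or times.ndim != 1:
            raise ValueError("times and mixing_ratio must be matching 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(chi < 0):
            raise ValueError("mixing ratios must be >= 0")
        if self.dry_mass_g <= 0 or self.headspace_volume_l <= 0:
            raise ValueError("dry_mass_g and headspace_volume_l must be positive")


@dataclass(frozen=True)
class FluxEstimate:
    """Fitted kinetic parameter and per-gram flux for one series.

    ``k_or_slope`` is the first-order constant (h^-1, uptake) or the linear
    slope (ppmv h^-1, production). ``rate`` is a positive magnitude: nmol
    g(dw)^-1 h^-1 for H2/CO uptake, umol g(dw)^-1 h^-1 for CO2 production.
    """

    gas: str
    mode: str                 # "uptake" | "production"
    k_or_slope: float
    rate: float
    fit_r2: float
    n_points: int


def _moles_from_ppmv(ppmv: float, volume_l: float, temperature_k: float,
                     pressure_pa: float) -> float:
    """Moles of trace gas at the given mixing ratio via the ideal gas law."""
    total_moles = pressure_pa * (volume_l * 1e-3) / (R_GAS * temperature_k)
    return ppmv * 1e-6 * total_moles


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot


def fit_first_order_uptake(ts: GasTimeSeries, floor: float = 0.0) -> FluxEstimate:
    """First-order uptake constant and initial-rate flux.

    k is minus the OLS slope of ln(chi(t) - floor) against t. The flux is the
    initial rate k * n0 / dry_mass with n0 the molar quantity above the
    compensation point at t = 0, reported in nmol g^-1 h^-1.
    """
    if ts.times.size < MIN_POINTS_UPTAKE:
        raise FluxFitError(
            f"uptake fit needs >= {MIN_POINTS_UPTAKE} points, got {ts.times.size}"
        )
    excess = ts.mixing_ratio - floor
    if np.any(excess <= 0):
        raise FluxFitError(
            "mixing ratios at or below the compensation point; log-linear fit undefined"
        )
    log_excess = np.log(excess)
    slope, intercept = np.polyfit(ts.times, log_excess, 1)
    k = -float(slope)
    fitted = intercept + slope * ts.times
    r2 = _r_squared(log_excess, fitted)
    chi0 = float(ts.mixing_ratio[0]) - floor
    n0_mol = _moles_from_ppmv(chi0, ts.headspace_volume_l, ts.temperature_k,
                              ts.pressure_pa)
    rate_nmol = abs(k) * n0_mol * 1e9 / ts.dry_mass_g
    return FluxEstimate(gas=ts.gas, mode="uptake", k_or_slope=k, rate=rate_nmol,
                        fit_r2=r2, n_points=int(ts.times.size))


def fit_linear_production(ts: GasTimeSeries) -> FluxEstimate:
    """Linear production slope and flux in umol g^-1 h^-1."""
    if ts.times.size < MIN_POINTS_PRODUCTION:
        raise FluxFitError(
            f"production fit needs >= {MIN_POINTS_PRODUCTION} points, got {ts.times.size}"
        )
    slope, intercept = np.polyfit(ts.times, ts.mixing_ratio, 1)
    fitted = intercept + slope * ts.times
    r2 = _r_squared(ts.mixing_ratio, fitted)
    rate_mol_per_h = _moles_from_ppmv(float(slope), ts.headspace_volume_l,
                                      ts.temperature_k, ts.pressure_pa)
    rate_umol = abs(rate_mol_per_h) * 1e6 / ts.dry_mass_g
    return FluxEstimate(gas=ts.gas, mode="production", k_or_slope=float(slope),
                        rate=rate_umol, fit_r2=r2, n_points=int(ts.times.size))


def coefficient_of_variation(values) -> float:
    """Sample CV as a percentage: 100 * SD(n-1) / mean.

    Rounding to integer percent is left to report time; the undefined mean = 0
    case raises.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean
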