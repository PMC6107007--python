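"""Spectral figures of merit for passive radiative cooling.

Reduces wavelength-resolved reflectance/transmittance spectra to the three
scalars that characterize a radiative cooler: solar-weighted reflectance,
Planck-weighted thermal emissivity at a stated temperature, and the band
emissivity in the 8-14 μm atmospheric transparency window.  Emissivity is
derived from measured spectra as 1 - R - T (opaque-sample Kirchhoff
identity with a transmission channel).

A parametric stand-in for the AM 1.5 solar spectrum (scaled 5777 K Planck
curve times a smooth atmospheric-attenuation envelope) is provided for
download-free operation; a user-supplied AM 1.5 CSV always takes
precedence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "RadiometricSummary",
    "emissivity_from_RT",
    "planck_spectral_emissive_power",
    "weighted_scalar",
    "synthetic_solar_weight",
    "summarize",
    "ATMOSPHERIC_WINDOW_UM",
]

log = logging.getLogger(__name__)

#: the atmospheric transparency window, μm
ATMOSPHERIC_WINDOW_UM = (8.0, 14.0)

# first and second radiation constants, SI
_C1 = 3.7417718521927573e-16  # 2*pi*h*c^2, W m^2
_C2 = 1.4387768775039337e-2  # h*c/kB, m K


@dataclass
class Spectrum:
    """Wavelength-resolved R/T(/ε) on a strictly increasing μm grid."""

    wavelength: np.ndarray
    reflectance: np.ndarray | None = None
    transmittance: np.ndarray | None = None
    emissivity: np.ndarray | None = None

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in ("reflectance", "transmittance", "emissivity"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.wavelength.shape:
                    raise ValueError(f"{name} shape mismatch")
                setattr(self, name, v)
        if self.reflectance is not None and self.transmittance is not None:
            if np.any(self.reflectance + self.transmittance > 1.0 + 1e-3):
                bad = self.wavelength[
                    self.reflectance + self.transmittance > 1.0 + 1e-3
                ]
                raise ValueError(
                    f"R+T exceeds 1 by more than 1e-3 at lambda={bad[:5]} um"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        df = pd.read_csv(path)
        required = {"wavelength_um"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected a 'wavelength_um' column")
        return cls(
            wavelength=df["wavelength_um"].to_numpy(),
            reflectance=df["reflectance"].to_numpy() if "reflectance" in df else None,
            transmittance=(
                df["transmittance"].to_numpy() if "transmittance" in df else None
            ),
            emissivity=df["emissivity"].to_numpy() if "emissivity" in df else None,
        )

    def to_csv(self, path: str | Path) -> None:
        cols = {"wavelength_um": self.wavelength}
        if self.reflectance is not None:
            cols["reflectance"] = self.reflectance
        if self.transmittance is not None:
            cols["transmittance"] = self.transmittance
        if self.emissivity is not None:
            cols["emissivity"] = self.emissivity
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class RadiometricSummary:
    solar_reflectance: float | None
    thermal_emissivity: float | None
    window_emissivity: float | None
    temperature: float
    solar_bounds: tuple[float, float]
    thermal_bounds: tuple[float, float]
    window_bounds: tuple[float, float]
    weight_provenance: str

    def to_dict(self) -> dict:
        return {
            "solar_reflectance": self.solar_reflectance,
            "thermal_emissivity": self.thermal_emissivity,
            "window_emissivity": self.window_emissivity,
            "temperature_K": self.temperature,
            "bounds_um": {
                "solar": list(self.solar_bounds),
                "thermal": list(self.thermal_bounds),
                "window": list(self.window_bounds),
            },
            "weight_provenance": self.weight_provenance,
        }


def emissivity_from_RT(spectrum: Spectrum) -> Spectrum:
    """ε = 1 - R - T, clipped to [0, 1] with clipping events logged."""
    if spectrum.reflectance is None or spectrum.transmittance is None:
        raise ValueError("spectrum must carry both reflectance and transmittance")
    eps = 1.0 - spectrum.reflectance - spectrum.transmittance
    n_clip = int(np.sum((eps < 0) | (eps > 1)))
    if n_clip:
        log.warning("emissivity clipped to [0,1] at %d wavelength samples", n_clip)
    return Spectrum(
        wavelength=spectrum.wavelength,
        reflectance=spectrum.reflectance,
        transmittance=spectrum.transmittance,
        emissivity=np.clip(eps, 0.0, 1.0),
    )


def planck_spectral_emissive_power(wavelength_um, T: float):
    """Blackbody hemispherical spectral emissive power, W m^-2 μm^-1.

    Planck's law per unit wavelength times pi (Lambertian hemisphere).
    """
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    lam = np.asarray(wavelength_um, dtype=float) * 1e-6  # m
    with np.errstate(over="ignore"):
        M = _C1 / lam**5 / np.expm1(_C2 / (lam * T))  # W m^-2 m^-1
    return M * 1e-6  # per μm


def _amplitude_envelope(lam: np.ndarray) -> np.ndarray:
    """Smooth parametric clear-sky attenuation for the synthetic solar weight.

    UV ozone cutoff plus Gaussian water/CO2 absorption dips; purely a
    qualitative stand-in, clearly labeled as synthetic.
    """
    env = 0.75 / (1.0 + np.exp(-(lam - 0.31) / 0.012))
    dips = [
        (0.94, 0.020, 0.35),
        (1.13, 0.030, 0.45),
        (1.40, 0.040, 0.80),
        (1.87, 0.050, 0.85),
        (2.60, 0.120, 0.95),
    ]
    for c, w, depth in dips:
        env *= 1.0 - depth * np.exp(-0.5 * ((lam - c) / w) ** 2)
    return env


def synthetic_solar_weight(
    bounds: tuple[float, float] = (0.28, 4.0),
    n_points: int = 2000,
    normalize: bool = False,
    user_csv: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Synthetic AM1.5-like solar weight: (wavelength μm, weight, provenance).

    A 5777 K Planck curve times a smooth atmospheric envelope.  When
    ``user_csv`` (columns wavelength_um, weight) is given it is used
    verbatim and provenance is reported as "user".
    """
    if user_csv is not None:
        df = pd.read_csv(user_csv)
        lam = df["wavelength_um"].to_numpy(dtype=float)
        w = df["weight"].to_numpy(dtype=float)
        if normalize:
            w = w / np.trapezoid(w, lam)
        return lam, w, "user"
    lo, hi = bounds
    if not (0.28 <= lo < hi <= 4.0):
        raise ValueError("synthetic solar bounds must lie within (0.28, 4.0) um")
    lam = np.linspace(lo, hi, n_points)
    w = planck_spectral_emissive_power(lam, 5777.0) * _amplitude_envelope(lam)
    w = np.maximum(w, 0.0)
    if normalize:
        w = w / np.trapezoid(w, lam)
    return lam, w, "synthetic"


def weighted_scalar(
    wavelength: np.ndarray,
    values: np.ndarray,
    weight_wavelength: np.ndarray,
    weight: np.ndarray,
    bounds: tuple[float, float],
) -> float:
    """∫ f w dλ / ∫ w dλ by trapezoid on the union grid over ``bounds``.

    Both curves are linearly interpolated onto the union of their grids
    (restricted to the bounds, with the bound points inserted); the
    spectrum must cover the bounds.
    """
    lo, hi = bounds
    wavelength = np.asarray(wavelength, float)
    values = np.asarray(values, float)
    if wavelength[0] > lo + 1e-12 or wavelength[-1] < hi - 1e-12:
        raise ValueError(
            f"spectrum covers [{wavelength[0]:.3g}, {wavelength[-1]:.3g}] um but "
            f"the weighting bounds are [{lo:.3g}, {hi:.3g}] um"
        )
    grid = np.union1d(wavelength, weight_wavelength)
    grid = np.union1d(grid, [lo, hi])
    grid = grid[(grid >= lo) & (grid <= hi)]
    f = np.interp(grid, wavelength, values)
    w = np.interp(grid, weight_wavelength, weight, left=0.0, right=0.0)
    denom = np.trapezoid(w, grid)
    if denom <= 0:
        raise ValueError("weight integrates to zero over the requested bounds")
    return float(np.trapezoid(f * w, grid) / denom)


def summarize(
    spectrum: Spectrum,
    temperature: float = 300.0,
    solar_bounds: tuple[float, float] = (0.4, 2.5),
    thermal_bounds: tuple[float, float] = (2.5, 25.0),
    window_bounds: tuple[float, float] = ATMOSPHERIC_WINDOW_UM,
    solar_csv: str | Path | None = None,
) -> RadiometricSummary:
    """Solar reflectance, 300 K thermal emissivity, and window emissivity.

    Emissivity is derived via 1 - R - T if absent.  Scalars whose spectral
    coverage is missing are reported as None rather than extrapolated.
    """
    if spectrum.emissivity is None:
        spectrum = emissivity_from_RT(spectrum)
    sw_lam, sw, provenance = synthetic_solar_weight(user_csv=solar_csv)

    def _try(values, w_lam, w, bounds):
        if values is None:
            return None
        try:
            return weighted_scalar(spectrum.wavelength, values, w_lam, w, bounds)
        except ValueError:
            return None

    th_lam = np.linspace(*thermal_bounds, 2000)
    th_w = planck_spectral_emissive_power(th_lam, temperature)
    win_lam = np.linspace(*window_bounds, 800)
    win_w = planck_spectral_emissive_power(win_lam, temperature)
    return RadiometricSummary(
        solar_reflectance=_try(spectrum.reflectance, sw_lam, sw, solar_bounds),
        thermal_emissivity=_try(spectrum.emissivity, th_lam, th_w, thermal_bounds),
        window_emissivity=_try(spectrum.emissivity, win_lam, win_w, window_bounds),
        temperature=temperature,
        solar_bounds=solar_bounds,
        thermal_bounds=thermal_bounds,
        window_bounds=window_bounds,
        weight_provenance=provenance,
    )
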