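"""Synthetic vehicle source spectra and miniature test worlds.

The calibrated sedan/motorcycle 1/3-octave source tables that drive the
model in production settings come from proprietary traffic-noise datasets
and cannot be redistributed, so this module generates SYNTHETIC stand-ins
with the right qualitative shape: sedans radiate a broad bump peaked near
1000 Hz (tyre/road noise), motorcycles peak near 250 Hz and are about
tenfold (10 dB) louder overall at equal speed.  They are constructed, not
measured — suitable for demonstrations and tests, not for prediction.

Every spectrum is emitted at the three reference speeds used for the
per-band power-law fits (6.7, 11.2 and 24.6 m/s).
"""

from __future__ import annotations

import numpy as np

from .acoustics import (
    BandPowerLaw,
    ThirdOctaveSpectrum,
    fit_band_powerlaw,
    overall_a_level,
    third_octave_centers,
)

__all__ = [
    "REFERENCE_SPEEDS",
    "VEHICLE_TYPES",
    "make_vehicle_spectra",
    "vehicle_power_laws",
    "make_toy_world",
]

REFERENCE_SPEEDS = (6.7, 11.2, 24.6)  # m/s

# Spectral bump shape: quadratic in octaves from the peak, ~12 dB/octave
# slope one octave out.  Speed growth: +25 dB per decade of speed in every
# band (plausible rolling-noise growth), so spectral shape is speed-invariant.
_ROLLOFF = 6.0  # dB per octave^2
_SPEED_SLOPE = 25.0  # dB per decade of speed
_SEDAN_PEAK_HZ = 1000.0
_MOTO_PEAK_HZ = 250.0
_SEDAN_PEAK_DB = 84.0  # at 1 m, at the top reference speed
_MOTO_OVERALL_EXCESS = 10.0  # dBA above the sedan at equal speed

VEHICLE_TYPES = ("sedan", "motorcycle")


def _bump(bands: np.ndarray, peak_hz: float, peak_db: float) -> np.ndarray:
    octaves = np.log2(bands / peak_hz)
    return peak_db - _ROLLOFF * octaves**2


def make_vehicle_spectra(vehicle_type: str, fmin: float = 50.0, fmax: float = 10000.0):
    """Synthetic 1/3-octave spectra at the three reference speeds.

    Returns ``(band_centers, {speed_mps: levels_db})`` with levels at 1 m.
    The motorcycle table is offset so its overall A-level exceeds the
    sedan's by exactly 10 dB at the top reference speed.
    """
    if vehicle_type not in VEHICLE_TYPES:
        raise ValueError(f"unknown vehicle type: {vehicle_type!r}")
    bands = third_octave_centers(fmin, fmax)
    v_top = REFERENCE_SPEEDS[-1]

    sedan_top = _bump(bands, _SEDAN_PEAK_HZ, _SEDAN_PEAK_DB)
    if vehicle_type == "sedan":
        shape_top = sedan_top
    else:
        moto_top = _bump(bands, _MOTO_PEAK_HZ, _SEDAN_PEAK_DB)
        sedan_dba = overall_a_level(ThirdOctaveSpectrum(bands, sedan_top))
        moto_dba = overall_a_level(ThirdOctaveSpectrum(bands, moto_top))
        shape_top = moto_top + (sedan_dba + _MOTO_OVERALL_EXCESS - moto_dba)

    levels = {}
    for v in REFERENCE_SPEEDS:
        levels[v] = shape_top + _SPEED_SLOPE * np.log10(v / v_top)
    return bands, levels


def vehicle_power_laws(vehicle_type: str, fmin: float = 50.0, fmax: float = 10000.0) -> BandPowerLaw:
    """Per-band power laws fitted to the synthetic reference-speed spectra."""
    bands, levels = make_vehicle_spectra(vehicle_type, fmin, fmax)
    table = np.column_stack([levels[v] for v in REFERENCE_SPEEDS])
    return fit_band_powerlaw(REFERENCE_SPEEDS, table, bands)


def make_toy_world(
    n_searchers: int,
    n_resources: int,
    n_vehicles: int,
    seed: int,
    nx: int = 40,
    ny: int = 31,
    **overrides,
):
    """A deterministic miniature simulation configuration for tests.

    The landscape is ``nx`` x ``ny`` 10 m cells (default 40 x 31, i.e.
    400 m x 310 m) with the usual road/trail geometry; resource count and
    vehicle count are given directly instead of via spacing / hourly-rate
    conversions.  Same arguments always produce the same world.
    """
    from .engine import SimulationConfig

    if n_resources > nx * ny:
        raise ValueError("more resources than cells")
    if n_vehicles > nx * ny + ny - 1:
        raise ValueError("more vehicles than road patches")
    cfg = dict(
        nx=nx,
        ny=ny,
        num_searchers=n_searchers,
        num_vehicles=float(n_vehicles),
        vehicle_count_mode="count",
        num_resources=n_resources,
        seed=seed,
        speed_limit=60.0,
        ambient_level=30.0,
        base_percept=28.1,
        human_mult=2.0,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)
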