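"""Orographic and thermal uplift velocity fields from terrain, wind and LST.

Orographic uplift follows the windward-deflection model: horizontal wind of
speed ``v`` meeting a slope of angle theta whose aspect beta faces the wind
source alpha produces a vertical air speed

    w0 = v * C_alpha,          C_alpha = sin(theta) * cos(alpha - beta)

with negative coefficients (leeward terrain, eddies, lee waves) clamped to
zero.  Thermal uplift uses the convective velocity scale

    w* = (g * z * H / theta_pot) ** (1/3)

where ``H`` is the surface sensible heat flux derived from a land-surface
temperature raster, ``theta_pot`` the potential temperature of the boundary
layer, and ``z`` a representative flight height above ground.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .raster import RasterGrid

__all__ = [
    "WindScenario",
    "ThermalConstants",
    "slope_aspect",
    "updraft_coefficient",
    "orographic_uplift",
    "aerodynamic_resistance",
    "sensible_heat_flux",
    "potential_temperature",
    "thermal_uplift",
    "thermal_uplift_from_lst",
]


@dataclass(frozen=True)
class WindScenario:
    """A steady horizontal wind: meteorological direction-from and speed.

    ``direction_from_deg`` uses the compass convention (north = 0, clockwise)
    and names the direction the wind blows *from*; a levanter blowing out of
    the east is ``direction_from_deg = 90``.
    """

    direction_from_deg: float
    speed_ms: float

    def __post_init__(self) -> None:
        if not 0 <= self.direction_from_deg < 360:
            raise ValueError("direction_from_deg must lie in [0, 360)")
        if self.speed_ms < 0:
            raise ValueError("speed_ms must be non-negative")

    @property
    def downwind_deg(self) -> float:
        """Compass direction the wind blows towards."""
        return (self.direction_from_deg + 180.0) % 360.0


@dataclass(frozen=True)
class ThermalConstants:
    """Physical constants of the thermal-uplift model.

    Defaults are the standard boundary-layer values: gravitational
    acceleration, sea-level air density at 288.15 K, isobaric mass heat
    capacity of dry air, air temperature 2 m above ground, sea-level standard
    pressure, boundary-layer pressure 1 km above sea level, and the Poisson
    constant for dry air.  ``flight_height_z`` is the representative flight
    height above ground (m) entering the convective velocity scale; it can be
    recomputed from tracking data as the mean height of active flight.
    """

    g: float = 9.8                       # m s^-2
    air_density_p: float = 1.225         # kg m^-3
    isobaric_heat_cp: float = 1.0035     # heat capacity of dry air
    air_temp_Ta: float = 288.15          # K
    sea_level_pressure_p0: float = 1013.25   # mbar
    boundary_layer_pressure_p: float = 898.7457  # mbar
    poisson_k: float = 0.2854
    flight_height_z: float = 400.0       # m

    def __post_init__(self) -> None:
        for name in ("g", "air_density_p", "isobaric_heat_cp", "air_temp_Ta",
                     "sea_level_pressure_p0", "boundary_layer_pressure_p",
                     "flight_height_z"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def with_flight_height(self, z: float) -> "ThermalConstants":
        return replace(self, flight_height_z=float(z))


# ----------------------------------------------------------------------
# terrain derivatives

def slope_aspect(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope and aspect rasters by Horn's 3x3 finite-difference method.

    Slope is in degrees from horizontal, in ``[0, 90]``.  Aspect is the
    compass direction the slope faces (downslope), north = 0, clockwise, in
    ``[0, 360)``; flat cells have undefined aspect (NaN).  Border cells and
    cells with any nodata neighbour are nodata in both outputs.
    """
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope/aspect needs a raster of at least 3x3 cells")
    cs = dem.cell_size_m

    # 3x3 neighbourhood of each interior cell; rows are stored top-down so
    # row i-1 lies to the north of row i.
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]

    # Horn's weighted differences: gx increases eastward, gy northward
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cs)

    grad = np.hypot(gx, gy)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    flat = grad == 0
    aspect[flat] = np.nan
    slope[np.isnan(grad)] = np.nan

    out_slope = np.full(z.shape, np.nan)
    out_aspect = np.full(z.shape, np.nan)
    out_slope[1:-1, 1:-1] = slope
    out_aspect[1:-1, 1:-1] = aspect
    return dem.with_values(out_slope), dem.with_values(out_aspect)


# ----------------------------------------------------------------------
# orographic uplift

def updraft_coefficient(slope_deg, aspect_deg, wind_from_deg):
    """Windwardness coefficient ``max(0, sin(theta) * cos(alpha - beta))``.

    ``slope_deg`` and ``aspect_deg`` may be scalars or arrays; an undefined
    (NaN) aspect — flat terrain — yields 0.  The result lies in ``[0, 1]``:
    negative raw values mark leeward terrain (turbulent eddies, lee waves)
    and are set to zero.
    """
    slope = np.asarray(slope_deg, float)
    aspect = np.asarray(aspect_deg, float)
    with np.errstate(invalid="ignore"):
        raw = np.sin(np.radians(slope)) * np.cos(np.radians(wind_from_deg) - np.radians(aspect))
    c = np.where(np.isnan(aspect), 0.0, raw)
    c = np.where(np.isnan(slope), np.nan, np.maximum(c, 0.0))
    if np.ndim(slope_deg) == 0 and np.ndim(aspect_deg) == 0:
        return float(c)
    return c


def orographic_uplift(wind: WindScenario, slope_deg: RasterGrid,
                      aspect_deg: RasterGrid) -> RasterGrid:
    """Orographic uplift velocity ``w0 = v * C_alpha`` (m/s) per cell."""
    if not slope_deg.same_geometry(aspect_deg):
        raise ValueError("slope and aspect rasters are not co-registered")
    c = updraft_coefficient(slope_deg.values, aspect_deg.values, wind.direction_from_deg)
    return slope_deg.with_values(wind.speed_ms * c)


# ----------------------------------------------------------------------
# thermal uplift

def aerodynamic_resistance(wind_speed_2m: float) -> float:
    """Aerodynamic resistance of a grassland surface, ``208 / v2`` (s/m)."""
    if not wind_speed_2m > 0:
        raise ValueError("wind speed at 2 m must be strictly positive")
    return 208.0 / wind_speed_2m


def sensible_heat_flux(lst: RasterGrid, constants: ThermalConstants,
                       ra: float) -> RasterGrid:
    """Surface sensible heat flux ``H = p * cp * (Ts - Ta) / ra`` per cell.

    ``lst`` is the land-surface temperature in Kelvin; values outside the
    plausible terrestrial range (150-400 K) raise, which catches Celsius
    rasters passed by mistake.  H is negative where the surface is colder
    than the air.
    """
    if not ra > 0:
        raise ValueError("aerodynamic resistance must be positive")
    ts = lst.values
    finite = ts[np.isfinite(ts)]
    if finite.size and (finite.min() < 150 or finite.max() > 400):
        raise ValueError("LST raster outside plausible Kelvin range (150-400 K)")
    h = constants.air_density_p * constants.isobaric_heat_cp * (ts - constants.air_temp_Ta) / ra
    return lst.with_values(h)


def potential_temperature(constants: ThermalConstants) -> float:
    """Potential temperature ``theta = Ta * (p0 / p) ** k`` (K), a scalar."""
    p0 = constants.sea_level_pressure_p0
    p = constants.boundary_layer_pressure_p
    if p0 <= 0 or p <= 0:
        raise ValueError("pressures must be strictly positive")
    return constants.air_temp_Ta * (p0 / p) ** constants.poisson_k


def thermal_uplift(H: RasterGrid, constants: ThermalConstants,
                   theta_pot: float) -> RasterGrid:
    """Convective velocity scale ``w* = (g * z * H / theta) ** (1/3)`` (m/s).

    Cells with non-positive sensible heat flux carry no thermal uplift and
    are set to 0, mirroring the clamping of negative windwardness in the
    orographic model.
    """
    if not theta_pot > 0:
        raise ValueError("potential temperature must be positive")
    if not constants.flight_height_z > 0:
        raise ValueError("flight height must be positive")
    h = H.values
    w = np.zeros_like(h)
    pos = h > 0
    w[pos] = np.cbrt(constants.g * constants.flight_height_z * h[pos] / theta_pot)
    w[np.isnan(h)] = np.nan
    return H.with_values(w)


def thermal_uplift_from_lst(lst: RasterGrid, constants: ThermalConstants,
                            wind_speed_2m: float) -> RasterGrid:
    """Convenience composition: LST raster -> H -> theta -> w*."""
    ra = aerodynamic_resistance(wind_speed_2m)
    H = sensible_heat_flux(lst, constants, ra)
    theta = potential_temperature(constants)
    return thermal_uplift(H, constants, theta)
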