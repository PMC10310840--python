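"""LED light-propagation model: Fresnel interfaces plus empirical scattering.

The stimulation LED is modelled as an 8 x 8 grid of point sources in water
above the cranial window.  A straight ray from each source to a target
point in the brain crosses the water->glass and glass->brain interfaces;
at each, the unpolarized Fresnel transmittance is applied.  Within the
brain an exponential scattering attenuation over the in-brain path length
is applied (the length constant is an empirical input, not derived here).
The per-source power is spread over a half-sphere of radius equal to the
source-target distance (density = P / (2 pi r^2)); sources are treated
independently and averaged.

Rays are straight lines (no refraction bending); Fresnel factors only
scale the transmitted power.  This is a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .datamodel import InvalidInputError


def fresnel_transmission(n1: float, n2: float, incidence_angle: float) -> float:
    """Unpolarized Fresnel power transmittance at a planar interface.

    Average of the s- and p-polarization transmittances ``1 - R``; beyond
    the critical angle (total internal reflection) the transmittance is 0.

    Parameters
    ----------
    n1, n2 : float
        Real refractive indices (>= 1) of the incident and transmitting media.
    incidence_angle : float
        Angle from the surface normal, in radians, in [0, pi/2).
    """
    if n1 < 1 or n2 < 1:
        raise InvalidInputError("refractive indices must be >= 1")
    if not 0 <= incidence_angle < np.pi / 2:
        raise InvalidInputError("incidence angle must be in [0, pi/2)")
    sin_t = n1 * np.sin(incidence_angle) / n2
    if sin_t >= 1.0:
        return 0.0
    theta_t = np.arcsin(sin_t)
    ci, ct = np.cos(incidence_angle), np.cos(theta_t)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return float(1.0 - 0.5 * (rs**2 + rp**2))


@dataclass
class OpticsConfig:
    """Geometry and optical parameters of the LED / window / brain stack.

    Distances in micrometers, powers in mW.  The coordinate frame has z = 0
    at the brain surface, z increasing downward into the brain; the glass
    window spans ``[-glass_thickness, 0]`` and water above it.
    """

    max_power_mw: float = 50.0  # total power at the LED face
    led_extent_um: float = 1000.0  # side length of the emitting face
    led_grid_n: int = 8  # grid is 8 x 8 when emulating the study
    led_height_um: float = 300.0  # water gap between LED face and window
    n_water: float = 1.33
    n_glass: float = 1.52
    n_brain: float = 1.36
    glass_thickness_um: float = 170.0
    scattering_length_um: Optional[float] = 200.0  # None disables scattering
    led_center_xy: Tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        for name in ("n_water", "n_glass", "n_brain"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")
        for name in ("max_power_mw", "led_extent_um", "led_height_um", "glass_thickness_um"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.led_grid_n < 1:
            raise InvalidInputError("led_grid_n must be >= 1")
        if self.scattering_length_um is not None and self.scattering_length_um <= 0:
            raise InvalidInputError("scattering_length_um must be > 0 (or None)")

    def source_positions(self) -> np.ndarray:
        """(n^2, 3) point-source coordinates above the window (z < 0)."""
        n = self.led_grid_n
        if n == 1:
            offsets = np.array([0.0])
        else:
            offsets = (np.arange(n) - (n - 1) / 2.0) * (self.led_extent_um / (n - 1))
        xs, ys = np.meshgrid(offsets + self.led_center_xy[0], offsets + self.led_center_xy[1])
        z = -(self.glass_thickness_um + self.led_height_um)
        return np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])


def power_density(point: Sequence[float], config: OpticsConfig) -> float:
    """Predicted power density (mW/mm^2) at a point inside the brain.

    Per source: straight ray to the target, Fresnel transmittances at both
    interfaces (incidence angle from the ray's inclination to the vertical
    interface normal), exponential scattering attenuation over the in-brain
    path, and half-sphere spreading ``P / (2 pi r^2)`` at the source
    distance.  Sources carry equal shares of the LED face power and are
    averaged by summing their independent contributions.
    """
    config.validate()
    p = np.asarray(point, dtype=float)
    if p[2] <= 0:
        raise InvalidInputError("target point must lie inside the brain (z > 0)")
    sources = config.source_positions()
    per_source_power = config.max_power_mw / sources.shape[0]
    total = 0.0
    for s in sources:
        d = p - s
        r = float(np.linalg.norm(d))
        # inclination to the vertical (interfaces are horizontal planes)
        cos_inc = abs(d[2]) / r
        angle = float(np.arccos(np.clip(cos_inc, -1.0, 1.0)))
        if angle >= np.pi / 2:
            continue
        t1 = fresnel_transmission(config.n_water, config.n_glass, angle)
        t2 = fresnel_transmission(config.n_glass, config.n_brain, angle)
        # in-brain path length of the straight ray
        frac_in_brain = p[2] / (p[2] - s[2])
        l_brain = r * frac_in_brain
        scatter = (
            1.0
            if config.scattering_length_um is None
            else float(np.exp(-l_brain / config.scattering_length_um))
        )
        r_mm = r / 1000.0
        total += per_source_power * t1 * t2 * scatter / (2.0 * np.pi * r_mm**2)
    return total


def depth_profile(
    config: OpticsConfig,
    depths_um: Sequence[float],
    lateral_extent_um: Optional[float] = None,
    lateral_n: int = 5,
) -> np.ndarray:
    """Mean lateral power density at each depth (mW/mm^2).

    Averages :func:`power_density` over a lateral grid centered under the
    LED (default extent = LED face).  Monotone nonincreasing in depth for
    any physical configuration.
    """
    config.validate()
    depths = np.asarray(depths_um, dtype=float)
    if np.any(depths <= 0):
        raise InvalidInputError("depths must be > 0 (inside the brain)")
    extent = config.led_extent_um if lateral_extent_um is None else lateral_extent_um
    if lateral_n == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-extent / 2, extent / 2, lateral_n)
    out = np.empty(depths.size)
    for k, z in enumerate(depths):
        vals = [
            power_density((x + config.led_center_xy[0], y + config.led_center_xy[1], z), config)
            for x in offsets
            for y in offsets
        ]
        out[k] = float(np.mean(vals))
    return out
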