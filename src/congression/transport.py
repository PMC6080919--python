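"""Chromosome motion before microtubule capture.

After NEBD a contractile F-actin network fills the nuclear region and
transports the embedded chromosomes toward a single convergence point *p*
at the animal pole. The network is not represented by explicit filaments;
its effect is the velocity field

    v(x, t) = (p - x) / (t_x - t)   for t in [0, t_m],
    v(x, t) = 0                     for t > t_m,

under which every chromosome moves toward *p* at a speed that is constant
in time and proportional to its distance from *p* at NEBD (all would
reach *p* simultaneously at t_x if transport did not stop at t_m).
Independent Brownian motion of the 0.8-µm chromosome sphere is added on
top (Euler–Maruyama at the global step), and excursions are reflected at
the nuclear boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import OocyteGeometry, SimParams, ValidationError, diffusion_coefficient

__all__ = ["VelocityField", "velocity_at", "step_free_positions", "brownian_sigma"]


@dataclass(frozen=True)
class VelocityField:
    """F-actin transport field parameters: convergence point and times (min)."""

    p: np.ndarray
    t_x: float = 15.0
    t_m: float = 12.5

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.t_m >= self.t_x:
            raise ValidationError(f"t_m ({self.t_m}) must be smaller than t_x ({self.t_x})")


def velocity_at(x, t: float, field: VelocityField) -> np.ndarray:
    """Transport velocity at position(s) ``x`` (µm) and time ``t`` (min), in µm/min.

    ``x`` may be a single 3-vector or an (m, 3) array. Returns the zero
    vector after the transport stop time t_m. Times at or beyond t_x are
    rejected defensively (they cannot occur while the field is active,
    since t_m < t_x).
    """
    if t < 0:
        raise ValidationError(f"t must be nonnegative, got {t}")
    x = np.asarray(x, dtype=float)
    if t > field.t_m:
        return np.zeros_like(x)
    if t >= field.t_x:
        raise ValidationError(f"t ({t}) must be below t_x ({field.t_x}) while the field is active")
    return (field.p - x) / (field.t_x - t)


def brownian_sigma(params: SimParams) -> float:
    """Per-axis standard deviation of the Brownian displacement per step, µm."""
    return float(np.sqrt(2.0 * diffusion_coefficient(params) * params.dt))


def _reflect_at_boundary(positions: np.ndarray, geometry: OocyteGeometry) -> np.ndarray:
    rel = positions - geometry.nucleus_center
    r = np.linalg.norm(rel, axis=-1)
    outside = r > geometry.nucleus_radius
    if np.any(outside):
        r_out = r[outside]
        # radial reflection r -> 2R - r (a single step never exceeds 2R)
        scale = (2.0 * geometry.nucleus_radius - r_out) / r_out
        positions = positions.copy() if positions.base is None else positions
        positions[outside] = geometry.nucleus_center + rel[outside] * scale[:, None]
    return positions


def step_free_positions(
    positions: np.ndarray,
    t: float,
    field: VelocityField | None,
    params: SimParams,
    geometry: OocyteGeometry,
    rng: np.random.Generator,
    sigma: float | None = None,
) -> np.ndarray:
    """Advance free-chromosome positions by one step ``dt``.

    ``positions`` is an (m, 3) array in µm; ``t`` the current time in
    minutes. With ``field=None`` (model variant 1) the motion is purely
    Brownian. Returns a new array; positions are reflected at the nuclear
    boundary.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if sigma is None:
        sigma = brownian_sigma(params)
    new = positions.copy()
    if field is not None:
        v = velocity_at(positions, t, field)  # µm/min
        new += v * (params.dt / 60.0)
    if sigma > 0:
        new += sigma * rng.standard_normal(positions.shape)
    return _reflect_at_boundary(new, geometry)
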