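"""Geometry, physical parameters, units and the randomness contract.

The spatial world is the germinal vesicle (nucleus) of a large oocyte:
a sphere of 70 µm diameter whose boundary carries the animal pole (AP).
Two static centrosomes sit just inside the boundary near the AP and
nucleate the astral microtubules that search for chromosomes.

Unit conventions used throughout the package:

* lengths in micrometres (µm)
* the integration time step ``dt`` is in seconds
* times, speeds and rates are expressed in minutes (min, µm/min, 1/min)
  except for the kinetochore binding rate ``k_on`` which is in 1/s
* time zero is NEBD (nuclear envelope breakdown)
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ValidationError",
    "OocyteGeometry",
    "SimParams",
    "RngStreams",
    "make_geometry",
    "diffusion_coefficient",
]

BOLTZMANN_J_PER_K = 1.380649e-23


class ValidationError(ValueError):
    """Raised when a parameter or geometry constraint is violated."""


def _as_point(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValidationError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class OocyteGeometry:
    """Nuclear sphere, AP convergence point and centrosome positions.

    ``ap_point`` is the point *p* on the nuclear boundary toward which the
    F-actin velocity field transports chromosomes; the two centrosomes sit
    ``cortex_offset`` µm inside the boundary, symmetric about the
    center→p axis.
    """

    nucleus_center: np.ndarray
    nucleus_radius: float
    ap_point: np.ndarray
    centrosome_positions: np.ndarray  # shape (2, 3)

    def __post_init__(self):
        object.__setattr__(self, "nucleus_center", _as_point(self.nucleus_center, "nucleus_center"))
        object.__setattr__(self, "ap_point", _as_point(self.ap_point, "ap_point"))
        cp = np.asarray(self.centrosome_positions, dtype=float)
        if cp.shape != (2, 3):
            raise ValidationError(
                f"centrosome_positions must have shape (2, 3), got {cp.shape}"
            )
        object.__setattr__(self, "centrosome_positions", cp)
        if self.nucleus_radius <= 0:
            raise ValidationError("nucleus_radius must be positive")


def make_geometry(
    nucleus_radius: float = 35.0,
    centrosome_gap: float = 6.0,
    cortex_offset: float = 3.0,
    nucleus_center=(0.0, 0.0, 0.0),
    ap_direction=(0.0, 0.0, 1.0),
) -> OocyteGeometry:
    """Build the oocyte geometry.

    The AP point ``p`` is the boundary point on the outward ray through the
    centrosome midpoint. Both centrosomes lie exactly ``cortex_offset`` µm
    inside the boundary (|c - center| = R - cortex_offset), separated by
    ``centrosome_gap`` µm perpendicular to the center→p axis and symmetric
    about it.

    Parameters
    ----------
    nucleus_radius : float
        Radius of the nuclear sphere in µm (default 35, i.e. 70 µm diameter).
    centrosome_gap : float
        Distance between the two centrosomes in µm (default 6).
    cortex_offset : float
        Distance of each centrosome from the cortex (nuclear boundary) in µm
        (default 3).
    """
    if nucleus_radius <= 0:
        raise ValidationError(f"nucleus_radius must be positive, got {nucleus_radius}")
    if cortex_offset <= 0:
        raise ValidationError(f"cortex_offset must be positive, got {cortex_offset}")
    if cortex_offset >= nucleus_radius:
        raise ValidationError(
            f"cortex_offset ({cortex_offset}) must be smaller than "
            f"nucleus_radius ({nucleus_radius})"
        )
    if centrosome_gap < 0:
        raise ValidationError(f"centrosome_gap must be nonnegative, got {centrosome_gap}")
    if centrosome_gap >= 2.0 * nucleus_radius:
        raise ValidationError(
            f"centrosome_gap ({centrosome_gap}) must be smaller than the "
            f"nucleus diameter ({2 * nucleus_radius})"
        )
    center = _as_point(nucleus_center, "nucleus_center")
    axis = _as_point(ap_direction, "ap_direction")
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValidationError("ap_direction must be a nonzero vector")
    axis = axis / norm

    c_radius = nucleus_radius - cortex_offset
    half_gap = centrosome_gap / 2.0
    if half_gap > c_radius:
        raise ValidationError(
            f"centrosome_gap ({centrosome_gap}) incompatible with "
            f"cortex_offset ({cortex_offset}): centrosomes cannot sit "
            f"{c_radius} µm from the center"
        )
    # perpendicular direction to the AP axis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = trial - np.dot(trial, axis) * axis
    perp /= np.linalg.norm(perp)

    axial = np.sqrt(c_radius**2 - half_gap**2)
    c0 = center + axial * axis + half_gap * perp
    c1 = center + axial * axis - half_gap * perp
    p = center + nucleus_radius * axis
    return OocyteGeometry(
        nucleus_center=center,
        nucleus_radius=float(nucleus_radius),
        ap_point=p,
        centrosome_positions=np.stack([c0, c1]),
    )


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    Microtubule parameters (``mt_growth_speed``, ``mt_shrink_speed``,
    ``n_mt_per_aster``, ``catastrophe_base``, ``catastrophe_slope``,
    ``capture_radius``, ``base_binding_rate``) were calibrated once against
    the actin-depolymerized condition (model variant 1: mean capture time of
    chromosomes inside the capture range, and the ~30 µm capture range
    itself) and are frozen at those values for all model variants; see
    docs/methods.md.

    ``model_variant`` selects the congression model:

    1. pure microtubule search-and-capture (no velocity field, no gate) —
       emulates the actin-depolymerized (Latrunculin) condition;
    2. search-and-capture plus the F-actin velocity field;
    3. variant 2 plus the time-gated kinetochore binding rate (the F-actin
       patch surrogate) — the full model.
    """

    dt: float = 0.05                  # integration step, s
    t_end: float = 25.0               # total simulated time, min
    t_x: float = 15.0                 # velocity-field convergence time, min
    t_m: float = 12.5                 # transport stop time, min
    chromosome_radius: float = 0.8    # µm
    viscosity: float = 0.1            # Pa s
    temperature: float = 293.0        # K
    n_chromosomes: int = 22
    mt_growth_speed: float = 15.0     # v_g, µm/min
    mt_shrink_speed: float = 25.0     # v_s, µm/min
    n_mt_per_aster: int = 150
    catastrophe_base: float = 0.4     # k0, 1/min
    catastrophe_slope: float = 2.0    # k1, 1/(min µm), applies beyond the knee
    catastrophe_knee: float = 20.0    # L_c, µm; 0 recovers the linear law k0 + k1*L
    capture_radius: float = 0.8       # rho_c, µm
    base_binding_rate: float = 0.02   # k_on, 1/s
    transport_speed: float = 9.22     # v_dyn, µm/min (dynein-driven poleward)
    arrival_radius: float = 2.0       # µm
    mt_burn_in: float = 0.0           # aster pre-equilibration before NEBD, min
    model_variant: int = 3
    seed: int = 0

    def __post_init__(self):
        positive = [
            "dt", "t_end", "t_x", "t_m", "chromosome_radius", "viscosity",
            "mt_growth_speed", "mt_shrink_speed",
            "capture_radius", "base_binding_rate", "arrival_radius",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in (
            "temperature", "catastrophe_base", "catastrophe_slope", "catastrophe_knee",
            "transport_speed", "mt_burn_in",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.dt > 0.1:
            raise ValidationError(f"dt must be <= 0.1 s, got {self.dt}")
        if self.t_m >= self.t_x:
            raise ValidationError(f"t_m ({self.t_m}) must be smaller than t_x ({self.t_x})")
        if self.n_chromosomes < 1:
            raise ValidationError(f"n_chromosomes must be >= 1, got {self.n_chromosomes}")
        if self.n_mt_per_aster < 1:
            raise ValidationError(f"n_mt_per_aster must be >= 1, got {self.n_mt_per_aster}")
        if self.model_variant not in (1, 2, 3):
            raise ValidationError(f"model_variant must be 1, 2 or 3, got {self.model_variant}")

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def diffusion_coefficient(params: SimParams) -> float:
    """Stokes–Einstein diffusion coefficient of a chromosome, in µm²/s.

    D = kT / (6 π η r) for a sphere of radius ``chromosome_radius`` in a
    fluid of viscosity ``viscosity`` at temperature ``temperature``.
    With the defaults (r = 0.8 µm, η = 0.1 Pa s, T = 293 K) this gives
    ≈ 2.68e-3 µm²/s.
    """
    r_m = params.chromosome_radius * 1e-6
    d_si = BOLTZMANN_J_PER_K * params.temperature / (6.0 * np.pi * params.viscosity * r_m)
    return d_si * 1e12  # m²/s -> µm²/s


@dataclass
class RngStreams:
    """Independent, seeded random substreams for the simulation modules.

    The same top-level seed always yields the same four substreams
    (chromosome placement, microtubule dynamics, chromosome transport
    noise, capture trials), so a simulation is bit-reproducible on a
    given build.
    """

    seed: int
    placement: np.random.Generator
    microtubules: np.random.Generator
    transport: np.random.Generator
    capture: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "RngStreams":
        ss = np.random.SeedSequence(int(seed))
        children = ss.spawn(4)
        return cls(
            seed=int(seed),
            placement=np.random.Generator(np.random.PCG64(children[0])),
            microtubules=np.random.Generator(np.random.PCG64(children[1])),
            transport=np.random.Generator(np.random.PCG64(children[2])),
            capture=np.random.Generator(np.random.PCG64(children[3])),
        )
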