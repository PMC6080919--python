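"""Gated kinetochore–microtubule binding, poleward transport and the
top-level congression simulation loop.

Three model variants are implemented:

1. classic search-and-capture: chromosomes diffuse in place until an
   astral microtubule passes within reach and binds (emulates the
   actin-depolymerized condition);
2. variant 1 plus the F-actin velocity field that transports chromosomes
   toward the animal pole;
3. variant 2 plus a time gate on the kinetochore binding rate that
   mirrors the disassembly kinetics of the F-actin patches enclosing
   chromosomes: binding is blocked for the first 4 min after NEBD and
   ramps to 10, 30, 70 and 100% of the maximal rate at minutes 4, 5, 6
   and 7.

A chromosome is captured when a microtubule segment passes within
``capture_radius + chromosome_radius`` of its center and a Bernoulli
binding trial at rate ``k_on * gate(t)`` succeeds. Capture is lateral:
the chromosome attaches at the nearest point of the filament and is then
transported poleward along it at the dynein speed ``transport_speed``
until it arrives within ``arrival_radius`` of the centrosome. The
velocity field acts only on free chromosomes; Brownian noise is off
during transport.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    OocyteGeometry,
    RngStreams,
    SimParams,
    ValidationError,
    diffusion_coefficient,
    make_geometry,
)
from .microtubules import MicrotubuleState, nucleate_asters, step_microtubules
from .transport import VelocityField, brownian_sigma, step_free_positions

__all__ = [
    "FREE",
    "CAPTURED",
    "ARRIVED",
    "LOST",
    "STATE_NAMES",
    "GateSchedule",
    "gate_value",
    "SimResult",
    "CohortResult",
    "place_chromosomes",
    "run_simulation",
    "run_cohort",
]

FREE, CAPTURED, ARRIVED, LOST = 0, 1, 2, 3
STATE_NAMES = {FREE: "free", CAPTURED: "captured", ARRIVED: "arrived", LOST: "lost"}


@dataclass(frozen=True)
class GateSchedule:
    """Piecewise-constant, right-continuous kinetochore binding-rate gate.

    ``breakpoints`` is an ordered tuple of (time in min, fraction in [0, 1]);
    the gate holds each fraction from its breakpoint (inclusive) to the
    next. The default ramp blocks binding entirely before minute 4 and
    steps to 10, 30, 70 and 100% at minutes 4, 5, 6 and 7, so the ramp
    spans 4–8 min after NEBD. ``GateSchedule.ramp(start_minute=5)``
    selects the alternative convention with increments at minutes 5–8.
    """

    breakpoints: tuple = ((0.0, 0.0), (4.0, 0.10), (5.0, 0.30), (6.0, 0.70), (7.0, 1.00))

    def __post_init__(self):
        bps = tuple((float(t), float(v)) for t, v in self.breakpoints)
        if not bps:
            raise ValidationError("breakpoints must be non-empty")
        times = [t for t, _ in bps]
        values = [v for _, v in bps]
        if sorted(times) != times or len(set(times)) != len(times):
            raise ValidationError("breakpoint times must be strictly increasing")
        if sorted(values) != values:
            raise ValidationError("gate fractions must be monotone nondecreasing")
        if values[0] < 0 or values[-1] > 1:
            raise ValidationError("gate fractions must lie in [0, 1]")
        object.__setattr__(self, "breakpoints", bps)

    @classmethod
    def constant(cls, value: float = 1.0) -> "GateSchedule":
        return cls(breakpoints=((0.0, value),))

    @classmethod
    def ramp(cls, start_minute: float = 4.0) -> "GateSchedule":
        s = float(start_minute)
        return cls(breakpoints=((0.0, 0.0), (s, 0.10), (s + 1, 0.30), (s + 2, 0.70), (s + 3, 1.00)))

    @property
    def times(self):
        return tuple(t for t, _ in self.breakpoints)

    @property
    def values(self):
        return tuple(v for _, v in self.breakpoints)


def gate_value(t: float, schedule: GateSchedule) -> float:
    """Gate fraction at time ``t`` (min after NEBD)."""
    if t < 0:
        raise ValidationError(f"t must be nonnegative, got {t}")
    idx = bisect.bisect_right(schedule.times, t) - 1
    if idx < 0:
        return 0.0
    return schedule.values[idx]


def place_chromosomes(
    geometry: OocyteGeometry,
    params: SimParams,
    rng: np.random.Generator,
    boundary_margin: float = 1.0,
    min_separation: float = 2.0,
) -> np.ndarray:
    """Initial chromosome positions, uniform over the nuclear volume.

    Rejection-sampled to lie at least ``boundary_margin`` µm inside the
    boundary and ``min_separation`` µm apart pairwise. There are no
    excluded-volume interactions afterwards.
    """
    r_max = geometry.nucleus_radius - boundary_margin
    if r_max <= 0:
        raise ValidationError("boundary_margin leaves no interior volume")
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < params.n_chromosomes:
        attempts += 1
        if attempts > 100000:
            raise ValidationError("chromosome placement failed: constraints too tight")
        cand = rng.uniform(-r_max, r_max, size=3)
        if np.dot(cand, cand) > r_max**2:
            continue
        pos = geometry.nucleus_center + cand
        if accepted and np.min(np.linalg.norm(np.array(accepted) - pos, axis=1)) < min_separation:
            continue
        accepted.append(pos)
    return np.array(accepted)


@dataclass
class SimResult:
    """Outcome of a single simulated oocyte.

    Trajectories are sampled every ``report_interval_s`` seconds (default
    3 s, the experimental frame interval). ``states`` holds the per-frame
    chromosome state codes (see ``STATE_NAMES``); free chromosomes at the
    end of the run are marked lost in ``final_states`` only.
    """

    params: SimParams
    geometry: OocyteGeometry
    gate: GateSchedule
    seed: int
    sample_times_s: np.ndarray          # (F,)
    positions: np.ndarray               # (F, n, 3) µm
    states: np.ndarray                  # (F, n) int8
    initial_positions: np.ndarray       # (n, 3) µm
    capture_times_min: np.ndarray       # (n,), NaN if never captured
    final_states: np.ndarray            # (n,) int8
    mt_records: list = field(default_factory=list)

    @property
    def n_chromosomes(self) -> int:
        return self.initial_positions.shape[0]

    def initial_distances_to_ap(self) -> np.ndarray:
        return np.linalg.norm(self.initial_positions - self.geometry.ap_point, axis=1)

    def events(self, oocyte: int = 0) -> pd.DataFrame:
        """Per-chromosome event table."""
        return pd.DataFrame(
            {
                "oocyte": oocyte,
                "chromosome": np.arange(self.n_chromosomes),
                "initial_distance_um": self.initial_distances_to_ap(),
                "capture_time_min": self.capture_times_min,
                "final_state": [STATE_NAMES[s] for s in self.final_states],
            }
        )

    def to_trajectories(self, oocyte: int = 0) -> pd.DataFrame:
        """Long-format trajectory table (oocyte, chromosome, t_s, x_um, y_um, z_um)."""
        n_frames, n_chrom, _ = self.positions.shape
        return pd.DataFrame(
            {
                "oocyte": np.full(n_frames * n_chrom, oocyte),
                "chromosome": np.tile(np.arange(n_chrom), n_frames),
                "t_s": np.repeat(self.sample_times_s, n_chrom),
                "x_um": self.positions[:, :, 0].ravel(),
                "y_um": self.positions[:, :, 1].ravel(),
                "z_um": self.positions[:, :, 2].ravel(),
            }
        ).sort_values(["oocyte", "chromosome", "t_s"], ignore_index=True)


def _capture_trials(
    free_pos: np.ndarray,
    mts: MicrotubuleState,
    aster_slices: list,
    geometry: OocyteGeometry,
    rho_eff: float,
    p_bind: float,
    rng: np.random.Generator,
):
    """Attempt binding for each free chromosome; return list of
    (row_in_free, mt_index, attach_s) for successful captures.

    Candidate filaments are those whose segment passes within ``rho_eff``
    (capture radius + chromosome radius) of the chromosome center; each
    candidate is tried nearest-first with success probability ``p_bind``.
    Chromosomes farther from a centrosome than the aster's longest
    filament plus ``rho_eff`` are skipped without computing distances.
    """
    captures = []
    taken = np.zeros(free_pos.shape[0], dtype=bool)
    for a, sl in enumerate(aster_slices):
        lengths = mts.lengths[sl]
        reach = lengths.max() + rho_eff
        rel = free_pos - geometry.centrosome_positions[a]
        w2 = np.einsum("ij,ij->i", rel, rel)
        near = np.nonzero(~taken & (w2 <= reach * reach))[0]
        if near.size == 0:
            continue
        proj = rel[near] @ mts.directions[sl].T        # (k, n_per)
        s_att = np.clip(proj, 0.0, lengths)            # nearest point on segment
        d2 = w2[near, None] - s_att * (2.0 * proj - s_att)
        hit = d2 <= rho_eff * rho_eff
        for row in np.nonzero(hit.any(axis=1))[0]:
            cols = np.nonzero(hit[row])[0]
            order = np.argsort(d2[row, cols])
            u = rng.random(cols.size)
            success = np.nonzero(u < p_bind)[0]
            if success.size:
                j = cols[order[success[0]]]
                captures.append((int(near[row]), sl.start + int(j), float(s_att[row, j])))
                taken[near[row]] = True
    return captures


def run_simulation(
    params: SimParams,
    geometry: OocyteGeometry | None = None,
    gate: GateSchedule | None = None,
    report_interval_s: float = 3.0,
    mt_record_interval_s: float | None = None,
) -> SimResult:
    """Simulate one oocyte from NEBD (t = 0) to ``t_end``.

    Per step: microtubules are advanced, free chromosomes move (velocity
    field per variant, plus Brownian noise), capture is attempted under
    the gate, and captured chromosomes are transported poleward. Variants
    1 and 2 always use the constant-1 gate; variant 3 defaults to the
    4–8 min ramp unless ``gate`` is given explicitly.

    ``mt_record_interval_s`` optionally records the microtubule population
    (aster, direction, length, state) every so many seconds for
    visualization.
    """
    if geometry is None:
        geometry = make_geometry()
    if params.model_variant in (1, 2):
        gate = GateSchedule.constant(1.0)
    elif gate is None:
        gate = GateSchedule.ramp()

    rngs = RngStreams.from_seed(params.seed)
    n = params.n_chromosomes
    dt_s = params.dt
    dt_min = dt_s / 60.0

    positions = place_chromosomes(geometry, params, rngs.placement)
    initial_positions = positions.copy()
    state = np.full(n, FREE, dtype=np.int8)
    capture_times = np.full(n, np.nan)
    attached_mt = np.full(n, -1, dtype=np.int64)
    attach_s = np.zeros(n)

    mts = nucleate_asters(geometry, params, rngs.microtubules)
    burn_in_steps = int(round(params.mt_burn_in * 60.0 / dt_s))
    for _ in range(burn_in_steps):
        step_microtubules(mts, geometry, params, rngs.microtubules)

    n_per = params.n_mt_per_aster
    aster_slices = [slice(0, n_per), slice(n_per, 2 * n_per)]
    field_obj = (
        VelocityField(p=geometry.ap_point, t_x=params.t_x, t_m=params.t_m)
        if params.model_variant >= 2
        else None
    )
    sigma = brownian_sigma(params)
    rho_eff = params.capture_radius + params.chromosome_radius
    ds_transport = params.transport_speed * dt_min

    n_steps = int(round(params.t_end * 60.0 / dt_s))
    report_every = max(1, int(round(report_interval_s / dt_s)))
    mt_every = (
        max(1, int(round(mt_record_interval_s / dt_s))) if mt_record_interval_s else None
    )

    frames_t: list[float] = []
    frames_pos: list[np.ndarray] = []
    frames_state: list[np.ndarray] = []
    mt_records: list = []

    def record(step_idx: int) -> None:
        frames_t.append(step_idx * dt_s)
        frames_pos.append(positions.copy())
        frames_state.append(state.copy())

    def record_mts(step_idx: int) -> None:
        mt_records.append(
            (
                step_idx * dt_s,
                pd.DataFrame(
                    {
                        "aster": mts.aster,
                        "dx": mts.directions[:, 0],
                        "dy": mts.directions[:, 1],
                        "dz": mts.directions[:, 2],
                        "length_um": mts.lengths,
                        "state": np.where(mts.growing, "growing", "shrinking"),
                    }
                ),
            )
        )

    record(0)
    if mt_every:
        record_mts(0)

    for step in range(1, n_steps + 1):
        t_min = step * dt_min

        if not np.any((state == FREE) | (state == CAPTURED)):
            # every chromosome has arrived; remaining frames are static
            if step % report_every == 0:
                record(step)
            if mt_every and step % mt_every == 0:
                record_mts(step)
            continue

        step_microtubules(mts, geometry, params, rngs.microtubules)

        free = np.nonzero(state == FREE)[0]
        if free.size:
            positions[free] = step_free_positions(
                positions[free], t_min, field_obj, params, geometry, rngs.transport, sigma=sigma
            )

            g = gate_value(t_min, gate)
            if g > 0.0:
                p_bind = -np.expm1(-params.base_binding_rate * g * dt_s)
                captures = _capture_trials(
                    positions[free], mts, aster_slices, geometry, rho_eff, p_bind, rngs.capture
                )
                for row, mt_idx, s_att in captures:
                    ci = free[row]
                    state[ci] = CAPTURED
                    capture_times[ci] = t_min
                    attached_mt[ci] = mt_idx
                    attach_s[ci] = s_att
                    positions[ci] = mts.origins[mt_idx] + s_att * mts.directions[mt_idx]

        carried = np.nonzero(state == CAPTURED)[0]
        for ci in carried:
            mt_idx = attached_mt[ci]
            if mts.renucleated[mt_idx]:
                # the filament fully depolymerized: the chromosome is released
                state[ci] = FREE
                attached_mt[ci] = -1
                continue
            s = attach_s[ci]
            if mts.lengths[mt_idx] < s:
                # lateral attachment slides with a shrinking tip
                s = mts.lengths[mt_idx]
            s = max(s - ds_transport, 0.0)
            attach_s[ci] = s
            positions[ci] = mts.origins[mt_idx] + s * mts.directions[mt_idx]
            if s <= params.arrival_radius:
                state[ci] = ARRIVED
                attached_mt[ci] = -1

        if step % report_every == 0:
            record(step)
        if mt_every and step % mt_every == 0:
            record_mts(step)

    final_states = state.copy()
    final_states[final_states == FREE] = LOST

    return SimResult(
        params=params,
        geometry=geometry,
        gate=gate,
        seed=params.seed,
        sample_times_s=np.array(frames_t),
        positions=np.array(frames_pos),
        states=np.array(frames_state),
        initial_positions=initial_positions,
        capture_times_min=capture_times,
        final_states=final_states,
        mt_records=mt_records,
    )


@dataclass
class CohortResult:
    """Results of ``n_oocytes`` independent runs (seeds base_seed + i)."""

    results: list

    def events(self) -> pd.DataFrame:
        return pd.concat(
            [r.events(oocyte=i) for i, r in enumerate(self.results)], ignore_index=True
        )

    def trajectories(self) -> pd.DataFrame:
        return pd.concat(
            [r.to_trajectories(oocyte=i) for i, r in enumerate(self.results)],
            ignore_index=True,
        )

    def capture_times(self) -> np.ndarray:
        """Pooled capture times (min) of all captured chromosomes."""
        times = np.concatenate([r.capture_times_min for r in self.results])
        return times[~np.isnan(times)]


def run_cohort(
    n_oocytes: int,
    params: SimParams,
    base_seed: int | None = None,
    geometry: OocyteGeometry | None = None,
    gate: GateSchedule | None = None,
) -> CohortResult:
    """Run ``n_oocytes`` independent simulations with seeds base_seed + i."""
    if n_oocytes < 1:
        raise ValidationError(f"n_oocytes must be >= 1, got {n_oocytes}")
    if base_seed is None:
        base_seed = params.seed
    results = [
        run_simulation(params.with_(seed=base_seed + i), geometry=geometry, gate=gate)
        for i in range(n_oocytes)
    ]
    return CohortResult(results=results)
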