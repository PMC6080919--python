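"""Labeled synthetic data emulating the live-imaging study conditions.

Three generators, each returning both the data and its ground truth so
that every analysis stage can be benchmarked without real recordings:

* two-phase chromosome trajectories (slow advective/diffusive phase, then
  fast directed poleward transport from a drawn switch time at a drawn
  speed), sampled at the experimental 3-s frame interval;
* normalized F-actin patch intensity traces (flat background before NEBD,
  rise to a peak, fall back to background) for control and
  actin-depolymerized (Latrunculin-like) kinetics;
* small two-channel 4D image stacks with chromosomes and patches rendered
  as Gaussian blobs, for end-to-end tests of the spherical-ROI
  quantification.

Default condition parameters are the measured study values: post-switch
speed 9.22 ± 2.86 µm/min; switch times 9.21 ± 2.36 min (control) and
6.16 ± 3.92 min (Latrunculin, only for chromosomes inside the ~30 µm
capture range — distal ones are lost); patch intensity peaking at ~5 min
and returning to background at ~8 min (control) or ~4 min (Latrunculin).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import erf

import numpy as np
import pandas as pd

from .core import SimParams, diffusion_coefficient, make_geometry, ValidationError
from .engine import place_chromosomes
from .transport import VelocityField

__all__ = ["SyntheticSpec", "make_trajectories", "make_intensity_traces", "make_image_stack"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``onset_min``, ``peak_min`` and ``return_min`` are the observable
    patch timings: the times at which a normalized trace crosses the
    detection band 1 + ``epsilon`` on the way up, peaks, and falls back
    through it. The trace template is constructed so that these drawn
    times are exactly what an unbiased timing estimator should recover,
    independent of the per-chromosome amplitude.
    """

    condition: str = "control"
    n_oocytes: int = 13
    n_chromosomes: int = 22
    frame_interval_s: float = 3.0
    t_end_min: float = 18.0
    # two-phase trajectory parameters
    speed_mean: float = 9.22          # µm/min, post-switch
    speed_sd: float = 2.86
    switch_mean: float = 9.21         # min after NEBD
    switch_sd: float = 2.36
    capture_range_um: float = 30.0    # Latrunculin: beyond this, no capture
    arrival_radius_um: float = 2.0
    phase2_jitter_um: float = 0.1     # per-axis localization jitter, µm/frame
    diffusion_um2_s: float | None = None  # None = Stokes-Einstein default
    # patch-trace parameters
    n_traces: int = 100
    trace_t_start_min: float = -2.0
    trace_t_end_min: float = 14.0
    onset_min: float = 1.5
    peak_min: float = 5.0
    return_min: float = 8.0
    amplitude_range: tuple = (2.0, 6.0)
    trace_noise: float = 0.05         # multiplicative Gaussian SD
    epsilon: float = 0.2              # detection band above background
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("control", "latrunculin"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.speed_sd < 0 or self.switch_sd < 0 or self.trace_noise < 0:
            raise ValidationError("spread parameters must be nonnegative")
        if not (self.onset_min < self.peak_min < self.return_min):
            raise ValidationError("patch timings must satisfy onset < peak < return")

    @classmethod
    def control(cls, **kwargs) -> "SyntheticSpec":
        return cls(condition="control", **kwargs)

    @classmethod
    def latrunculin(cls, **kwargs) -> "SyntheticSpec":
        """Actin-depolymerized condition: no advection, earlier capture of
        in-range chromosomes, premature patch disassembly at ~4 min."""
        defaults = dict(
            switch_mean=6.16,
            switch_sd=3.92,
            peak_min=2.5,
            return_min=4.0,
        )
        defaults.update(kwargs)
        return cls(condition="latrunculin", **defaults)

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def _truncated_normal(rng, mean, sd, low, size):
    """Draw from N(mean, sd) truncated to values > low, by resampling."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    bad = out <= low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out


def make_trajectories(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate two-phase chromosome trajectories with ground truth.

    Phase 1: F-actin velocity-field advection plus Brownian noise
    (control) or pure Brownian motion (latrunculin). Phase 2, from the
    drawn switch time: straight-line motion toward the AP point at the
    drawn speed until within ``arrival_radius_um`` of it, then
    stationary, with per-frame localization jitter.

    Returns ``(trajectories, truth)``: the canonical long-format table
    and one truth row per track (initial distance, switch time, speed,
    lost flag). Lost tracks (latrunculin, outside the capture range)
    have NaN switch time and speed.
    """
    geometry = make_geometry()
    params = SimParams()  # physical constants: D, t_x, t_m
    d_coef = spec.diffusion_um2_s if spec.diffusion_um2_s is not None else diffusion_coefficient(params)
    field = VelocityField(p=geometry.ap_point, t_x=params.t_x, t_m=params.t_m)
    p = geometry.ap_point

    dt_s = spec.frame_interval_s
    times_s = np.arange(0.0, spec.t_end_min * 60.0 + dt_s / 2, dt_s)
    times_min = times_s / 60.0
    sigma = np.sqrt(2.0 * d_coef * dt_s)

    root = np.random.SeedSequence(spec.seed)
    traj_rows = []
    truth_rows = []
    for oocyte, child in enumerate(root.spawn(spec.n_oocytes)):
        rng = np.random.Generator(np.random.PCG64(child))
        start = place_chromosomes(geometry, params.with_(n_chromosomes=spec.n_chromosomes), rng)
        d0 = np.linalg.norm(start - p, axis=1)

        switch = _truncated_normal(rng, spec.switch_mean, spec.switch_sd, 0.0, spec.n_chromosomes)
        speed = _truncated_normal(rng, spec.speed_mean, spec.speed_sd, 0.0, spec.n_chromosomes)
        lost = np.zeros(spec.n_chromosomes, dtype=bool)
        if spec.condition == "latrunculin":
            lost = d0 > spec.capture_range_um
        switch[lost] = np.nan
        speed[lost] = np.nan

        for c in range(spec.n_chromosomes):
            x = start[c].copy()
            pos = np.empty((len(times_s), 3))
            pos[0] = x
            transported = False
            for k in range(1, len(times_s)):
                t0, t1 = times_min[k - 1], times_min[k]
                if not transported and not lost[c] and t1 >= switch[c]:
                    transported = True
                if transported:
                    to_p = p - x
                    dist = np.linalg.norm(to_p)
                    step = speed[c] * dt_s / 60.0
                    if dist > spec.arrival_radius_um and dist > 0:
                        x = x + to_p / dist * min(step, dist - spec.arrival_radius_um)
                else:
                    if spec.condition == "control" and t0 <= field.t_m:
                        # exact advective propagation over one frame
                        frac = (field.t_x - min(t1, field.t_m)) / (field.t_x - t0)
                        x = p + (x - p) * frac
                    x = x + sigma * rng.standard_normal(3)
                pos[k] = x
            jitter = spec.phase2_jitter_um * rng.standard_normal(pos.shape)
            pos = pos + jitter
            traj_rows.append(
                pd.DataFrame(
                    {
                        "oocyte": oocyte,
                        "chromosome": c,
                        "t_s": times_s,
                        "x_um": pos[:, 0],
                        "y_um": pos[:, 1],
                        "z_um": pos[:, 2],
                    }
                )
            )
            truth_rows.append(
                {
                    "oocyte": oocyte,
                    "chromosome": c,
                    "initial_distance_um": d0[c],
                    "switch_time_min": switch[c],
                    "speed_um_min": speed[c],
                    "lost": bool(lost[c]),
                }
            )

    traj = pd.concat(traj_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return traj, truth


def _trace_template(times_min, onset, peak, ret, amplitude, eps):
    """Normalized patch-intensity template.

    Flat at 1 before the rise; linear rise through the detection band
    1 + eps exactly at ``onset`` reaching ``amplitude`` at ``peak``;
    cosine fall crossing the band exactly at ``ret`` and relaxing to 1
    shortly after. The crossing times are amplitude-independent by
    construction.
    """
    a = amplitude
    r = eps / (a - 1.0)
    # rise starts slightly before the band crossing so the crossing is at onset
    t_start = (onset - r * peak) / (1.0 - r)
    theta = np.arccos(2.0 * r - 1.0)  # band-crossing phase of the cosine fall
    t_base = peak + (ret - peak) * np.pi / theta  # where the fall reaches 1

    y = np.ones_like(times_min)
    rise = (times_min >= t_start) & (times_min < peak)
    y[rise] = 1.0 + (a - 1.0) * (times_min[rise] - t_start) / (peak - t_start)
    fall = (times_min >= peak) & (times_min < t_base)
    phase = np.pi * (times_min[fall] - peak) / (t_base - peak)
    y[fall] = 1.0 + (a - 1.0) * (1.0 + np.cos(phase)) / 2.0
    return y


def make_intensity_traces(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate raw patch-intensity traces with ground-truth timings.

    Each trace is the normalized template scaled by a random background
    level, with multiplicative Gaussian noise, sampled every
    ``frame_interval_s`` from ``trace_t_start_min`` (before NEBD) to
    ``trace_t_end_min``. Returns ``(traces, truth)``; traces carry
    columns (trace, t_min, raw).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    dt_min = spec.frame_interval_s / 60.0
    times = np.arange(spec.trace_t_start_min, spec.trace_t_end_min + dt_min / 2, dt_min)

    rows = []
    truth = []
    lo, hi = spec.amplitude_range
    for i in range(spec.n_traces):
        amplitude = rng.uniform(lo, hi)
        background = rng.uniform(50.0, 200.0)
        y = _trace_template(
            times, spec.onset_min, spec.peak_min, spec.return_min, amplitude, spec.epsilon
        )
        raw = background * y
        if spec.trace_noise > 0:
            raw = raw * (1.0 + spec.trace_noise * rng.standard_normal(len(times)))
        rows.append(pd.DataFrame({"trace": i, "t_min": times, "raw": raw}))
        truth.append(
            {
                "trace": i,
                "onset_min": spec.onset_min,
                "peak_min": spec.peak_min,
                "return_min": spec.return_min,
                "amplitude": amplitude,
                "background": background,
            }
        )
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth)


def make_image_stack(
    spec: SyntheticSpec,
    shape_zyx: tuple = (40, 40, 40),
    voxel_size_um: float = 0.5,
    n_frames: int = 80,
    frame_interval_s: float = 12.0,
    n_chromosomes: int = 2,
    background: float = 100.0,
    patch_sigma_um: float = 1.0,
    chromosome_sigma_um: float = 0.8,
    roi_radius_um: float = 2.5,
    noise: bool = True,
):
    """Render a small two-channel 4D stack with ground truth.

    Chromosomes perform slow Brownian motion inside the volume; channel 0
    holds the chromosome label (Gaussian blobs of constant brightness),
    channel 1 the patch label: a uniform background plus one Gaussian
    blob per chromosome whose integrated intensity follows the
    patch-kinetics template, scaled such that the total intensity in a
    ``roi_radius_um`` sphere, normalized to the pre-NEBD background,
    reproduces the template value. Optional Poisson noise emulates the
    camera. Frame 0 corresponds to ``trace_t_start_min``.

    Returns ``(stack, positions, truth)``: a float array of shape
    (T, 2, Z, Y, X), a DataFrame of ground-truth centers (chromosome,
    frame, t_min, x/y/z_um) and the per-chromosome timing truth table.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed + 7)))
    nz, ny, nx = shape_zyx
    extent = np.array([nx, ny, nz]) * voxel_size_um  # x, y, z
    times_min = spec.trace_t_start_min + np.arange(n_frames) * frame_interval_s / 60.0

    margin = roi_radius_um + 3.0 * patch_sigma_um
    for e in extent:
        if e <= 2 * margin:
            raise ValidationError("stack too small for the ROI and blob size")
    centers0 = rng.uniform(margin, extent - margin, size=(n_chromosomes, 3))
    step_sd = 0.02  # µm per frame; chromosomes are nearly static in the crop

    # voxel-center coordinate grids (x fastest)
    zc = (np.arange(nz) + 0.5) * voxel_size_um
    yc = (np.arange(ny) + 0.5) * voxel_size_um
    xc = (np.arange(nx) + 0.5) * voxel_size_um

    # number of voxel centers inside the ROI sphere (for intensity scaling)
    rr = np.arange(-int(np.ceil(roi_radius_um / voxel_size_um)) - 1,
                   int(np.ceil(roi_radius_um / voxel_size_um)) + 2)
    gz, gy, gx = np.meshgrid(rr, rr, rr, indexing="ij")
    n_roi_vox = int(np.count_nonzero(
        (gz**2 + gy**2 + gx**2) * voxel_size_um**2 <= roi_radius_um**2
    ))
    roi_background_sum = background * n_roi_vox
    # fraction of a 3D Gaussian's mass inside the ROI sphere (Maxwell CDF);
    # the blob is scaled up by 1/fraction so the ROI sum matches the template
    a = roi_radius_um / patch_sigma_um
    in_roi_fraction = float(
        erf(a / np.sqrt(2.0)) - np.sqrt(2.0 / np.pi) * a * np.exp(-a * a / 2.0)
    )

    amplitudes = rng.uniform(*spec.amplitude_range, size=n_chromosomes)
    stack = np.empty((n_frames, 2, nz, ny, nx), dtype=float)
    pos_rows = []
    truth = []
    for c in range(n_chromosomes):
        truth.append(
            {
                "chromosome": c,
                "onset_min": spec.onset_min,
                "peak_min": spec.peak_min,
                "return_min": spec.return_min,
                "amplitude": amplitudes[c],
            }
        )

    def add_blob(vol, center, sigma, integral):
        """Add a 3D Gaussian of given integrated intensity (in voxel sum units)."""
        cx, cy, cz = center
        half = 4.0 * sigma
        xs = slice(*np.clip([int((cx - half) / voxel_size_um), int((cx + half) / voxel_size_um) + 2], 0, nx))
        ys = slice(*np.clip([int((cy - half) / voxel_size_um), int((cy + half) / voxel_size_um) + 2], 0, ny))
        zs = slice(*np.clip([int((cz - half) / voxel_size_um), int((cz + half) / voxel_size_um) + 2], 0, nz))
        gx_ = xc[xs] - cx
        gy_ = yc[ys] - cy
        gz_ = zc[zs] - cz
        g = np.exp(
            -(gz_[:, None, None] ** 2 + gy_[None, :, None] ** 2 + gx_[None, None, :] ** 2)
            / (2.0 * sigma**2)
        )
        norm = (2.0 * np.pi * sigma**2) ** 1.5 / voxel_size_um**3
        vol[zs, ys, xs] += integral / norm * g

    centers = centers0.copy()
    for f, t in enumerate(times_min):
        chrom_ch = np.zeros((nz, ny, nx))
        patch_ch = np.full((nz, ny, nx), background)
        for c in range(n_chromosomes):
            if f > 0:
                centers[c] = np.clip(
                    centers[c] + step_sd * rng.standard_normal(3), margin, extent - margin
                )
            y = _trace_template(
                np.array([t]), spec.onset_min, spec.peak_min, spec.return_min,
                amplitudes[c], spec.epsilon,
            )[0]
            add_blob(chrom_ch, centers[c], chromosome_sigma_um, 5000.0)
            if y > 1.0:
                add_blob(
                    patch_ch, centers[c], patch_sigma_um,
                    (y - 1.0) * roi_background_sum / in_roi_fraction,
                )
            pos_rows.append(
                {
                    "chromosome": c,
                    "frame": f,
                    "t_min": t,
                    "x_um": centers[c, 0],
                    "y_um": centers[c, 1],
                    "z_um": centers[c, 2],
                }
            )
        stack[f, 0] = chrom_ch
        stack[f, 1] = patch_ch

    if noise:
        stack = rng.poisson(np.maximum(stack, 0.0)).astype(float)
    return stack, pd.DataFrame(pos_rows), pd.DataFrame(truth)
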