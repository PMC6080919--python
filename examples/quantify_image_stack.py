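"""Spherical-ROI quantification of a rendered 4D two-channel stack.

Renders a small synthetic stack (channel 0: chromosomes, channel 1:
patch label over a uniform background), measures the total patch
intensity in a 2.5-µm-radius sphere around each tracked chromosome at
every time point, normalizes to the pre-NEBD background, and extracts
the patch timings. The recovered times should match the generator's
control kinetics (peak ~5 min, background return ~8 min).
"""

from congression import (
    SyntheticSpec,
    make_image_stack,
    normalize_trace,
    patch_timing,
    quantify_stack,
)

spec = SyntheticSpec.control(seed=5)
stack, positions, truth = make_image_stack(
    spec, shape_zyx=(40, 40, 40), voxel_size_um=0.5,
    n_frames=80, frame_interval_s=12.0, n_chromosomes=2,
)
print(f"stack: {stack.shape} (T, C, Z, Y, X), voxel 0.5 um, frame every 12 s")

traces = quantify_stack(stack, positions, radius_um=2.5, voxel_size_um=0.5, channel=1)
for chrom, g in traces.groupby("chromosome"):
    trace = normalize_trace(g.t_min.to_numpy(), g.raw.to_numpy(), chromosome=int(chrom))
    t = patch_timing(trace)
    print(f"chromosome {chrom}: peak {t.peak_min:.1f} min, "
          f"background return {t.disassembly_min:.1f} min "
          f"(generator: peak 5.0, return 8.0)")
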