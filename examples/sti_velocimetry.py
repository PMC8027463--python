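"""Axial velocity from a space-time image (STI).

Builds a synthetic STI whose streaks advect at a known slope, degrades
it to 6 dB SNR, and shows that the CWT-filtered orientation search still
recovers the axial speed. Slope (samples/frame) x dx / dt converts to
mm/s: 5 x 1.5 um / (1/60 s) = 0.45 mm/s.
"""

from hemoflow.synthetic import generate_sti
from hemoflow.velocimetry import estimate_axial_velocity

sti, truth = generate_sti(
    slope_samples_per_frame=5.0, shape=(100, 120), dx_um=1.5, dt_s=1 / 60,
    noise_sigma=0.5, seed=0,
)
est = estimate_axial_velocity(sti)

print(f"true Va      = {truth['va_mm_s']:.3f} mm/s")
print(f"estimated Va = {est.va_mm_s:.3f} mm/s (quality {est.quality:.2f})")
print(f"streak slope = {est.slope_samples_per_frame:+.2f} samples/frame")
# quality is the peak contrast of the orientation-energy profile;
# values near 0 mean "no observable flow" and are excluded downstream.
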