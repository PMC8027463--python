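"""From diameter and axial velocity to flow and wall shear rate.

Evaluates the profile-factor function, volumetric flow and wall shear
rate at the healthy-cohort mean values (D = 21.43 um, Va = 0.53 mm/s)
and shows the diameter grouping used for stratified comparisons.
"""

from hemoflow import hemodynamics as hd

d, va = 21.43, 0.53
vs = hd.cross_sectional_velocity(va, d)
print(f"Vs  = {vs:.4f} mm/s   (profile factor {va / vs:.3f})")
print(f"Q   = {hd.volume_flow(vs, d):.1f} pl/s")
print(f"WSR = {hd.wall_shear_rate(vs, d):.1f} 1/s")

for dia in (9.12, 13.55, 19.16, 27.81):
    print(f"D = {dia:5.2f} um -> group {hd.assign_group(dia)}")
# narrow vessels (D <= 0.6 x 7.65 um) carry cells in single file, so
# Vs equals Va there; wider vessels divide by the blunted-profile factor.
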