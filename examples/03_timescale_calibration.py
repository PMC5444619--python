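"""The cardiac-cycle timescale experiment and recruitment calibration.

Evaluates hourly leukocyte transendothelial migration (TEM) on a
1.0 mm-plaque artery under three WSS evaluation policies: the full
pulsatile cycle (80 snapshots at 0.01 s), the peak-systole snapshot, and a
single mean-steady-flow field. The recruitment scale kappa is fixed so the
full-cycle expectation is 16 TEM/h on this fixture, then reused unchanged
for the 1.5 mm fixture.

Takes a few minutes (160 flow solves).
"""

from atherosim.experiments import (build_plaque_fixture, calibrate_kappa,
                                   cycle_wss_fields, timescale_experiment)

lat, _ = build_plaque_fixture(1000.0)
fields = cycle_wss_fields(lat)
kappa = calibrate_kappa(fields)
print(f"calibrated kappa = {kappa:.4g}  (full-cycle expectation = 16 TEM/h)")

for radius_um in (1000.0, 1500.0):
    res = timescale_experiment(radius_um, kappa, seeds=(0, 1, 2),
                               phase_fields=fields if radius_um == 1000.0
                               else None)
    s = res["sampled"]
    print(f"\nplaque radius {radius_um / 1000:.1f} mm (TEM per hour, "
          f"3-seed means):")
    print(f"  full cycle   : {s['full_cycle']:6.1f}")
    print(f"  peak systole : {s['peak_systole']:6.1f}")
    print(f"  steady mean  : {s['steady_mean']:6.1f}")
# The 1.5 mm prediction (~26/h) and the steady-flow deficit (~7/h on the
# 1.0 mm fixture) fall out of the frozen calibration: bigger plaques carve
# larger low-shear zones, while a steady mean flow never visits the
# low-flow phases of the cycle that recruit most leukocytes.
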