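"""Wall shear stress over a stenosed artery: backends and the cardiac cycle.

Computes the WSS field with the fast 1D (Poiseuille) estimator and the
axisymmetric Navier-Stokes backend, and shows why they differ: only the
flow solve captures the post-stenotic separation zone of low shear, which
is where leukocytes preferentially enter the wall.
"""

import numpy as np

from atherosim import FlowWaveform, estimate_wss
from atherosim.experiments import build_plaque_fixture
from atherosim.lattice import EC

lat, _pop = build_plaque_fixture(1500.0)     # 'big' fixture, ~29 % stenosis
wf = FlowWaveform.default()
print(f"waveform: period {wf.period_s} s, {len(wf.times_s)} samples, "
      f"mean Q {wf.mean_q * 1e6:.2f} ml/s, peak {wf.peak_systolic_q * 1e6:.2f} ml/s")

throat = int(np.argmin(lat.lumen_count_per_plane()))
for backend in ("poiseuille", "axisym"):
    field = estimate_wss(lat, wf.mean_q, backend=backend)
    tau = np.array([
        field.values[:, :, z][lat.patch_class[:, :, z] == EC].mean()
        for z in range(lat.nz)])
    low = int((tau < 1.2).sum())
    print(f"\n{backend:10s}: throat tau = {tau[throat]:.2f} Pa, "
          f"inlet tau = {tau[2]:.2f} Pa")
    print(f"{'':10s}  planes with tau < 1.2 Pa (recruitment-permissive): {low}")
    print(f"{'':10s}  distal band tau (throat+3..+12): "
          f"{tau[throat + 3: throat + 12].mean():.2f} Pa")
# The 1D estimate can only raise shear at the throat (tau ~ 1/r^3); the
# axisymmetric solve additionally produces the low-shear recirculation zone
# distal to the throat where adhesion rules activate.
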