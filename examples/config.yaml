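# Example simulation configuration for the `atherosim run` CLI.
# Keys mirror atherosim.simulation.SimulationConfig.

geometry:
  lumen_radius_um: 1000.0
  wall_thickness_um: 600.0
  length_um: 2000.0
  plaques: []          # list of {center_um: [x, y, z], radius_um: r}

capacity_fraction: 0.40  # 0.04 = accelerated growth mode
duration_ticks: 240      # 1 tick = 1 hour
seed: 0
insult: default          # the 15-leukocyte mid-wall insult, or omit

wss:
  backend: axisym        # axisym | poiseuille
  policy: peak_systole   # peak_systole | steady_mean
  handshake: per_lumen_change   # or accelerated (+ quota)

recruitment:
  kappa: 2.625e-5         # WSS-pathway scale (full-cycle calibration)
  stiffness_kpa: 3.0
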