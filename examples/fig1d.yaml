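# Spiral in the cAF sheet under constant, uniform, global sub-threshold
# illumination (0.092 mW/mm^2, 5 s): the spiral persists (no breakup).
# Load a spiral initial condition first (see README); this config describes
# the illumination phase.
geometry: {kind: sheet, nx: 512, ny: 512}
params: caf
numerics: {dt: 0.02, dx: 0.022, D: 0.0023, duration: 5000.0}
light: {mode: constant, ee: 0.092}
recorders:
  trace_sites: [[128, 128], [128, 384], [384, 384], [384, 128], [256, 256]]
  trace_every: 1.0
  frame_every: 10.0
out: fig1d.h5
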