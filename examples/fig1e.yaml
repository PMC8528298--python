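# Same irradiance applied as a 1.0 Hz periodic perturbation (500 ms pulses):
# spiral breakup via conduction blocks.
geometry: {kind: sheet, nx: 512, ny: 512}
params: caf
numerics: {dt: 0.02, dx: 0.022, D: 0.0023, duration: 5000.0}
light: {mode: pulsed, ee: 0.092, freq_hz: 1.0, pw_ms: 500.0}
recorders:
  trace_sites: [[128, 128], [128, 384], [384, 384], [384, 128], [256, 256]]
  trace_every: 1.0
  frame_every: 10.0
out: fig1e.h5
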