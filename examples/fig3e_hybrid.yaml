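# Hybrid geometry: 512 x 512 sheet driving a 1536 x 30 strip; pulsed light
# confined to the strip (region x >= 512) produces conduction block away
# from the spiral.
geometry: {kind: hybrid, nx: 512, ny: 512, strip_nx: 1536, strip_ny: 30}
params: caf
numerics: {dt: 0.02, dx: 0.022, D: 0.0023, duration: 5000.0}
light:
  mode: pulsed
  ee: 0.092
  freq_hz: 1.0
  pw_ms: 500.0
  region: {x0: 512}
recorders: {trace_sites: [[1024, 256], [1800, 256]], trace_every: 1.0, frame_every: 10.0}
out: fig3e.h5
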