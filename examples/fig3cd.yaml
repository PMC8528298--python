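# Pseudo-1D cable (512 x 10) paced electrically from the left boundary at
# 11.5 Hz under whole-domain 1.0 Hz pulsed light (Fig 3D condition; set
# ee: 0 for the dark control of Fig 3C).
geometry: {kind: cable, nx: 512, ny: 10}
params: caf
numerics: {dt: 0.02, dx: 0.022, D: 0.0023, duration: 3000.0}
pace: {amplitude: 33.0, duration: 2.0, period: 86.96, region: left-edge}
light: {mode: pulsed, ee: 0.092, freq_hz: 1.0, pw_ms: 500.0}
recorders: {trace_sites: [[256, 5]], trace_every: 1.0, frame_every: 5.0}
out: fig3cd.h5
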