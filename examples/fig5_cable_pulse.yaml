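# 1000 ms light pulse applied to a plane wave in the 512 x 10 cable:
# wave-profile pinching and post-pulse recovery along y = 5.
geometry: {kind: cable, nx: 512, ny: 10}
params: caf
numerics: {dt: 0.02, dx: 0.022, D: 0.0023, duration: 1500.0}
pace: {amplitude: 33.0, duration: 2.0, period: 1000000.0, region: left-edge}
light: {mode: pulsed, ee: 0.092, freq_hz: 0.5, pw_ms: 1000.0, t_on: 60.0}
recorders: {trace_sites: [[256, 5]], trace_every: 1.0, frame_every: 5.0}
out: fig5.h5
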