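# Electrical analogue of the pulsed-light protocol: global sub-threshold
# current pulses, 1.0 Hz, 20 ms (O(0.1 APD)), on the spiral sheet.
geometry: {kind: sheet, nx: 512, ny: 512}
params: caf
numerics: {dt: 0.02, dx: 0.022, D: 0.0023, duration: 5000.0}
pace: {amplitude: 2.0, duration: 20.0, period: 1000.0, region: null}
recorders: {trace_sites: [[256, 256]], trace_every: 1.0, frame_every: 10.0}
out: s3.h5
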