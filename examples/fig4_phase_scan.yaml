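# Single-cell phase scan is a protocol driver, not a plain simulation:
#   optocardiax phase-scan --params caf --ee 0.092 --pw 100
# This config documents the underlying cell setup.
geometry: {kind: cell}
params: caf
numerics: {dt: 0.02, duration: 1000.0}
light: {mode: pulsed, ee: 0.092, freq_hz: 1.0, pw_ms: 100.0}
out: fig4_cell.h5
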