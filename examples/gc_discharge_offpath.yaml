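# Seven-site off-path discharge protocol on a synthetic granule cell.
# Run: dendrinh simulate --config examples/gc_discharge_offpath.yaml --out out/
task: protocol.discharge
seed: 1
cell:
  cell_type: GC
  spiking: true
params:
  g_exc_grid_ns: [10, 18, 26, 34, 42]
  condition: off_path
  n_trials: 40
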