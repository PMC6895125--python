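# Inhibitory-effect mapping on a synthetic PVI with constrained gradients.
# Run: dendrinh simulate --config examples/pvi_ie_map.yaml --out out/
task: protocol.ie-map
seed: 1
cell:
  cell_type: PVI
params:
  exc_distance_um: 150.0
  gaba_locations_um: [50.0, 100.0, 150.0, 200.0, 250.0]
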