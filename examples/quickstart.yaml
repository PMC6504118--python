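# Reduced-scale quiet-state run of the homogeneous circuit.
# Usage: microhet simulate --config examples/quickstart.yaml
condition: Hom
N: 250
state: quiet
nu_in: 10.0
duration: 2000.0
seed_circuit: 7
seed_background: 11
seed_input: 3
seed_analysis: 4
output_dir: runs/quickstart
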