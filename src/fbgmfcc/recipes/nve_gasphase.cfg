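# Gas-phase NVE conservation experiment: Ace-(ALA)9-NME, 2 ps at 1 fs.
# Run once with balance_mode=paper and once with balance_mode=none and
# compare total-energy drift slopes (fbgmfcc analyze drift).
[system]
source = builder
sequence = AAAAAAAAA
geometry = extended

[dynamics]
ensemble = nve
dt = 1.0
steps = 2000
seed = 1
balance_mode = paper
initial_temperature = 300

[output]
trajectory = nve_gasphase.xyz
energy_log = nve_gasphase.log
checkpoint = nve_gasphase.chk
stride = 100
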