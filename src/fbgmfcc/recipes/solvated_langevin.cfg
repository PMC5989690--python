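# Scaled-down solvated experiment: tri-alanine in a small water ball,
# Langevin thermostat at 2.0 ps^-1, backbone restraint 50 kcal/mol/A^2
# and a 20 kcal/mol/A^2 half-harmonic wall on the water-ball boundary.
[system]
source = builder
sequence = AAA
geometry = extended
n_waters = 40
solvent_seed = 7

[dynamics]
ensemble = langevin
dt = 1.0
steps = 500
temperature = 300
gamma = 2.0
seed = 3
balance_mode = paper
initial_temperature = 100

[restraints]
backbone_k = 50
boundary_k = 20

[output]
energy_log = solvated_langevin.log
checkpoint = solvated_langevin.chk
stride = 100
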