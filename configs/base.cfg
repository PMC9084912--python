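# Example configuration (base model).
# Energies/strengths are calibration choices reproducing the
# model's qualitative migration behavior at desk scale; see
# docs/methods.md.
lattice-width = 150
lattice-height = 150
cell-count = 30
total-mcs = 5000
equilibration-mcs = 1000
track-interval = 1
snapshot-interval = 0
temperature = 20.0
connectivity-constraint = False
model = base
j-cell-med = 20.0
j-cell-cell = 30.0
lambda-area = 25.0
target-area = 250.0
lambda-persistence = 0.1
decay-time = 20.0
lambda-act = 160.0
max-act = 40.0
p-ext = 0.3
p-retr = 0.3
init-dir-strength = 3.0
cont-dir-strength = 8.0
max-growth-time = 60.0
stall-limit = 20
time-between-extensions = 20.0
retraction-mode = backward
neighboring-actin-bonus = 60.0
n-pseudopods = 3
move-dir-decay-time = 10.0
pull-strength = 0.0
tip-bonus = 0.0
max-distance-for-tip-bonus = 3.0
touch-behavior = nothing
p-touch-retr = 0.1
lateral-threshold = 0.85
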