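[arm]
i1 = 0.025
i2 = 0.045
m1 = 1.4
m2 = 1.0
l1 = 0.3
l2 = 0.33
lg1 = 0.11
lg2 = 0.16
b11 = 0.0
b12 = 0.0
b22 = 0.0

[noise]
sigma = 0.005
d = 0.01
beta = 0.003
delay = 0.0

[cost]
r = 2000.0
alpha = 0.02
rho = 1000.0

[task]
q1_deg = 50.0
q2_deg = 100.0
direction_deg = 135.0
distance = 0.074

[sim]
dt = 0.005
n_trials = 1000.0
seed = 0.0
n_controls = 21.0
n_steps = 100.0

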