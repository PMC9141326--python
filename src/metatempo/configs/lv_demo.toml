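# Pure Lotka-Volterra demo: conservative predator-prey cycles.
system = "lv"

[params]
alpha0 = 1.0
beta0 = 0.1
gamma0 = 1.5
delta0 = 0.075

[init]
x = 10.0
y = 5.0

[integration]
t_end = 100.0
n_points = 4001
rtol = 1e-8
atol = 1e-10
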