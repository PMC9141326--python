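# Trait-coupled predator-prey run in the damped regime: the same initial
# ecology as lv_demo, with prey-defense and predator-offense evolution
# turning the neutral cycles into initially damped oscillations that settle
# into a narrow band around equilibrium.
system = "lv_coevo"

[params]
alpha0 = 1.0
beta0 = 0.1
gamma0 = 1.5
delta0 = 0.075
V1 = 0.25
V2 = 0.03
c1 = 1.0
c2 = 3.0
conversion = 0.75
functional_response = "mass_action"

[init]
x = 10.0
y = 5.0
u = 0.0
v = 0.0

[integration]
t_end = 100.0
n_points = 4001
rtol = 1e-8
atol = 1e-10
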