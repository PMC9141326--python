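# Equilibrium fixture: the generator starts identical to the background,
# so no discriminator can beat chance and detection hovers at 50%.
[space]
means = [[-2.0], [2.0]]
cov_scale = 0.25
weights = [0.5, 0.5]

[generator]
means = [[-2.0], [2.0]]
cov_scale = 0.25
weights = [0.5, 0.5]

[run]
freeze_generator = false
window = 20
tol = 0.05
max_iterations = 2000
batch_size = 64
n_eval = 400
disc_learning_rate = 0.2
gen_learning_rate = 0.05
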