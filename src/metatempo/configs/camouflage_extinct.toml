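# Prey-extinction fixture: the generator is frozen as a near-point-mass
# far outside the background mixture's support, so the discriminator soon
# detects 100% of generated patterns on every iteration of the window.
[space]
means = [[-2.0], [2.0]]
cov_scale = 0.25
weights = [0.5, 0.5]

[generator]
means = [[10.0]]
cov_scale = 1e-6

[run]
freeze_generator = true
window = 20
tol = 0.05
max_iterations = 2000
batch_size = 64
n_eval = 400
disc_learning_rate = 0.2
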