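# Methods

This note records the models, the parameter choices that matter, the
numerical decisions, and what the synthetic experiments do and do not show.

## Two-timescale environments (`envstreams`)

The environment drives `n1 + n2` sensory bits through two independent
processes. The fast sector is resampled i.i.d. uniform every
sensation–action cycle (its timescale is pinned to one cycle; only the
ratio of cycle time to slow timescale enters any cost formula). The slow
sector changes either every `round(τ2)` cycles (`periodic`) or with
per-cycle probability `1/τ2` (`geometric`, giving geometric inter-change
intervals with mean `τ2`). Two schedules exist because the cost ledger can
then be checked both exactly (periodic) and statistically (geometric). The
marginal bit distribution is uniform; nothing downstream depends on it. On
a scheduled change the new slow pattern is forced to differ from the old
one (a random bit is flipped on the `2^-n2`-probability collision), so the
change annotations are identical to the schedule with probability one.

Assumed synchrony: the environment's change clock and the agent's cycle
clock tick together; sub-cycle change timing is not modeled.

## Cost calculus and competition (`energetics`)

Costs are linear: `ε` per rewritten bit (default 1.0, natural units; a
constructor accepts a temperature and an efficiency `β ≥ ln 2` and sets
`ε = β·kB·T` joules), `m` compute steps per input bit per cycle, `m_detect`
detector steps per slow bit per cycle. The detector overhead defaults to
`Δ = n2·m_detect·ε` — a per-bit change detector that runs every cycle —
but an explicit `Δ` can be supplied, which is what makes the advantage
boundary sweepable. The ledger simulation charges the monolithic
architecture `(n1+n2)·m·ε` every cycle and the metaprocessor
`n1·m·ε + n2·m_detect·ε` every cycle plus `n2·m·ε` on change cycles; on a
periodic schedule whose period divides the cycle count its mean is equal to
the closed form `Ξ` with no tolerance at all.

The compounded advantage of an energy saving is stated over a dimensionless
base: the printed form of the advantage adds an energy difference to 1, so
the saving is normalized by the joint per-cycle budget,
`s = (n·m·ε − Ξ)/(n·m·ε)`, which preserves the sign and the
exponential-in-generations structure and recovers the unnormalized form
when the joint budget is taken as the energy unit.

Competition is a haploid Wright–Fisher model: two lineages, relative
fitness `1` and `1+s`, binomial resampling at constant population size,
initial frequency 0.5. No population-genetic model is prescribed by the
theory being illustrated — Wright–Fisher with multinomial resampling is the
standard minimal choice. The reported slope is the mean per-generation
increment of `log(p/(1−p))` over generations where both lineages
segregate; conditioning on segregation biases the stochastic slope
slightly above `ln(1+s)`, so the exact identity is asserted only in the
deterministic (infinite-population) mode, where it holds to machine
precision.

## Discrete free energy and the drift experiment (`inference`)

All state spaces are finite and categorical, so the divergence integral is
a sum and every bound can be checked to 1e−12. Logs are natural. The
evidence term is implemented as `−ln p(m)` for a fixed model; the
joint-evidence form differs by a constant that affects neither the bound
nor the minimizer. `KL(p‖q)` uses the convention `0·ln(0/q) = 0` and
returns `inf` (rather than raising) when `p` has mass outside `q`'s
support; a zero-evidence observation likewise yields an infinite free
energy, not an exception. The total prediction error `δ` in the fitness
map `g = 1 − δ` is an input, not something computed from a model: no
operational formula for it is part of the theory.

The drift experiment requires care. If the external state is redrawn
independently every cycle, the expected value of any model's posterior is
the prior, and the expected free energy of a lagged believer is provably
independent of the previous cycle's emission model — drifting and
stationary schedules then have *identical* means (we verified the identity
to machine precision), and no drift penalty can be demonstrated. The
experiment therefore uses a persistent hidden state: each cycle it stays
with probability 0.9 and is otherwise redrawn from the prior. The agent's
model is fixed at the first schedule entry (it is calibrated to the
stationary phase); each cycle it believes the previous cycle's posterior
pushed through the persistence kernel, and since it minimizes free energy
exactly within the cycle, its realized per-cycle VFE is the predictive
surprisal `−ln p(m_t | m_{1:t−1})`. A constant schedule gives the
stationary predictive entropy rate; a drifting schedule adds an average
KL penalty (≈ 0.34 nats per cycle for the committed likelihood pair).
Because the filtered belief is history-dependent there is no finite closed
form; comparisons are Monte-Carlo at three combined standard errors over a
3000-cycle horizon, which makes the ≈ 0.3-nat effect detectable with large
margin.

## Eco-evolutionary dynamics (`ecodyn`)

The trait parameterization is the one genuinely open design choice: the
trait equations evolve the interaction rates but no functional forms or
trade-offs are prescribed, and without a trade-off the rates run away. We
introduce prey defense `u` and predator offense `v` with

    α(u) = α0 − c1·u²,   β(u,v) = β0·e^(v−u),
    γ(v) = γ0 + c2·v²,   δ(u,v) = conversion·β(u,v),

quadratic costs guaranteeing interior trait equilibria. Per-capita mutant
fitness is `w1(u_i) = α(u_i) − β(u_i,v)·y` and
`w2(v_i) = conversion·β(u,v_i)·x − γ(v_i)` (mass action; the Holling-II
forms keep the resident attack rate in the predator's saturation term),
and the trait derivatives are the mutant gradients evaluated at the
resident value, multiplied by constant genetic variances `V1`, `V2` (a
callable hook could replace constants; nothing here needs it). Each
variance multiplies the gradient in its own population's equation.

Integration uses `scipy.integrate.solve_ivp` with LSODA (adaptive,
stiff-capable), relative tolerance 1e−8 and absolute 1e−10; at those
defaults the Lotka–Volterra first integral
`V = δx − γ·ln x + βy − α·ln y` drifts below 1e−6 relative over 100 time
units (measured ≈ 9e−8), which is the integration-accuracy oracle.
Densities below 1e−9 are clamped to zero in the output (extinction floor).
Peak detection is post hoc three-point comparison (scipy `find_peaks`) with
optional moving-average smoothing, not solver event detection.

The committed `coevo_damped` configuration (α0=1, β0=0.1, γ0=1.5, δ0=0.075,
conversion 0.75, V1=0.25, V2=0.03, c1=1, c2=3, start x=10, y=5, u=v=0) was
located by a coarse parameter search for the damped regime with both traits
evolving and then frozen: prey-peak amplitudes fall strictly over the first
three cycles and the terminal coefficient of variation of prey density is
below 1% of the initial one, against ≥ 80% retention for the pure
ecological system from the same initial state. Large predator-side
variances with weak offense costs push the exponential attack rate into
runaway; the committed values sit well inside the stable basin.

## Coupled genetic algorithm (`coupled_ga`)

The encounter game is bit matching: a predator's payoff against an opponent
is the fraction of equal bits, the prey's is the complement, so every
encounter is zero-sum and the best response to any frozen population is
exhaustively computable (per-position majority/minority). Fitness is
lifetime-sampled: `lifetime_samples` opponents per genome per generation,
drawn without replacement (the all-pairs limit is `lifetime_samples =
pop_size`). Selection is tournament of size 2 by default (proportional
optional, elitism off by default); crossover is single-point, mutation
per-bit.

Memory attaches to individuals: each genome's selected-on fitness is the
exponential moving average `λ·previous + (1−λ)·instantaneous`, and
offspring inherit the mean filtered value of their parents (the
alternative — one population-level memory — would not let selection
distinguish lineages by their history). Reproduction coupling splits a
conserved total of `2·pop_size` offspring in proportion to
`(mean filtered fitness)^κ`; a population allotted zero offspring is
extinct and the run terminates.

Default study conditions: genome length 8, 32 individuals per population,
mutation 0.01 per bit, crossover 0.5, 8 opponents per evaluation, 300
generations. At these values the unstabilized system (λ=0, κ=0) shows Red
Queen cycling — second-half mean-fitness standard deviation above 0.05 in
20/20 seeds — which is the baseline the stabilizers are compared against.

What the comparisons show, and honestly do not: the memory filter reduces
the dispersion of the population fitness series (the fitness the
individuals actually carry and are selected on) in 19/20 paired seeds; it
does **not** reduce the dispersion of the instantaneous evaluation series,
because the inherited moving average adds phase lag to the coevolutionary
feedback loop. The positive performance→reproduction coupling (κ=1) does
not reduce fitness dispersion at all in this generational zero-sum design
— granting the currently fitter side more offspring accelerates its
convergence while the shrinking loser loses standing variation, a positive
feedback on the fitness gap — and in small populations it produces
extinction spirals. The corresponding acceptance check is left failing
rather than redefined; the inverted coupling (loser breeds more) does
stabilize but contradicts the monotone share contract, so it is not
implemented. What κ=1 does deliver at the default conditions is long-run
viability: neither population went extinct over 500 generations in 20/20
seeds.

## Camouflage arms race (`camouflage`)

No neural networks: the generator is an isotropic Gaussian mixture
(learnable means, shared variance, weights), the discriminator a logistic
model over a polynomial feature expansion (degree 2 by default). The
object of study is the coupled adversarial dynamic and its termination
rules, and these parametric choices keep every gradient exact and every
run deterministic per seed. The discriminator takes one full-batch
gradient-ascent step on label log-likelihood per iteration; the generator
takes one score-function (likelihood-ratio) step against the mean
"generated" score of its samples, with a moving-average baseline for
variance reduction and a finite-difference fallback behind a flag; the
mixture variance is floored at 1e−6.

A classification tie at score exactly 0.5 counts as background (favoring
the prey), which pins the untrained discriminator at detection rate 0.
Raw detection rate has a pitfall worth recording: when generator and
background coincide, a trained discriminator's score noise is common-mode
across samples, so the raw rate is bimodal at 0 or 1 even though the
classifier has no actual skill. Chance-level behavior is therefore
measured by the discrimination index `0.5 + (hits − false alarms)/2`,
which equals 0.5 in expectation for *any* discriminator facing identical
distributions. Termination over a sliding window of K=20 iterations with
tolerance 0.05 (cap 2000, all committed in the default configs):
`prey_extinct` when the raw detection rate is exactly 1.0 throughout the
window (the literal all-targets-found rule), `equilibrium` when the index
stays within the tolerance of chance, `predator_blind` — an extension
added for symmetry, since predator extinction has no canonical definition
— when the index stays below chance minus the tolerance. Coupled-network
weight sharing across multiple adversarial pairs is out of scope.

## Problem sizes

All experiments are desk-scale by design: streams of 10⁴–10⁵ cycles,
Wright–Fisher populations of 10³ over 10² generations, 3000-cycle drift
horizons, 100-time-unit integrations at 4001 samples, GA runs of 300–500
generations with 32–64 individuals per side, arms races of at most 2000
iterations. The full test suite runs in about 90 seconds on one CPU.

## Known limitations

Two timescales only (no k-sector generalization of the cost margin);
informative bits only (fuel and waste traffic is not modeled as channel
load); categorical state spaces (no continuous/Gaussian free energy, no
policy selection); no bifurcation-continuation machinery for the
ecological models; no spatial or demographic-noise predator–prey variants;
the GA ships a single game (others can be registered); image-based
camouflage and deep adversarial training are out of scope. Synthetic
streams are i.i.d. within sectors, so passing tests say nothing about
temporally correlated natural scenes; the synthetic mixtures are
low-dimensional, so arms-race conclusions are about the dynamic, not about
camouflage realism.
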