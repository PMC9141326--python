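"""Adversarial camouflage arms race at desk scale.

Prey display patterns drawn from a learnable Gaussian-mixture distribution
(the *generator*); a predator classifier (the *discriminator*, a logistic
model over a polynomial feature expansion) tries to tell prey patterns from
the fixed background-pattern distribution. The two are updated in
alternation — the discriminator by gradient ascent on label likelihood, the
generator by a score-function (likelihood-ratio) gradient step that lowers
the mean probability its samples are flagged as generated — and the run
terminates by the arms-race rules:

* ``prey_extinct``   — the discriminator detects 100% of generated
  patterns on every iteration of a sliding window (the predator finds all
  the prey, every time);
* ``equilibrium``    — detection stays within a tolerance of chance (50%)
  throughout a window (camouflage is as good as the background);
* ``predator_blind`` — detection stays below chance minus the tolerance
  throughout a window (the symmetric predator-extinction rule, an
  extension: the discriminator is persistently worse than guessing);
* ``max_iters``      — the iteration cap is reached first.

There is deliberately no neural-network stack: the coupled adversarial
dynamic and its termination rules are the object of study, and parametric
mixtures plus a logistic discriminator keep every gradient exact,
deterministic per seed, and checkable against closed forms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from .envstreams import ValidationError

__all__ = [
    "PatternSpace",
    "GeneratorParams",
    "DiscriminatorParams",
    "ArmsRaceConfig",
    "ArmsRaceOutcome",
    "detection_rate",
    "update_discriminator",
    "update_generator",
    "fit_discriminator",
    "run_arms_race",
]

COV_FLOOR = 1e-6

Status = Literal["equilibrium", "prey_extinct", "predator_blind", "max_iters"]


def _check_mixture(means: np.ndarray, cov_scale: float, weights: np.ndarray, what: str) -> None:
    if means.ndim != 2:
        raise ValidationError(f"{what} means must be a (components, d) array")
    if cov_scale <= 0:
        raise ValidationError(f"{what} cov_scale must be positive")
    if weights.shape[0] != means.shape[0]:
        raise ValidationError(f"{what} weights must have one entry per component")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{what} weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class _Mixture:
    """Isotropic Gaussian mixture: shared scalar covariance across components."""

    means: np.ndarray = field(repr=False)
    cov_scale: float = 1.0
    weights: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        weights = (
            np.full(means.shape[0], 1.0 / means.shape[0])
            if self.weights is None
            else np.asarray(self.weights, dtype=float)
        )
        _check_mixture(means, self.cov_scale, weights, type(self).__name__)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "weights", weights / weights.sum())

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        return self.means[comp] + math.sqrt(self.cov_scale) * rng.standard_normal((n, self.d))

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, shape (n, components)."""
        sq = ((x[:, None, :] - self.means[None, :, :]) ** 2).sum(axis=2)
        log_comp = -0.5 * sq / self.cov_scale - 0.5 * self.d * math.log(
            2 * math.pi * self.cov_scale
        ) + np.log(self.weights)[None, :]
        log_comp -= log_comp.max(axis=1, keepdims=True)
        w = np.exp(log_comp)
        return w / w.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PatternSpace(_Mixture):
    """The fixed background ("real") pattern distribution over R^d."""


@dataclass(frozen=True)
class GeneratorParams(_Mixture):
    """The prey's learnable pattern distribution; same structure as the background."""


@dataclass(frozen=True)
class DiscriminatorParams:
    """Logistic classifier over a polynomial feature expansion.

    ``score(x) = sigmoid(w . phi(x) + b)`` is the probability the pattern
    is generated (prey). A pattern is classified "generated" only when its
    score strictly exceeds 0.5; an exact tie counts as background, which
    favors the prey and pins the untrained (zero-weight) discriminator at
    detection rate 0.
    """

    weights: np.ndarray = field(repr=False)
    bias: float = 0.0
    degree: int = 2

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or not np.isfinite(self.bias):
            raise ValidationError("discriminator parameters must be finite")
        object.__setattr__(self, "weights", w)

    @classmethod
    def zeros(cls, d: int, degree: int = 2) -> "DiscriminatorParams":
        return cls(weights=np.zeros(_n_poly_features(d, degree)), bias=0.0, degree=degree)

    def score(self, x: np.ndarray) -> np.ndarray:
        """P(generated) for each row of x."""
        z = _poly_features(np.atleast_2d(x), self.degree) @ self.weights + self.bias
        return expit(z)


def _poly_features(x: np.ndarray, degree: int) -> np.ndarray:
    """All monomials of total degree 1..degree (no constant column)."""
    n, d = x.shape
    cols = []
    for deg in range(1, degree + 1):
        for combo in itertools.combinations_with_replacement(range(d), deg):
            cols.append(np.prod(x[:, combo], axis=1))
    return np.stack(cols, axis=1)


def _n_poly_features(d: int, degree: int) -> int:
    return sum(math.comb(d + deg - 1, deg) for deg in range(1, degree + 1))


def detection_rate(
    disc: DiscriminatorParams,
    gen: GeneratorParams,
    space: PatternSpace,
    n_eval: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of n_eval generator samples classified as generated (score > 0.5)."""
    if n_eval < 1:
        raise ValidationError(f"n_eval must be >= 1, got {n_eval!r}")
    samples = gen.sample(n_eval, rng)
    return float(np.mean(disc.score(samples) > 0.5))


def discrimination_index(
    disc: DiscriminatorParams,
    gen: GeneratorParams,
    space: PatternSpace,
    n_eval: int,
    rng: np.random.Generator,
) -> float:
    """Chance-referenced discrimination skill: 0.5 + (hits - false alarms)/2.

    Hits are generated patterns flagged generated; false alarms are
    background patterns flagged generated. For any discriminator facing a
    generator identical to the background the two rates have equal
    expectation, so the index is 0.5 (chance) up to sampling noise — unlike
    the raw detection rate, which a score offset alone can pin at 0 or 1
    on both pattern sources at once. 1.0 is perfect separation; below 0.5
    the discriminator is actively mistaken about which source is which.
    """
    if n_eval < 1:
        raise ValidationError(f"n_eval must be >= 1, got {n_eval!r}")
    hits = float(np.mean(disc.score(gen.sample(n_eval, rng)) > 0.5))
    false_alarms = float(np.mean(disc.score(space.sample(n_eval, rng)) > 0.5))
    return 0.5 + 0.5 * (hits - false_alarms)


def update_discriminator(
    disc: DiscriminatorParams,
    real_batch: np.ndarray,
    generated_batch: np.ndarray,
    learning_rate: float,
) -> DiscriminatorParams:
    """One gradient-ascent step on the mean log-likelihood of correct labels.

    Real patterns carry label 0, generated patterns label 1; the logistic
    gradient per example is ``(label - score) * phi(x)``.
    """
    real = np.atleast_2d(real_batch)
    fake = np.atleast_2d(generated_batch)
    if real.shape[0] == 0 or fake.shape[0] == 0:
        raise ValidationError("both batches must be nonempty")
    x = np.vstack([real, fake])
    labels = np.concatenate([np.zeros(real.shape[0]), np.ones(fake.shape[0])])
    phi = _poly_features(x, disc.degree)
    resid = labels - disc.score(x)
    grad_w = phi.T @ resid / x.shape[0]
    grad_b = float(resid.mean())
    if not (np.all(np.isfinite(grad_w)) and np.isfinite(grad_b)):
        raise FloatingPointError(
            f"non-finite discriminator gradient; batch means real={real.mean(axis=0)}, "
            f"generated={fake.mean(axis=0)}"
        )
    return replace(disc, weights=disc.weights + learning_rate * grad_w, bias=disc.bias + learning_rate * grad_b)


def fit_discriminator(
    space_or_real: np.ndarray,
    generated: np.ndarray,
    degree: int = 2,
    learning_rate: float = 0.5,
    steps: int = 200,
) -> DiscriminatorParams:
    """Convenience batch trainer: repeated full-batch updates on fixed data."""
    d = np.atleast_2d(space_or_real).shape[1]
    disc = DiscriminatorParams.zeros(d, degree)
    for _ in range(steps):
        disc = update_discriminator(disc, space_or_real, generated, learning_rate)
    return disc


def update_generator(
    gen: GeneratorParams,
    disc: DiscriminatorParams,
    space: PatternSpace,
    batch_size: int,
    learning_rate: float,
    rng: np.random.Generator,
    baseline: float | None = None,
    method: Literal["score_function", "finite_difference"] = "score_function",
) -> tuple[GeneratorParams, float]:
    """One generator step lowering the mean discriminator score of its samples.

    Score-function (likelihood-ratio) estimator by default: the gradient of
    ``E[score]`` with respect to the mixture parameters is estimated as the
    batch mean of ``(score - baseline) * grad log p_gen(x)``, with an
    externally maintained moving-average baseline for variance reduction. A
    central finite-difference fallback over the stacked parameter vector is
    available behind the ``method`` flag. Covariance is floored at
    ``COV_FLOOR``. Returns the updated generator and the batch mean score.
    """
    if batch_size < 1:
        raise ValidationError(f"batch_size must be >= 1, got {batch_size!r}")
    x = gen.sample(batch_size, rng)
    scores = disc.score(x)
    mean_score = float(scores.mean())
    b = mean_score if baseline is None else baseline
    advantage = scores - b

    if method == "finite_difference":
        return _update_generator_fd(gen, disc, batch_size, learning_rate, rng), mean_score

    resp = gen.responsibilities(x)  # (n, k)
    diff = x[:, None, :] - gen.means[None, :, :]  # (n, k, d)
    grad_means = (advantage[:, None, None] * resp[:, :, None] * diff / gen.cov_scale).mean(axis=0)
    sq = (diff**2).sum(axis=2)  # (n, k)
    grad_log_cov = float(
        (advantage * (resp * (0.5 * sq / gen.cov_scale - 0.5 * gen.d)).sum(axis=1)).mean()
    )
    grad_logits = (advantage[:, None] * (resp - gen.weights[None, :])).mean(axis=0)

    new_means = gen.means - learning_rate * grad_means
    new_log_cov = math.log(gen.cov_scale) - learning_rate * grad_log_cov
    new_cov = max(math.exp(new_log_cov), COV_FLOOR)
    logits = np.log(np.clip(gen.weights, 1e-12, None)) - learning_rate * grad_logits
    logits -= logits.max()
    new_weights = np.exp(logits)
    new_weights /= new_weights.sum()
    return (
        GeneratorParams(means=new_means, cov_scale=new_cov, weights=new_weights),
        mean_score,
    )


def _update_generator_fd(
    gen: GeneratorParams,
    disc: DiscriminatorParams,
    batch_size: int,
    learning_rate: float,
    rng: np.random.Generator,
    eps: float = 1e-3,
) -> GeneratorParams:
    """Central finite differences of E[score] over means and log cov_scale.

    Common random numbers: each perturbed expectation reuses one normalized
    sample of offsets, so the difference is smooth in the parameters.
    """
    comp = rng.choice(gen.n_components, size=batch_size, p=gen.weights)
    z = rng.standard_normal((batch_size, gen.d))

    def objective(means: np.ndarray, log_cov: float) -> float:
        x = means[comp] + math.exp(0.5 * log_cov) * z
        return float(disc.score(x).mean())

    grad_means = np.zeros_like(gen.means)
    for k in range(gen.n_components):
        for j in range(gen.d):
            up = gen.means.copy()
            dn = gen.means.copy()
            up[k, j] += eps
            dn[k, j] -= eps
            grad_means[k, j] = (
                objective(up, math.log(gen.cov_scale)) - objective(dn, math.log(gen.cov_scale))
            ) / (2 * eps)
    lc = math.log(gen.cov_scale)
    grad_log_cov = (objective(gen.means, lc + eps) - objective(gen.means, lc - eps)) / (2 * eps)

    new_means = gen.means - learning_rate * grad_means
    new_cov = max(math.exp(lc - learning_rate * grad_log_cov), COV_FLOOR)
    return GeneratorParams(means=new_means, cov_scale=new_cov, weights=gen.weights)


@dataclass(frozen=True)
class ArmsRaceConfig:
    """All knobs of one arms-race run; everything overridable from TOML."""

    space: PatternSpace
    generator: GeneratorParams
    degree: int = 2
    batch_size: int = 64
    n_eval: int = 400
    disc_learning_rate: float = 0.2
    gen_learning_rate: float = 0.05
    freeze_generator: bool = False
    window: int = 20
    tol: float = 0.05
    max_iterations: int = 2000
    baseline_decay: float = 0.9

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError(f"window must be >= 1, got {self.window!r}")
        if not (0 < self.tol < 0.5):
            raise ValidationError(f"tol must lie in (0, 0.5), got {self.tol!r}")
        if self.max_iterations < self.window:
            raise ValidationError("max_iterations must be at least the window length")
        if self.space.d != self.generator.d:
            raise ValidationError("background and generator must share the pattern dimension")


@dataclass(frozen=True)
class ArmsRaceOutcome:
    """Termination status plus the full detection-rate series."""

    status: Status
    iterations: int
    final_detection_rate: float
    series: pd.DataFrame = field(repr=False)  # columns: iteration, detection_rate, disc_norm


def run_arms_race(config: ArmsRaceConfig, seed: int | None = 0) -> ArmsRaceOutcome:
    """Alternate discriminator and generator updates until a rule fires.

    Per iteration: draw a real and a generated batch, update the
    discriminator, update the generator (unless frozen), then measure both
    the raw detection rate and the chance-referenced discrimination index
    on fresh samples. Termination checks, in precedence order over the
    trailing window: prey_extinct (raw detection rate exactly 1.0
    throughout — the predator finds every generated target on every
    iteration), equilibrium (|index - 0.5| <= tol throughout: the
    discriminator holds no skill beyond chance), predator_blind
    (index <= 0.5 - tol throughout: persistently worse than chance);
    otherwise max_iters. The skill-based rules use the index rather than
    the raw rate because a score offset alone can hold the raw rate at 0
    or 1 with no actual discrimination.
    """
    rng = np.random.default_rng(seed)
    gen = config.generator
    disc = DiscriminatorParams.zeros(config.space.d, config.degree)
    baseline: float | None = None

    rates: list[float] = []
    indices: list[float] = []
    norms: list[float] = []
    status: Status = "max_iters"
    for it in range(config.max_iterations):
        real = config.space.sample(config.batch_size, rng)
        fake = gen.sample(config.batch_size, rng)
        disc = update_discriminator(disc, real, fake, config.disc_learning_rate)
        if not config.freeze_generator:
            gen, mean_score = update_generator(
                gen, disc, config.space, config.batch_size, config.gen_learning_rate, rng, baseline
            )
            baseline = (
                mean_score
                if baseline is None
                else config.baseline_decay * baseline + (1 - config.baseline_decay) * mean_score
            )
        rates.append(detection_rate(disc, gen, config.space, config.n_eval, rng))
        indices.append(discrimination_index(disc, gen, config.space, config.n_eval, rng))
        norms.append(float(np.linalg.norm(disc.weights)))

        if len(rates) >= config.window:
            w_rate = rates[-config.window :]
            w_idx = indices[-config.window :]
            if all(r == 1.0 for r in w_rate):
                status = "prey_extinct"
                break
            if all(abs(i - 0.5) <= config.tol for i in w_idx):
                status = "equilibrium"
                break
            if all(i <= 0.5 - config.tol for i in w_idx):
                status = "predator_blind"
                break

    series = pd.DataFrame(
        {
            "iteration": np.arange(len(rates)),
            "detection_rate": rates,
            "discrimination_index": indices,
            "disc_norm": norms,
        }
    )
    return ArmsRaceOutcome(
        status=status,
        iterations=len(rates),
        final_detection_rate=rates[-1] if rates else float("nan"),
        series=series,
    )
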