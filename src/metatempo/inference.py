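"""Discrete-state variational free energy (VFE) machinery.

A system separated from its environment by a Markov blanket holds beliefs
``q(e)`` over the external states ``e`` it cannot observe directly; its
generative model is a prior ``p(e)`` plus a likelihood ``p(m | e)`` over
blanket (sensory) states ``m``. For an observed ``m`` the variational free
energy of a belief ``q`` is

    F(m, q) = -ln p(m) + KL(q || p(e | m)),

an upper bound on the surprisal ``-ln p(m)`` that is tight exactly when
``q`` is the Bayes posterior. (The model's parameters play the role of the
internal state; with the model fixed, the joint-evidence form of the first
term differs from ``-ln p(m)`` only by a constant.) All state spaces here
are finite and categorical, so every integral is a sum and every quantity
is exactly computable; logs are natural (nats).

The drift experiment quantifies why a *changing* environment is costly: an
agent whose belief each cycle is the posterior from the previous cycle's
observation accrues strictly more free energy when the likelihood drifts
between cycles than when it is stationary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .envstreams import ValidationError

__all__ = [
    "DiscreteGenerativeModel",
    "Belief",
    "VFEResult",
    "kl_divergence",
    "vfe",
    "posterior_belief",
    "prediction_fitness",
    "average_vfe_under_drift",
]

_ATOL = 1e-12


def _as_prob_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be a 1-d probability vector")
    if np.any(v < 0):
        raise ValidationError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{name} must sum to 1, sums to {v.sum()!r}")
    return v / v.sum()


@dataclass(frozen=True)
class DiscreteGenerativeModel:
    """Finite categorical generative model: prior p(e) and likelihood p(m|e).

    ``likelihood`` is row-stochastic with one row per external state and one
    column per blanket state.
    """

    external_states: tuple
    blanket_states: tuple
    prior: np.ndarray = field(repr=False)
    likelihood: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "external_states", tuple(self.external_states))
        object.__setattr__(self, "blanket_states", tuple(self.blanket_states))
        prior = _as_prob_vector(self.prior, "prior")
        lik = np.asarray(self.likelihood, dtype=float)
        if prior.shape[0] != len(self.external_states):
            raise ValidationError("prior length must match external_states")
        if lik.shape != (len(self.external_states), len(self.blanket_states)):
            raise ValidationError(
                f"likelihood must have shape (n_external, n_blanket) = "
                f"({len(self.external_states)}, {len(self.blanket_states)}), got {lik.shape}"
            )
        if np.any(lik < 0):
            raise ValidationError("likelihood has negative entries")
        rowsums = lik.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValidationError("every likelihood row must sum to 1")
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "likelihood", lik / rowsums[:, None])

    def blanket_index(self, m) -> int:
        try:
            return self.blanket_states.index(m)
        except ValueError:
            raise ValidationError(f"unknown blanket state {m!r}") from None

    def marginal(self, m) -> float:
        """Model evidence p(m) = sum_e p(e) p(m|e)."""
        return float(self.prior @ self.likelihood[:, self.blanket_index(m)])

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteGenerativeModel":
        """Build from a plain mapping (e.g. parsed TOML/JSON)."""
        return cls(
            external_states=tuple(d["external_states"]),
            blanket_states=tuple(d["blanket_states"]),
            prior=np.asarray(d["prior"], dtype=float),
            likelihood=np.asarray(d["likelihood"], dtype=float),
        )


@dataclass(frozen=True)
class Belief:
    """A variational distribution q(e) over external states."""

    q: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _as_prob_vector(self.q, "belief"))


def kl_divergence(p, q) -> float:
    """KL(p || q) = sum p ln(p/q) in nats, with 0 ln(0/q) = 0.

    Returns ``inf`` (rather than raising) when p puts mass where q does not.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {q.shape}")
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


class VFEResult(NamedTuple):
    """VFE and its exact decomposition: total = evidence_term + kl_term."""

    total: float
    evidence_term: float
    kl_term: float


def posterior_belief(model: DiscreteGenerativeModel, m) -> Belief:
    """Exact Bayes posterior p(e | m); the unique minimizer of the VFE."""
    j = model.blanket_index(m)
    joint = model.prior * model.likelihood[:, j]
    pm = joint.sum()
    if pm <= 0:
        raise ValidationError(f"blanket state {m!r} has zero evidence under the model")
    return Belief(q=joint / pm)


def vfe(model: DiscreteGenerativeModel, m, belief: Belief) -> VFEResult:
    """Variational free energy of a belief given an observation, in nats.

    evidence_term = -ln p(m); kl_term = KL(q || p(e|m)); total is their sum
    and hence always >= the surprisal, with equality iff q is the posterior.
    A zero-evidence observation yields an infinite result, not an error.
    """
    pm = model.marginal(m)
    if pm == 0:
        return VFEResult(float("inf"), float("inf"), float("nan"))
    evidence_term = -float(np.log(pm))
    posterior = posterior_belief(model, m)
    kl_term = kl_divergence(belief.q, posterior.q)
    return VFEResult(evidence_term + kl_term, evidence_term, kl_term)


def prediction_fitness(delta: float) -> float:
    """Survival probability g = 1 - delta for total prediction error delta in [0, 1]."""
    if not (0.0 <= delta <= 1.0):
        raise ValidationError(f"delta must lie in [0, 1], got {delta!r}")
    return 1.0 - delta


def average_vfe_under_drift(
    likelihood_schedule: Sequence[np.ndarray],
    prior,
    horizon: int,
    seed: int | None = 0,
    persistence: float = 0.9,
    return_stderr: bool = False,
) -> float | tuple[float, float]:
    """Mean per-cycle VFE of a lagged believer facing a (possibly) drifting world.

    The environment holds a persistent hidden external state: each cycle it
    stays put with probability ``persistence`` and is otherwise redrawn
    from the prior; the observation is emitted through the schedule's
    likelihood at that cycle (the schedule repeats if shorter than the
    horizon). The agent's generative model is fixed at the *first* schedule
    entry — it is calibrated to the stationary phase. Each cycle the agent
    believes the previous cycle's posterior (pushed through the persistence
    kernel); taking that belief as its prior over external states and
    minimizing the free energy of the new observation exactly, its realized
    VFE is the predictive surprisal ``-ln p(m_t | m_{1:t-1})``. The
    returned value is the time average (optionally with its standard
    error).

    With a constant schedule the agent's model matches the emission process
    and the average is the stationary predictive entropy rate; when the
    emission likelihood drifts away from the agent's model the average
    acquires a mismatch excess (an average Kullback-Leibler penalty), which
    is the free-energy cost of environmental time variation.
    """
    if horizon < 2:
        raise ValidationError(f"horizon must be at least 2, got {horizon!r}")
    if not (0.0 <= persistence <= 1.0):
        raise ValidationError(f"persistence must lie in [0, 1], got {persistence!r}")
    p = _as_prob_vector(prior, "prior")
    n_e = p.shape[0]
    schedule = [np.asarray(lik, dtype=float) for lik in likelihood_schedule]
    n_m = schedule[0].shape[1]
    for lik in schedule:
        if lik.shape != (n_e, n_m):
            raise ValidationError("all likelihoods in a schedule must share state spaces")
    agent_lik = schedule[0]

    rng = np.random.default_rng(seed)
    e = rng.choice(n_e, p=p)
    belief = p.copy()
    values = np.empty(horizon)
    for t in range(horizon):
        if t > 0 and rng.random() >= persistence:
            e = rng.choice(n_e, p=p)
        true_lik = schedule[t % len(schedule)]
        m = rng.choice(n_m, p=true_lik[e])
        # Predict with yesterday's posterior, then observe and update.
        predicted = persistence * belief + (1.0 - persistence) * p
        p_m = float(predicted @ agent_lik[:, m])
        if p_m <= 0:
            values[t] = float("inf")
            belief = p.copy()
            continue
        values[t] = -math.log(p_m)
        belief = predicted * agent_lik[:, m] / p_m
    mean = float(values.mean())
    if return_stderr:
        return mean, float(values.std(ddof=1) / math.sqrt(horizon))
    return mean
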