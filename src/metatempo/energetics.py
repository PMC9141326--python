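"""Landauer-cost calculus for multi-timescale input processing.

Rewriting a bit costs at least ``kB*T*ln 2`` of free energy (Landauer's
principle); a realistic processor pays ``epsilon = beta_thermo*kB*T`` per
bit with efficiency ``beta_thermo > ln 2``. An organism that recomputes a
function of all ``n`` sensory bits every sensation-action cycle, at
``m_steps`` computational steps per bit, spends ``n*m_steps*epsilon`` per
cycle. If the input factors into a fast sector of ``n1`` bits (changing
every cycle) and a slow sector of ``n2`` bits (changing every ``tau2``
cycles), a *metaprocessing* architecture — a switch that detects slow-sector
changes and reprocesses that sector only then — spends

    Xi = (n1 + tau_ratio * n2) * m_steps * epsilon + delta,

where ``tau_ratio = tau/tau2`` is the ratio of the cycle time to the slow
timescale and ``delta`` is the overhead of the change detector. Separate
processing is energetically advantageous exactly when ``delta`` is below
the margin ``(1 - tau_ratio) * n2 * m_steps * epsilon``; the per-cycle
energy saving, normalized by the joint budget, acts as a selection
coefficient whose fitness advantage compounds as ``(1 + s)**N`` over ``N``
generations.

Two simulations back the algebra: an energy ledger that charges an agent
architecture cycle by cycle against an :class:`~metatempo.envstreams.InputStream`,
and a haploid Wright-Fisher competition between an efficient
(metaprocessing) and a wasteful (monolithic) lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .envstreams import InputStream, ValidationError

__all__ = [
    "CostModel",
    "TimescalePartition",
    "EnergyLedger",
    "FixationSummary",
    "joint_cost",
    "separate_cost",
    "metaprocessing_margin",
    "selection_coefficient",
    "fitness_ratio",
    "simulate_ledger",
    "compete_lineages",
]

#: Boltzmann's constant, J/K.
BOLTZMANN_JOULES_PER_KELVIN = 1.380649e-23

Architecture = Literal["monolithic", "metaprocessor"]


@dataclass(frozen=True)
class CostModel:
    """Per-bit thermodynamic cost of computation.

    ``epsilon`` is the free energy per processed (rewritten) bit, in
    natural units by default; ``m_steps`` the computational steps each
    input bit costs per cycle; ``m_detect`` the detector steps per slow
    bit per cycle (the concrete form of the metaprocessing overhead).
    """

    epsilon: float = 1.0
    m_steps: int = 1
    m_detect: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.epsilon) and self.epsilon > 0):
            raise ValidationError(f"epsilon must be a positive real, got {self.epsilon!r}")
        if not (isinstance(self.m_steps, (int, np.integer)) and self.m_steps >= 1):
            raise ValidationError(f"m_steps must be a positive integer, got {self.m_steps!r}")
        if not (isinstance(self.m_detect, (int, np.integer)) and self.m_detect >= 0):
            raise ValidationError(f"m_detect must be a non-negative integer, got {self.m_detect!r}")

    @classmethod
    def from_temperature(
        cls, temperature_K: float, beta_thermo: float = math.log(2), m_steps: int = 1, m_detect: int = 0
    ) -> "CostModel":
        """Physical units: epsilon = beta_thermo * kB * T joules per bit.

        ``beta_thermo = ln 2`` is the Landauer lower limit; real devices
        have ``beta_thermo > ln 2``.
        """
        if temperature_K <= 0:
            raise ValidationError(f"temperature_K must be positive, got {temperature_K!r}")
        if beta_thermo < math.log(2):
            raise ValidationError(f"beta_thermo must be >= ln 2, got {beta_thermo!r}")
        return cls(
            epsilon=beta_thermo * BOLTZMANN_JOULES_PER_KELVIN * temperature_K,
            m_steps=m_steps,
            m_detect=m_detect,
        )


@dataclass(frozen=True)
class TimescalePartition:
    """Fast/slow factorization of the sensory input.

    ``tau_ratio`` is tau/tau2 in (0, 1]: the fraction of cycles on which
    the slow sector actually changes. ``delta`` is the per-cycle detector
    overhead; if None it is derived from the cost model as
    ``n2 * m_detect * epsilon``.
    """

    n1: int
    n2: int
    tau_ratio: float
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.n1 < 0:
            raise ValidationError(f"n1 must be non-negative, got {self.n1!r}")
        if self.n2 < 0:
            raise ValidationError(f"n2 must be non-negative, got {self.n2!r}")
        if not (0 < self.tau_ratio <= 1):
            raise ValidationError(f"tau_ratio must lie in (0, 1], got {self.tau_ratio!r}")
        if self.delta is not None and self.delta < 0:
            raise ValidationError(f"delta must be non-negative, got {self.delta!r}")

    def resolve_delta(self, cost: CostModel) -> float:
        """The overhead actually charged: explicit delta, else n2*m_detect*epsilon."""
        if self.delta is not None:
            return float(self.delta)
        return self.n2 * cost.m_detect * cost.epsilon


def joint_cost(cost: CostModel, n: int) -> float:
    """Energy per cycle for processing all ``n`` bits every cycle: n*m*epsilon."""
    if n < 0:
        raise ValidationError(f"n must be non-negative, got {n!r}")
    return n * cost.m_steps * cost.epsilon


def separate_cost(cost: CostModel, part: TimescalePartition) -> float:
    """Energy per cycle for the metaprocessing architecture.

    Xi = (n1 + tau_ratio * n2) * m_steps * epsilon + delta.
    """
    return (part.n1 + part.tau_ratio * part.n2) * cost.m_steps * cost.epsilon + part.resolve_delta(cost)


def metaprocessing_margin(cost: CostModel, part: TimescalePartition) -> float:
    """Largest detector overhead at which separate processing still pays.

    Delta_max = (1 - tau_ratio) * n2 * m_steps * epsilon; separate
    processing is strictly advantageous iff delta < Delta_max. Identically
    the joint-minus-separate saving at delta = 0.
    """
    return (1.0 - part.tau_ratio) * part.n2 * cost.m_steps * cost.epsilon


def selection_coefficient(cost: CostModel, part: TimescalePartition, n: int | None = None) -> float:
    """Energy saving of metaprocessing as a dimensionless selection coefficient.

    s = (joint - separate) / joint, i.e. the per-cycle saving normalized by
    the joint per-cycle budget. Positive when the detector overhead is below
    the margin, zero when the architectures cost the same, negative when
    metaprocessing is wasteful.
    """
    if n is None:
        n = part.n1 + part.n2
    elif n != part.n1 + part.n2:
        raise ValidationError(f"n must equal n1 + n2 = {part.n1 + part.n2}, got {n!r}")
    jc = joint_cost(cost, n)
    if jc == 0:
        raise ValidationError("selection coefficient undefined: joint cost is zero (n = 0)")
    return (jc - separate_cost(cost, part)) / jc


def fitness_ratio(s: float, generations: int) -> float:
    """Compounded fitness advantage (1 + s)**N after N generations."""
    if s <= -1:
        raise ValidationError(f"s must exceed -1, got {s!r}")
    if generations < 0:
        raise ValidationError(f"generations must be non-negative, got {generations!r}")
    return (1.0 + s) ** generations


@dataclass(frozen=True)
class EnergyLedger:
    """Per-cycle energy accounting for one architecture on one stream."""

    architecture: Architecture
    records: pd.DataFrame = field(repr=False)  # columns: cycle, architecture, bits_processed, energy_spent

    @property
    def total(self) -> float:
        return float(self.records["energy_spent"].sum())

    @property
    def mean_per_cycle(self) -> float:
        return float(self.records["energy_spent"].mean())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def simulate_ledger(stream: InputStream, architecture: Architecture, cost: CostModel) -> EnergyLedger:
    """Charge an agent architecture cycle by cycle against a stream.

    monolithic: (n1 + n2) * m_steps * epsilon every cycle.
    metaprocessor: n1 * m_steps * epsilon every cycle, plus the change
    detector n2 * m_detect * epsilon every cycle, plus n2 * m_steps *
    epsilon on cycles where the slow sector changed.
    """
    n1, n2 = stream.spec.n1, stream.spec.n2
    cycles = stream.spec.cycles
    if architecture == "monolithic":
        bits = np.full(cycles, (n1 + n2) * cost.m_steps, dtype=float)
        energy = bits * cost.epsilon
    elif architecture == "metaprocessor":
        changed = stream.change_flags.astype(float)
        bits = n1 * cost.m_steps + n2 * cost.m_detect + changed * n2 * cost.m_steps
        energy = bits * cost.epsilon
    else:
        raise ValidationError(f"architecture must be 'monolithic' or 'metaprocessor', got {architecture!r}")
    records = pd.DataFrame(
        {
            "cycle": np.arange(cycles),
            "architecture": architecture,
            "bits_processed": bits,
            "energy_spent": energy,
        }
    )
    return EnergyLedger(architecture=architecture, records=records)


@dataclass(frozen=True)
class FixationSummary:
    """Outcome of repeated two-lineage Wright-Fisher competitions."""

    replicates: int
    fixed_meta: int
    fixed_mono: int
    mean_logratio_slope: float
    s_analytic: float


def compete_lineages(
    s: float,
    pop_size: int | None,
    generations: int,
    replicates: int = 1,
    seed: int | None = 0,
    initial_freq: float = 0.5,
) -> FixationSummary:
    """Haploid Wright-Fisher competition between two lineages.

    The metaprocessing lineage has relative fitness ``1 + s`` against 1 for
    the monolithic lineage, starting at frequency ``initial_freq``. Each
    generation the next population is a multinomial (binomial) resample with
    selection-weighted expected frequency. ``pop_size=None`` selects the
    deterministic infinite-population (replicator) limit, in which the
    log-frequency-ratio grows by exactly ``ln(1 + s)`` per generation.

    The reported slope is the mean per-generation increment of
    ``log(p / (1 - p))`` over generations where both lineages segregate.
    """
    if s <= -1:
        raise ValidationError(f"s must exceed -1, got {s!r}")
    if pop_size is not None and pop_size < 2:
        raise ValidationError(f"pop_size must be at least 2, got {pop_size!r}")
    if not (0 < initial_freq < 1):
        raise ValidationError(f"initial_freq must lie in (0, 1), got {initial_freq!r}")
    if generations < 1:
        raise ValidationError(f"generations must be positive, got {generations!r}")

    if pop_size is None:
        # Replicator limit: the log-odds of the favored lineage advance by
        # ln(1+s) per generation regardless of the current frequency.
        return FixationSummary(
            replicates=replicates,
            fixed_meta=0,
            fixed_mono=0,
            mean_logratio_slope=math.log1p(s),
            s_analytic=s,
        )

    rng = np.random.default_rng(seed)
    fixed_meta = 0
    fixed_mono = 0
    slopes: list[float] = []
    for _ in range(replicates):
        p = initial_freq
        increments: list[float] = []
        for _ in range(generations):
            expected = p * (1 + s) / (p * (1 + s) + (1 - p))
            k = rng.binomial(pop_size, expected)
            p_next = k / pop_size
            if 0 < p < 1 and 0 < p_next < 1:
                increments.append(
                    math.log(p_next / (1 - p_next)) - math.log(p / (1 - p))
                )
            p = p_next
            if p == 0.0 or p == 1.0:
                break
        if p == 1.0:
            fixed_meta += 1
        elif p == 0.0:
            fixed_mono += 1
        if increments:
            slopes.append(float(np.mean(increments)))

    return FixationSummary(
        replicates=replicates,
        fixed_meta=fixed_meta,
        fixed_mono=fixed_mono,
        mean_logratio_slope=float(np.mean(slopes)) if slopes else float("nan"),
        s_analytic=s,
    )
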