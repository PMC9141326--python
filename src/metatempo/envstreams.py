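"""Synthetic two-timescale sensory environments.

An agent reads a vector of sensory bits once per sensation-action cycle.
The environment drives those bits through two independent stochastic
processes: a *fast* sector ``s1`` of ``n1`` bits that is resampled every
cycle (characteristic timescale of one cycle), and a *slow* sector ``s2``
of ``n2`` bits whose state changes only every ``tau2`` cycles on average.
Streams produced here are the inputs to the energy-ledger experiments in
:mod:`metatempo.energetics`: the whole point of the two-sector structure is
that an architecture which notices that ``s2`` rarely changes can skip
reprocessing it.

Two change schedules are provided. ``periodic`` changes the slow sector at
exactly every ``round(tau2)``-th cycle, which makes cost-ledger comparisons
against the closed-form separate-processing cost exact. ``geometric``
changes it independently each cycle with probability ``1/tau2``, giving a
geometric inter-change interval with mean ``tau2``; ledger comparisons then
hold statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["StreamSpec", "InputStream", "generate_stream"]

Schedule = Literal["periodic", "geometric"]


class ValidationError(ValueError):
    """Raised when a specification field is out of range; names the field."""


@dataclass(frozen=True)
class StreamSpec:
    """Parameters of a two-timescale bit stream.

    Parameters
    ----------
    n1, n2 : int
        Number of fast / slow sensory bits. At least one bit total.
    tau2 : float
        Mean number of cycles between slow-sector changes, >= 1. The fast
        sector's timescale is fixed at one cycle.
    schedule : {"periodic", "geometric"}
        Deterministic or memoryless change process for the slow sector.
    cycles : int
        Number of sensation-action cycles to generate.
    seed : int
        Seed for the stream's private random generator.
    """

    n1: int
    n2: int
    tau2: float
    schedule: Schedule = "periodic"
    cycles: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n1, (int, np.integer)) and self.n1 >= 0):
            raise ValidationError(f"n1 must be a non-negative integer, got {self.n1!r}")
        if not (isinstance(self.n2, (int, np.integer)) and self.n2 >= 0):
            raise ValidationError(f"n2 must be a non-negative integer, got {self.n2!r}")
        if self.n1 + self.n2 < 1:
            raise ValidationError("n1 + n2 must be at least 1")
        if not np.isfinite(self.tau2) or self.tau2 < 1:
            raise ValidationError(f"tau2 must be a finite real >= 1, got {self.tau2!r}")
        if self.schedule not in ("periodic", "geometric"):
            raise ValidationError(f"schedule must be 'periodic' or 'geometric', got {self.schedule!r}")
        if not (isinstance(self.cycles, (int, np.integer)) and self.cycles >= 1):
            raise ValidationError(f"cycles must be a positive integer, got {self.cycles!r}")


@dataclass(frozen=True)
class InputStream:
    """A realized stream: one row of bits per cycle plus change annotations.

    ``frames`` has shape ``(cycles, n1 + n2)``; the first ``n1`` columns are
    the fast sector, the rest the slow sector. ``change_flags[t]`` is True
    iff the slow sector at cycle ``t`` differs from cycle ``t - 1`` (the
    first cycle is always flagged: the initial state counts as a change).
    """

    spec: StreamSpec
    frames: np.ndarray = field(repr=False)
    change_flags: np.ndarray = field(repr=False)

    @property
    def fast(self) -> np.ndarray:
        return self.frames[:, : self.spec.n1]

    @property
    def slow(self) -> np.ndarray:
        return self.frames[:, self.spec.n1 :]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: cycle, s1_bits, s2_bits (bitstrings), s2_changed."""
        s1 = ["".join(map(str, row)) for row in self.fast]
        s2 = ["".join(map(str, row)) for row in self.slow]
        return pd.DataFrame(
            {
                "cycle": np.arange(self.spec.cycles),
                "s1_bits": s1,
                "s2_bits": s2,
                "s2_changed": self.change_flags.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _change_cycles(spec: StreamSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of cycles at which the slow sector is resampled."""
    flags = np.zeros(spec.cycles, dtype=bool)
    flags[0] = True
    if spec.schedule == "periodic":
        period = int(round(spec.tau2))
        flags[::period] = True
    else:
        flags[1:] |= rng.random(spec.cycles - 1) < 1.0 / spec.tau2
    return flags


def generate_stream(spec: StreamSpec) -> InputStream:
    """Generate a two-timescale bit stream.

    The fast sector is i.i.d. uniform each cycle. The slow sector is held
    constant between change cycles; at a change cycle it is resampled
    uniformly and forced to differ from its previous value (on the
    probability-``2**-n2`` collision a random bit is flipped), so the
    change annotations coincide exactly with the schedule.

    Identical specs (including the seed) give bitwise-identical streams.
    """
    rng = np.random.default_rng(spec.seed)
    flags = _change_cycles(spec, rng)

    frames = np.empty((spec.cycles, spec.n1 + spec.n2), dtype=np.uint8)
    frames[:, : spec.n1] = rng.integers(0, 2, size=(spec.cycles, spec.n1), dtype=np.uint8)

    slow = rng.integers(0, 2, size=spec.n2, dtype=np.uint8)
    for t in range(spec.cycles):
        if flags[t] and t > 0 and spec.n2 > 0:
            new = rng.integers(0, 2, size=spec.n2, dtype=np.uint8)
            if np.array_equal(new, slow):
                new[rng.integers(spec.n2)] ^= 1
            slow = new
        frames[t, spec.n1 :] = slow

    if spec.n2 == 0:
        flags = np.zeros(spec.cycles, dtype=bool)
        flags[0] = True
    return InputStream(spec=spec, frames=frames, change_flags=flags)
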