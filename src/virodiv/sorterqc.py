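"""Droplet-coincidence arithmetic for single-particle flow sorting.

A jet-in-air sorter generates drops at the piezoelectric frequency; detected
events minus the electronic-noise baseline give the net particle rate.  The
drops-per-particle ratio says how sparsely particles are spread across drops
(the worked configuration: 38,700 drops/s against a net 30 particles/s gives
1,290 ~ 1/1,300), and a Poisson occupancy model turns the same numbers into
the probability that an occupied drop actually holds two or more particles —
the doublet risk that single-virus sorting has to keep negligible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InputError, UndefinedStatisticError


@dataclass(frozen=True)
class SorterParams:
    drop_frequency_hz: float = 38700.0
    event_rate_hz: float = 50.0
    noise_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        if min(self.drop_frequency_hz, self.event_rate_hz, self.noise_rate_hz) < 0:
            raise InputError("rates must be non-negative")
        if self.event_rate_hz < self.noise_rate_hz:
            raise InputError("event rate must be >= noise rate")

    @property
    def net_particle_rate_hz(self) -> float:
        return self.event_rate_hz - self.noise_rate_hz


@dataclass(frozen=True)
class DropRatio:
    raw: float
    rounded_to_hundred: int


def drop_particle_ratio(params: SorterParams) -> DropRatio:
    """Drops generated per sorted particle, raw and rounded to the nearest 100."""
    net = params.net_particle_rate_hz
    if net <= 0:
        raise UndefinedStatisticError("net particle rate must be positive")
    raw = params.drop_frequency_hz / net
    return DropRatio(raw=raw, rounded_to_hundred=int(round(raw / 100.0)) * 100)


def doublet_probability(params: SorterParams) -> float:
    """P(drop holds >= 2 particles | it holds >= 1) under Poisson occupancy.

    With occupancy lambda = net rate / drop frequency this is
    (1 - e^-l - l e^-l) / (1 - e^-l); for small lambda it approaches l/2.
    """
    net = params.net_particle_rate_hz
    if net <= 0:
        raise UndefinedStatisticError("net particle rate must be positive")
    lam = net / params.drop_frequency_hz
    if lam > 1:
        warnings.warn(
            f"occupancy lambda={lam:.2f} > 1: far outside the single-particle regime",
            stacklevel=2,
        )
    denom = 1.0 - math.exp(-lam)
    return (denom - lam * math.exp(-lam)) / denom
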