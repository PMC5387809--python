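"""Synthetic data generators.

Everything the pipeline consumes can be generated here so that every stage
is testable offline: noisy two-phase SPR sensorgrams from known kinetic
truth, uniform random aptamer populations, and a motif-count fitness oracle
that stands in for experimental binding signals when exercising the GA
loop end to end.  The fitness oracle is explicitly *not* a binding-affinity
model — it exists to make selection pressure observable in tests.

Defaults mirror the experimental protocol the toolkit targets: a 30 min
association phase and a 13 min dissociation phase sampled at 1 Hz, analyte
at 2 ng/ml (about 6e-11 M for a 33 kDa protein).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biosensor import (
    ASSOCIATION,
    DISSOCIATION,
    KineticParams,
    Sensorgram,
    langmuir_response,
)
from .errors import InputError
from .seqio import AptamerSequence

#: Protocol durations (s): 30 min association, 13 min dissociation.
DEFAULT_T_ASSOC = 1800.0
DEFAULT_T_DISSOC = 780.0


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and acquisition settings for a synthetic sensorgram."""

    ka: float = 1e5  # M^-1 s^-1
    kd: float = 1e-3  # s^-1
    rmax: float = 1.0  # response units
    concentration: float = 1e-8  # M
    t_assoc: float = DEFAULT_T_ASSOC  # s
    t_dissoc: float = DEFAULT_T_DISSOC  # s
    sampling_hz: float = 1.0
    noise_sd: float = 0.0  # response units, additive Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_assoc <= 0 or self.t_dissoc <= 0 or self.sampling_hz <= 0:
            raise InputError("durations and sampling rate must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")

    @property
    def truth(self) -> KineticParams:
        return KineticParams(self.ka, self.kd, self.rmax)


def simulate_sensorgram(spec: SimulationSpec) -> Sensorgram:
    """Model curve plus i.i.d. Gaussian noise; reproducible under seed."""
    dt = 1.0 / spec.sampling_hz
    t = np.arange(dt, spec.t_assoc + spec.t_dissoc + dt / 2, dt)
    clean = langmuir_response(
        t, spec.truth, spec.concentration, t_dissoc_start=spec.t_assoc
    )
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=t.shape)
    phase = np.where(t < spec.t_assoc, ASSOCIATION, DISSOCIATION)
    return Sensorgram(t, noisy, phase, spec.concentration)


def random_population(
    n: int, length: int = 24, seed: int = 0, prefix: str = "SEQ"
) -> list[AptamerSequence]:
    """n aptamers with uniform i.i.d. variable regions, named sequentially."""
    if n < 0 or (n > 0 and length < 1):
        raise InputError("need n >= 0 and length >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ATGC"))
    return [
        AptamerSequence(
            f"{prefix}{i + 1}",
            "".join(rng.choice(bases, size=length)),
        )
        for i in range(n)
    ]


def synthetic_fitness(
    seq: AptamerSequence, motif: str, weight: float = 1.0
) -> float:
    """Weighted count of (overlapping) motif matches in the variable region."""
    if not motif:
        raise InputError("motif must be non-empty")
    region = seq.variable_region
    count = sum(
        1
        for i in range(len(region) - len(motif) + 1)
        if region[i : i + len(motif)] == motif
    )
    return weight * count
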