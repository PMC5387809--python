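"""Genetic-algorithm engine for in silico aptamer maturation.

One maturation round takes a small pool of experimentally validated parent
aptamers and produces a next-generation candidate pool by *reproduction*
(copying a parent unchanged) and *crossover* (recombining two parents'
chromosomes at one or more cut points) on the 2-bit base encoding.  An
optional per-bit mutation operator is available; its default rate is 0 so
that, out of the box, every offspring position is attributable to one of
its parents.

Cut points live on *bit* boundaries by default, because the search operates
on the binary coding: a cut between the two bits of one base can create a
base present in neither parent at that position.  Set
``GAConfig.base_boundary_cuts`` to restrict cuts to whole-base boundaries.

:func:`explain_offspring` solves the inverse problem — given an offspring
and a parent pool, find the crossover template (parent pair + cut points)
that explains it with the fewest unexplained (mutated) positions.  It is an
exhaustive search and is meant for auditing published offspring pools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .seqio import AptamerSequence, BitChromosome, decode_bits, encode_bits

SELECTION_SCHEMES = ("uniform", "fitness_proportional")


@dataclass(frozen=True)
class GAConfig:
    """Knobs for one generation step.

    n_offspring          number of candidates to produce
    n_crossover_points   cuts per crossover event (0 = pure reproduction)
    mutation_rate        independent per-bit flip probability
    selection_scheme     'uniform' or 'fitness_proportional'
    rng_seed             seed for the single generator threaded everywhere
    base_boundary_cuts   restrict cut points to whole-base boundaries
    dedup                drop duplicate offspring (resampling to keep count)
    """

    n_offspring: int
    n_crossover_points: int = 1
    mutation_rate: float = 0.0
    selection_scheme: str = "uniform"
    rng_seed: int = 0
    base_boundary_cuts: bool = False
    dedup: bool = False
    name_prefix: str = "PSAG"

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise InputError("n_offspring must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise InputError("mutation_rate must be in [0, 1]")
        if self.n_crossover_points < 0:
            raise InputError("n_crossover_points must be >= 0")
        if self.selection_scheme not in SELECTION_SCHEMES:
            raise InputError(
                f"selection_scheme must be one of {SELECTION_SCHEMES}"
            )


@dataclass(frozen=True)
class LineageRecord:
    """How one offspring was built: parents, cuts, and mutated bit positions."""

    offspring_name: str
    parent_a: str
    parent_b: str
    cut_points: tuple[int, ...]  # bit indices, strictly increasing
    mutated_bits: tuple[int, ...]


@dataclass(frozen=True)
class Generation:
    """A full generation step: inputs, outputs and per-offspring lineage."""

    index: int
    parents: tuple[AptamerSequence, ...]
    offspring: tuple[AptamerSequence, ...]
    lineage: tuple[LineageRecord, ...]
    config: GAConfig


@dataclass(frozen=True)
class ProvenanceReport:
    """Best crossover explanations for one offspring against a parent pool.

    ``min_mutations`` is the smallest number of offspring positions not
    matching the implied parental template over every ordered parent pair and
    every placement of at most ``max_cut_points`` base-level cuts searched.
    ``best_explanations`` lists every (parent_a, parent_b, cut_points) tuple
    achieving that minimum, with the unexplained base positions (0-based).
    """

    offspring_name: str
    min_mutations: int
    best_explanations: tuple[tuple[str, str, tuple[int, ...], tuple[int, ...]], ...]
    max_cut_points: int


def select_parent_pairs(
    parents: list[AptamerSequence],
    fitness: dict[str, float] | None,
    n_pairs: int,
    config: GAConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[AptamerSequence, AptamerSequence]]:
    """Draw ordered parent pairs with replacement.

    Under ``fitness_proportional`` each slot is drawn with probability
    proportional to its (non-negative) fitness; under ``uniform`` all parents
    are equiprobable.
    """
    if not parents:
        raise InputError("parent list is empty")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if config.selection_scheme == "fitness_proportional":
        if fitness is None:
            raise InputError("fitness_proportional selection requires fitness")
        missing = [p.name for p in parents if p.name not in fitness]
        if missing:
            raise InputError(f"fitness missing for parents: {missing}")
        weights = np.array([fitness[p.name] for p in parents], dtype=float)
        if np.any(weights < 0):
            raise InputError("fitness values must be non-negative")
        total = weights.sum()
        if total <= 0:
            raise InputError("all-zero fitness: proportional selection degenerate")
        probs = weights / total
    else:
        probs = np.full(len(parents), 1.0 / len(parents))
    idx = rng.choice(len(parents), size=(n_pairs, 2), p=probs)
    return [(parents[a], parents[b]) for a, b in idx]


def crossover(
    parent_a: BitChromosome,
    parent_b: BitChromosome,
    cut_points: list[int] | tuple[int, ...],
    take_first_from: str = "A",
) -> BitChromosome:
    """Recombine two chromosomes, switching source parent at each cut.

    ``cut_points`` are strictly increasing bit indices in (0, length); an
    empty list is plain reproduction of the flagged parent.
    """
    if len(parent_a) != len(parent_b):
        raise InputError("parent chromosomes differ in length")
    n = len(parent_a)
    cuts = tuple(cut_points)
    if any(c2 <= c1 for c1, c2 in zip(cuts, cuts[1:])):
        raise InputError(f"cut points must be strictly increasing: {cuts}")
    if any(not 0 < c < n for c in cuts):
        raise InputError(f"cut points must lie in (0, {n}): {cuts}")
    if take_first_from not in ("A", "B"):
        raise InputError("take_first_from must be 'A' or 'B'")
    sources = (parent_a, parent_b) if take_first_from == "A" else (parent_b, parent_a)
    bits: list[int] = []
    bounds = (0,) + cuts + (n,)
    for seg, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        bits.extend(sources[seg % 2].bits[lo:hi])
    return BitChromosome(tuple(bits))


def mutate(
    chromosome: BitChromosome, rate: float, rng: np.random.Generator
) -> tuple[BitChromosome, tuple[int, ...]]:
    """Flip each bit independently with probability ``rate``.

    Returns the mutated chromosome and the flipped bit positions.
    """
    if not 0.0 <= rate <= 1.0:
        raise InputError("mutation rate must be in [0, 1]")
    if rate == 0.0:
        return chromosome, ()
    flips = rng.random(len(chromosome)) < rate
    bits = tuple(b ^ int(f) for b, f in zip(chromosome.bits, flips))
    return BitChromosome(bits), tuple(int(i) for i in np.flatnonzero(flips))


def _draw_cuts(
    rng: np.random.Generator, n_bits: int, n_cuts: int, base_boundary: bool
) -> tuple[int, ...]:
    if n_cuts == 0:
        return ()
    if base_boundary:
        candidates = np.arange(2, n_bits, 2)
    else:
        candidates = np.arange(1, n_bits)
    n_cuts = min(n_cuts, len(candidates))
    return tuple(sorted(int(c) for c in rng.choice(candidates, n_cuts, replace=False)))


def next_generation(
    parents: list[AptamerSequence],
    fitness: dict[str, float] | None,
    config: GAConfig,
    generation_index: int = 2,
) -> Generation:
    """Produce one generation of named offspring with full lineage records.

    Offspring are named ``<prefix><generation><i>`` (e.g. PSAG28 for the
    8th offspring of generation 2).  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_bits = 2 * len(parents[0].variable_region)
    offspring: list[AptamerSequence] = []
    lineage: list[LineageRecord] = []
    seen: set[str] = set()
    attempts = 0
    while len(offspring) < config.n_offspring:
        attempts += 1
        if attempts > 100 * config.n_offspring:
            raise InputError(
                "dedup could not produce enough distinct offspring"
            )
        (pa, pb) = select_parent_pairs(parents, fitness, 1, config, rng)[0]
        cuts = _draw_cuts(rng, n_bits, config.n_crossover_points, config.base_boundary_cuts)
        child_bits = crossover(encode_bits(pa), encode_bits(pb), cuts)
        child_bits, mutated = mutate(child_bits, config.mutation_rate, rng)
        name = f"{config.name_prefix}{generation_index}{len(offspring) + 1}"
        child = decode_bits(
            child_bits, name=name, flank5=pa.flank5, flank3=pa.flank3
        )
        if config.dedup and child.variable_region in seen:
            continue
        seen.add(child.variable_region)
        offspring.append(child)
        lineage.append(
            LineageRecord(name, pa.name, pb.name, cuts, mutated)
        )
    return Generation(
        index=generation_index,
        parents=tuple(parents),
        offspring=tuple(offspring),
        lineage=tuple(lineage),
        config=config,
    )


def explain_offspring(
    offspring: AptamerSequence,
    parents: list[AptamerSequence],
    max_cut_points: int = 1,
) -> ProvenanceReport:
    """Exhaustively search crossover templates explaining an offspring.

    Cuts are placed on base boundaries (positions 1..L-1 of the variable
    region); for each ordered parent pair and each choice of 0..max cuts the
    template alternates parental segments, and the mismatch count is the
    number of offspring positions differing from the template.  All minimal
    explanations are reported.
    """
    region = offspring.variable_region
    n = len(region)
    for p in parents:
        if len(p.variable_region) != n:
            raise InputError(
                f"parent {p.name!r} length differs from offspring"
            )
    best = n + 1
    explanations: list[tuple[str, str, tuple[int, ...], tuple[int, ...]]] = []
    for pa, pb in itertools.product(parents, repeat=2):
        a, b = pa.variable_region, pb.variable_region
        for k in range(max_cut_points + 1):
            if k > 0 and pa.name == pb.name:
                continue  # cutting between identical parents adds nothing
            for cuts in itertools.combinations(range(1, n), k):
                bounds = (0,) + cuts + (n,)
                template = "".join(
                    (a if seg % 2 == 0 else b)[lo:hi]
                    for seg, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
                )
                mismatches = tuple(
                    i for i in range(n) if region[i] != template[i]
                )
                if len(mismatches) < best:
                    best = len(mismatches)
                    explanations = [(pa.name, pb.name, cuts, mismatches)]
                elif len(mismatches) == best:
                    explanations.append((pa.name, pb.name, cuts, mismatches))
    # simplest explanation first: fewest cuts, then parent-name order
    explanations.sort(key=lambda e: (len(e[2]), e[0], e[1], e[2]))
    return ProvenanceReport(
        offspring_name=offspring.name,
        min_mutations=best,
        best_explanations=tuple(explanations),
        max_cut_points=max_cut_points,
    )
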