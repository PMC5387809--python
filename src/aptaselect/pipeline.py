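"""Orchestration of one maturation round: evolve -> screen -> rank -> select.

A round starts either from parent aptamers (the GA produces the candidate
pool) or from an already-printed candidate pool (sequences + structures
supplied directly).  Structures and docking scores are always external
inputs: folding and docking run outside this toolkit, and their outputs are
ingested per candidate name.  The stages then run in fixed order —
secondary-structure elimination, ZRANK ranking of the survivors, top-k
selection — and the report records every elimination with its reason, the
full ranking, the GA lineage (when evolved) and the seed/config hash so a
rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import seqio
from .errors import InputError
from .ga import GAConfig, Generation, next_generation
from .ranking import (
    RankedCandidates,
    ScoreTable,
    load_scores,
    rank_by_zrank,
    select_top_k,
)
from .structure import FilterOutcome, SecondaryStructure, filter_population, read_vienna


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and knobs for one round.

    Exactly one candidate source is required: ``parents_fasta`` (GA breeds
    the pool; a Vienna structures file for the offspring is then mandatory)
    or ``structures_vienna`` alone (pool = the records in that file).
    """

    structures_vienna: str | None = None
    scores_tsv: str | None = None
    parents_fasta: str | None = None
    fitness_tsv: str | None = None
    k: int = 1
    generation_index: int = 2
    n_offspring: int = 12
    n_crossover_points: int = 1
    mutation_rate: float = 0.0
    selection_scheme: str = "uniform"
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GenerationReport:
    """Everything one round produced, JSON-serializable and deterministic."""

    generation_index: int
    seed: int
    config_hash: str
    candidates: tuple[str, ...]
    filter_outcome: FilterOutcome
    ranking: RankedCandidates
    selected: tuple[str, ...]
    offspring_fasta: str
    lineage: tuple | None
    log: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "generation_index": self.generation_index,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_generated": len(self.candidates),
            "n_kept": len(self.filter_outcome.kept),
            "n_removed": len(self.filter_outcome.removed),
            "candidates": list(self.candidates),
            "kept": list(self.filter_outcome.kept),
            "removed": {
                name: self.filter_outcome.reasons[name]
                for name in self.filter_outcome.removed
            },
            "ranking": [list(e) for e in self.ranking.entries],
            "selected": list(self.selected),
            "lineage": [dataclasses.asdict(l) for l in self.lineage]
            if self.lineage
            else None,
            "log": list(self.log),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, ensure_ascii=False, indent=2)


def _read_fitness(path: str) -> dict[str, float]:
    fitness: dict[str, float] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise InputError(f"fitness line needs 2 columns: {ln!r}")
        if parts[0] == "name":
            continue
        fitness[parts[0]] = float(parts[1])
    return fitness


def run_generation(config: PipelineConfig) -> GenerationReport:
    """Run one full round per the configured candidate source.

    Raises :class:`InputError` naming the absent file when a stage's input
    is missing.
    """
    log: list[str] = [f"seed={config.seed}", f"config={config.config_hash()}"]

    lineage = None
    if config.parents_fasta is not None:
        parents = seqio.read_fasta_file(config.parents_fasta)
        fitness = (
            _read_fitness(config.fitness_tsv) if config.fitness_tsv else None
        )
        ga_config = GAConfig(
            n_offspring=config.n_offspring,
            n_crossover_points=config.n_crossover_points,
            mutation_rate=config.mutation_rate,
            selection_scheme=config.selection_scheme,
            rng_seed=config.seed,
        )
        gen = next_generation(
            parents, fitness, ga_config, config.generation_index
        )
        candidates = list(gen.offspring)
        lineage = gen.lineage
        log.append(
            f"evolve: {len(parents)} parents -> {len(candidates)} offspring"
        )
    elif config.structures_vienna is None:
        raise InputError(
            "no candidate source: provide parents_fasta or structures_vienna"
        )
    else:
        candidates = None  # taken from the structures file below

    # --- structure screen ---------------------------------------------
    if config.structures_vienna is None:
        raise InputError(
            "structure stage input missing: structures_vienna not set"
        )
    if not Path(config.structures_vienna).exists():
        raise InputError(
            f"structure stage input missing: {config.structures_vienna}"
        )
    vienna = read_vienna(
        Path(config.structures_vienna).read_text(), to_dna=True
    )
    struct_by_name = {name: st for name, _seq, st in vienna}
    if candidates is None:
        candidates = [
            seqio.split_flanks(name, seq) for name, seq, _st in vienna
        ]
    missing = [c.name for c in candidates if c.name not in struct_by_name]
    if missing:
        raise InputError(
            f"structure stage input missing structures for: {missing} "
            f"(file {config.structures_vienna})"
        )
    outcome = filter_population(
        [(c.name, struct_by_name[c.name]) for c in candidates]
    )
    log.append(
        f"filter: kept {len(outcome.kept)}, removed {len(outcome.removed)}"
    )

    # --- ranking + selection ------------------------------------------
    if config.scores_tsv is None or not Path(config.scores_tsv).exists():
        raise InputError(
            f"ranking stage input missing: {config.scores_tsv or 'scores_tsv not set'}"
        )
    table = load_scores(Path(config.scores_tsv).read_text())
    kept_set = set(outcome.kept)
    kept_rows = ScoreTable(
        tuple(r for r in table.rows if r.name in kept_set)
    )
    unscored = kept_set - {r.name for r in kept_rows.rows if r.available}
    if unscored:
        raise InputError(
            f"ranking stage input missing scores for kept candidates: "
            f"{sorted(unscored)} (file {config.scores_tsv})"
        )
    ranking = rank_by_zrank(kept_rows)
    selected = tuple(select_top_k(ranking, config.k))
    log.append(f"rank: {len(ranking)} ranked; selected top {len(selected)}")

    report = GenerationReport(
        generation_index=config.generation_index,
        seed=config.seed,
        config_hash=config.config_hash(),
        candidates=tuple(c.name for c in candidates),
        filter_outcome=outcome,
        ranking=ranking,
        selected=selected,
        offspring_fasta=seqio.write_fasta(candidates),
        lineage=lineage,
        log=tuple(log),
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "offspring.fasta").write_text(report.offspring_fasta)
    return report
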