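"""Packaged reference tables for the PSA-aptamer maturation study.

Two candidate generations (sequences, external dot-bracket structures and
minimum free energies, docking scores), the QCM replicate summaries for the
synthesized candidates of each generation, the SPR surface-coverage
summaries, and the fitted SPR kinetic parameters.  These are ingested
experimental/simulation outputs — nothing here is recomputed by the
toolkit; they drive the selection stages and serve as regression fixtures.

The benchmark aptamer ΔPSap4#5 (the best previously published PSA binder)
appears in the QCM/SPR tables as the control; its docking scores were
ZDOCK 45.1 / ZRANK -70.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .ranking import ScoreTable, score_table_from_records
from .seqio import AptamerSequence, split_flanks
from .structure import SecondaryStructure, parse_dotbracket

BENCHMARK_NAME = "ΔPSap4#5"
BENCHMARK_ZDOCK = 45.1
BENCHMARK_ZRANK = -70.0

#: Parents used to breed generation 2, chosen on the generation-1 QCM signal.
GENERATION2_PARENTS = ("PSAG15", "PSAG112", "PSAG117", "PSAG119")


def _read(name: str) -> pd.DataFrame:
    with resources.files("aptaselect.data").joinpath(name).open(
        encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


@dataclass(frozen=True)
class GenerationTable:
    """One candidate generation with structures and docking scores."""

    generation: int
    frame: pd.DataFrame

    def sequences(self) -> list[AptamerSequence]:
        return [
            split_flanks(r["name"], r["sequence"], strict=True)
            for _, r in self.frame.iterrows()
        ]

    def structures(self) -> list[tuple[str, SecondaryStructure]]:
        return [
            (
                r["name"],
                parse_dotbracket(r["dotbracket"], mfe=float(r["mfe"])),
            )
            for _, r in self.frame.iterrows()
        ]

    def scores(self) -> ScoreTable:
        records = []
        for _, r in self.frame.iterrows():
            zd = None if r["zdock"] == "N.A." else float(r["zdock"])
            zr = None if r["zrank"] == "N.A." else float(r["zrank"])
            records.append((r["name"], zd, zr))
        return score_table_from_records(records)

    def sequence_by_name(self, name: str) -> AptamerSequence:
        for s in self.sequences():
            if s.name == name:
                return s
        raise KeyError(name)


def load_generation(generation: int) -> GenerationTable:
    """Candidate pool of generation 1 (20 offspring) or 2 (12 offspring)."""
    if generation not in (1, 2):
        raise ValueError("generation must be 1 or 2")
    return GenerationTable(generation, _read(f"generation{generation}.tsv"))


def load_qcm(generation: int) -> pd.DataFrame:
    """QCM frequency-change summaries (Hz, magnitudes of frequency drops)."""
    if generation not in (1, 2):
        raise ValueError("generation must be 1 or 2")
    df = _read(f"qcm_generation{generation}.tsv")
    for col in df.columns:
        if col != "name":
            df[col] = pd.to_numeric(df[col])
    return df


def load_kinetics() -> pd.DataFrame:
    """Fitted SPR kinetics: ka (x1e3 M^-1 s^-1), kd (x1e-3 s^-1), KA (x1e6 M^-1)."""
    df = _read("spr_kinetics.tsv")
    for col in df.columns:
        if col != "name":
            df[col] = pd.to_numeric(df[col])
    return df


def load_spr_coverage() -> pd.DataFrame:
    """SPR surface-coverage endpoints; note PSAG28's row was printed in
    ng/mm^2 where the others are ng/cm^2 (source inconsistency, preserved)."""
    df = _read("spr_coverage.tsv")
    for col in ("coverage", "coverage_sd"):
        df[col] = pd.to_numeric(df[col])
    return df
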