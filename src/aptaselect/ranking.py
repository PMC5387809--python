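"""Docking-score ingestion, ZRANK ranking and top-k selection.

Candidates that survive the structure screen are docked against the target
protein externally (rigid-body FFT docking rescored with the ZRANK energy
function); this module only *ingests* the resulting score table.  Ranking
is by ZRANK ascending — a lower (more negative) ZRANK score predicts a
better complex — with the raw docking score carried along but never used
for ordering.  ``compare_rankings`` quantifies how well a simulated ranking
agrees with an experimental one.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError, ParseError

NA_TOKENS = {"N.A.", "NA", "N/A", "NaN", ""}


@dataclass(frozen=True)
class ScoreRow:
    name: str
    zdock: float | None
    zrank: float | None
    available: bool


@dataclass(frozen=True)
class ScoreTable:
    rows: tuple[ScoreRow, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate candidate names: {dupes}")

    def available_rows(self) -> list[ScoreRow]:
        return [r for r in self.rows if r.available]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class RankedCandidates:
    """Candidates ordered by ZRANK ascending with 1-based consecutive ranks."""

    entries: tuple[tuple[str, float, int], ...]  # (name, zrank, rank)

    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def rank_of(self, name: str) -> int:
        for n, _, r in self.entries:
            if n == name:
                return r
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)


def _parse_score(token, name: str, column: str) -> float | None:
    if token is None:
        return None
    s = str(token).strip()
    if s in NA_TOKENS:
        return None
    try:
        return float(s.replace("−", "-"))
    except ValueError as exc:
        raise ParseError(
            f"row {name!r}: non-numeric {column} score {s!r}"
        ) from exc


def load_scores(text: str) -> ScoreTable:
    """Parse a TSV with columns name, zdock, zrank ('N.A.' = unavailable)."""
    stripped = text.strip()
    if not stripped:
        return ScoreTable(())
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "zdock", "zrank"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"score table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    rows = []
    for rec in df.itertuples(index=False):
        zd = _parse_score(rec.zdock, rec.name, "zdock")
        zr = _parse_score(rec.zrank, rec.name, "zrank")
        rows.append(ScoreRow(rec.name, zd, zr, available=zr is not None))
    return ScoreTable(tuple(rows))


def score_table_from_records(
    records: Iterable[tuple[str, float | None, float | None]],
) -> ScoreTable:
    return ScoreTable(
        tuple(
            ScoreRow(name, zd, zr, available=zr is not None)
            for name, zd, zr in records
        )
    )


def rank_by_zrank(table: ScoreTable) -> RankedCandidates:
    """Order available rows by ZRANK ascending; ties break lexicographically."""
    rows = table.available_rows()
    if not rows:
        raise InputError("no rows with available scores to rank")
    rows.sort(key=lambda r: (r.zrank, r.name))
    return RankedCandidates(
        tuple((r.name, r.zrank, i + 1) for i, r in enumerate(rows))
    )


def select_top_k(ranked: RankedCandidates, k: int) -> list[str]:
    """First min(k, n) candidate names in rank order."""
    if k < 1:
        raise InputError("k must be >= 1")
    return ranked.names()[:k]


@dataclass(frozen=True)
class RankConcordance:
    """Agreement between an experimental and a simulated ordering."""

    pairs: tuple[tuple[str, int, int], ...]  # (name, rank_exp, rank_sim)
    exact_matches: int
    closest: tuple[str, ...]  # names at the minimal nonzero rank distance
    spearman_rho: float


def compare_rankings(
    experimental: Sequence[str], simulated: Sequence[str]
) -> RankConcordance:
    """Per-name rank pairs, exact-match count and Spearman rank correlation.

    Both arguments are orderings (best first) of the same name set.  Because
    the two rankings are permutations, Spearman's rho reduces to the
    classic 1 - 6*sum(d^2)/(n*(n^2-1)) formula with no tie correction.
    """
    if set(experimental) != set(simulated):
        raise InputError("rankings must cover the same name set")
    if len(set(experimental)) != len(experimental):
        raise InputError("duplicate names in ranking")
    n = len(experimental)
    sim_rank = {name: i + 1 for i, name in enumerate(simulated)}
    pairs = tuple(
        (name, i + 1, sim_rank[name]) for i, name in enumerate(experimental)
    )
    exact = sum(1 for _, re_, rs in pairs if re_ == rs)
    if n < 2:
        rho = float("nan")
    else:
        d2 = sum((re_ - rs) ** 2 for _, re_, rs in pairs)
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    nonzero = [(abs(re_ - rs), name) for name, re_, rs in pairs if re_ != rs]
    if nonzero:
        dmin = min(d for d, _ in nonzero)
        closest = tuple(sorted(name for d, name in nonzero if d == dmin))
    else:
        closest = ()
    return RankConcordance(pairs, exact, closest, rho)
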