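"""Dot-bracket secondary structures: parsing, the elimination filter, and a
base-pair-maximization folder.

Candidate aptamers are screened on their predicted secondary structure: a
sequence whose dot-bracket string contains no brackets at all (every
position unpaired) has no stem-loop to present a binding interface and is
eliminated before any docking simulation.  Structures normally come from an
external thermodynamic folder (Vienna-format files are ingested with their
minimum free energy, MFE); a Nussinov-style maximum-base-pairing folder is
included as a self-contained auxiliary screen — it maximizes Watson-Crick
pair counts, not free energy, and never reproduces external MFE values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import AlphabetError, InputError, StructureError

#: Non-ASCII glyphs that typography sometimes substitutes for runs of '.'.
_PERIOD_LIKE = {
    "…": "...",  # horizontal ellipsis
    "·": ".",    # middle dot
    "․": ".",    # one-dot leader
    "‥": "..",   # two-dot leader
    "。": ".",    # ideographic full stop
}

_CANONICAL_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
_WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})


def normalize_dotbracket(s: str) -> str:
    """Map period-like Unicode glyphs to ASCII '.' and strip whitespace."""
    for glyph, repl in _PERIOD_LIKE.items():
        s = s.replace(glyph, repl)
    return s.strip()


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure in dot-bracket notation.

    ``pair_table`` is 1-based like the classic Vienna convention:
    ``pair_table[i]`` is the partner of position i, or 0 if unpaired
    (index 0 is unused and holds the length).
    """

    dotbracket: str
    pair_table: tuple[int, ...]
    mfe: float | None = None
    source: str = "external"

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def __len__(self) -> int:
        return len(self.dotbracket)


@dataclass(frozen=True)
class FilterOutcome:
    """Partition of a candidate pool into kept and removed names."""

    kept: tuple[str, ...]
    removed: tuple[str, ...]
    reasons: dict[str, str]


def parse_dotbracket(
    s: str, mfe: float | None = None, source: str = "external"
) -> SecondaryStructure:
    """Parse a dot-bracket string, building the pair table by stack matching.

    Unbalanced parentheses or foreign characters raise
    :class:`StructureError`.  Period-like Unicode glyphs are normalized to
    '.' first.
    """
    s = normalize_dotbracket(s)
    n = len(s)
    table = [0] * (n + 1)
    table[0] = n
    stack: list[int] = []
    for pos, c in enumerate(s, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            j = stack.pop()
            table[j] = pos
            table[pos] = j
        elif c != ".":
            raise StructureError(f"foreign character {c!r} at position {pos}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return SecondaryStructure(s, tuple(table), mfe=mfe, source=source)


def is_structured(st: SecondaryStructure) -> bool:
    """True iff the structure contains at least one base pair.

    An all-dots string (equivalently MFE 0 from a thermodynamic folder)
    means no stable secondary structure formed.
    """
    return st.n_pairs > 0


def filter_population(
    candidates: Iterable[tuple[str, SecondaryStructure]],
) -> FilterOutcome:
    """Remove candidates without a clear secondary structure.

    Exactly the candidates with an all-dots dot-bracket are removed; input
    order is preserved within both partitions.  A bracketed structure whose
    stated MFE is 0 is kept (the stated criterion is the dot-bracket
    content), but flagged in the reasons map.
    """
    kept: list[str] = []
    removed: list[str] = []
    reasons: dict[str, str] = {}
    seen: set[str] = set()
    for name, st in candidates:
        if name in seen:
            raise InputError(f"duplicate candidate name {name!r}")
        seen.add(name)
        if is_structured(st):
            kept.append(name)
            if st.mfe == 0:
                reasons[name] = "kept: brackets present despite MFE 0"
        else:
            removed.append(name)
            reasons[name] = "no clear secondary structure (all unpaired)"
    return FilterOutcome(tuple(kept), tuple(removed), reasons)


def _can_pair(a: str, b: str, allow_gt: bool) -> bool:
    pair = (a, b)
    return pair in _CANONICAL_PAIRS or (allow_gt and pair in _WOBBLE_PAIRS)


def nussinov_fold(
    seq: str,
    min_loop: int = 3,
    allow_gt: bool = False,
) -> SecondaryStructure:
    """Maximum-base-pairing fold (Nussinov dynamic program).

    Maximizes the number of allowed base pairs subject to proper nesting and
    a minimum hairpin loop of ``min_loop`` unpaired bases.  Traceback is
    deterministic: when several pairings achieve the optimum, the leftmost
    pairing partner is chosen.  The result carries no free energy — this is
    a combinatorial screen, not a thermodynamic prediction.
    """
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ATGC")
    if bad:
        raise AlphabetError(f"non-ATGC characters {sorted(bad)!r}")
    if min_loop < 0:
        raise InputError("min_loop must be >= 0")
    n = len(seq)
    # dp[i][j]: max pairs in seq[i..j], 0-based inclusive
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if _can_pair(seq[k], seq[j], allow_gt):
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i][j] = best
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j - i > min_loop:
            target = dp[i][j]
            paired = False
            for k in range(i, j - min_loop):
                if not _can_pair(seq[k], seq[j], allow_gt):
                    continue
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + inner + 1 == target:
                    structure[k] = "("
                    structure[j] = ")"
                    traceback(k + 1, j - 1)
                    j_new = k - 1
                    j = j_new
                    paired = True
                    break
            if not paired:
                j -= 1

    if n:
        traceback(0, n - 1)
    st = parse_dotbracket("".join(structure), source="nussinov")
    return st


def read_vienna(text: str, to_dna: bool = False) -> list[tuple[str, str, SecondaryStructure]]:
    """Read Vienna-style records: header, sequence, structure [ (energy) ].

    The optional trailing ``(<energy>)`` on the structure line is parsed
    into the ``mfe`` field.  With ``to_dna=True`` sequence U's become T's.
    """
    out: list[tuple[str, str, SecondaryStructure]] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i].strip()
        if not header.startswith(">"):
            raise StructureError(f"expected FASTA header, got {header!r}")
        if i + 2 >= len(lines):
            raise StructureError(f"truncated record {header!r}")
        seq = lines[i + 1].strip().upper()
        if to_dna:
            seq = seq.replace("U", "T")
        struct_line = normalize_dotbracket(lines[i + 2])
        mfe: float | None = None
        if " " in struct_line:
            db, _, tail = struct_line.partition(" ")
            tail = tail.strip()
            if tail.startswith("(") and tail.endswith(")"):
                try:
                    mfe = float(tail[1:-1].replace("−", "-"))
                except ValueError as exc:
                    raise StructureError(f"bad energy field {tail!r}") from exc
            struct_line = db
        if len(struct_line) != len(seq):
            raise StructureError(
                f"record {header!r}: structure length {len(struct_line)} != "
                f"sequence length {len(seq)}"
            )
        out.append((header[1:], seq, parse_dotbracket(struct_line, mfe=mfe)))
        i += 3
    return out


def structures_to_tsv(
    entries: Sequence[tuple[str, SecondaryStructure]],
) -> str:
    """Export (name, mfe, dotbracket, structured) rows as TSV text."""
    lines = ["name\tmfe\tdotbracket\tstructured"]
    for name, st in entries:
        mfe = "" if st.mfe is None else f"{st.mfe:g}"
        lines.append(f"{name}\t{mfe}\t{st.dotbracket}\t{int(is_structured(st))}")
    return "\n".join(lines) + "\n"
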