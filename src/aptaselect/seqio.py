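"""Aptamer sequence model, FASTA I/O and the 2-bit nucleotide encoding.

The aptamers handled here are short single-stranded DNAs built from a
constant 5' flank (``TTTTT``), a variable region (24 nt by default), and a
constant 3' flank (``TTT``).  Only the variable region carries search-space
information, so the genetic-algorithm chromosome is the variable region
encoded two bits per base::

    A -> 00    T -> 01    G -> 10    C -> 11

with the most-significant bit first within each base.  The encoding is
exactly invertible; see :func:`encode_bits` / :func:`decode_bits`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FlankError, ParseError

DEFAULT_FLANK5 = "TTTTT"
DEFAULT_FLANK3 = "TTT"
VARIABLE_LENGTH = 24

_BASE_TO_BITS = {"A": (0, 0), "T": (0, 1), "G": (1, 0), "C": (1, 1)}
_BITS_TO_BASE = {v: k for k, v in _BASE_TO_BITS.items()}


def _check_alphabet(s: str, context: str) -> None:
    bad = set(s) - set("ATGC")
    if bad:
        raise AlphabetError(
            f"{context}: non-ATGC characters {sorted(bad)!r} in {s!r}"
        )


@dataclass(frozen=True)
class AptamerSequence:
    """A named aptamer: constant flanks around a variable region.

    ``full_sequence`` is always the concatenation flank5 + variable_region +
    flank3 (32 nt with the defaults).
    """

    name: str
    variable_region: str
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        _check_alphabet(self.variable_region, f"sequence {self.name!r}")
        _check_alphabet(self.flank5, f"sequence {self.name!r} 5' flank")
        _check_alphabet(self.flank3, f"sequence {self.name!r} 3' flank")

    @property
    def full_sequence(self) -> str:
        return self.flank5 + self.variable_region + self.flank3

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class BitChromosome:
    """Binary chromosome: two bits per variable-region base, MSB first."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("chromosome bits must be 0 or 1")
        if len(self.bits) % 2 != 0:
            raise ValueError(
                f"chromosome length must be even, got {len(self.bits)}"
            )

    def __len__(self) -> int:
        return len(self.bits)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "BitChromosome":
        return cls(tuple(int(c) for c in s))


def encode_bits(seq: AptamerSequence | str) -> BitChromosome:
    """Encode a variable region as a 2-bit-per-base chromosome.

    Accepts either an :class:`AptamerSequence` (its variable region is
    encoded; flanks are constant and carry no information) or a raw base
    string.
    """
    region = seq.variable_region if isinstance(seq, AptamerSequence) else seq
    _check_alphabet(region, "encode_bits")
    bits: list[int] = []
    for base in region:
        bits.extend(_BASE_TO_BITS[base])
    return BitChromosome(tuple(bits))


def decode_bits(
    chromosome: BitChromosome,
    name: str = "decoded",
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
) -> AptamerSequence:
    """Decode a chromosome back to an aptamer; inverse of :func:`encode_bits`."""
    bits = chromosome.bits
    bases = [
        _BITS_TO_BASE[(bits[i], bits[i + 1])] for i in range(0, len(bits), 2)
    ]
    return AptamerSequence(name, "".join(bases), flank5=flank5, flank3=flank3)


def split_flanks(
    name: str,
    full: str,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
    strict: bool = False,
) -> AptamerSequence:
    """Split a full-length sequence into flanks + variable region.

    The split is positional (first ``len(flank5)`` and last ``len(flank3)``
    characters).  With ``strict=True`` the split-off ends must equal the
    configured flank patterns, otherwise :class:`FlankError` is raised.
    """
    if len(full) < len(flank5) + len(flank3) + 1:
        raise ParseError(
            f"record {name!r}: length {len(full)} shorter than flanks"
        )
    head, middle, tail = (
        full[: len(flank5)],
        full[len(flank5) : len(full) - len(flank3)],
        full[len(full) - len(flank3) :],
    )
    if strict and (head != flank5 or tail != flank3):
        raise FlankError(
            f"record {name!r}: flanks {head!r}/{tail!r} do not match "
            f"expected {flank5!r}/{flank3!r}"
        )
    return AptamerSequence(name, middle, flank5=head, flank3=tail)


def parse_fasta(
    text: str,
    strict_flanks: bool = False,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
) -> list[AptamerSequence]:
    """Parse FASTA text into aptamers, splitting off the constant flanks.

    ``U`` is transliterated to ``T`` on input (RNA-style output from external
    folding servers).  In strict mode records whose ends do not match the
    flank patterns raise :class:`FlankError`.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records and text.strip():
        raise ParseError("input is not FASTA (no records parsed)")
    out = []
    for rec in records:
        full = str(rec.seq).upper().replace("U", "T")
        _check_alphabet(full, f"record {rec.id!r}")
        out.append(split_flanks(rec.id, full, flank5, flank3, strict_flanks))
    return out


def write_fasta(seqs: Iterable[AptamerSequence]) -> str:
    """Serialize aptamers to FASTA; round-trips through :func:`parse_fasta`."""
    handle = io.StringIO()
    records = [
        SeqRecord(Seq(s.full_sequence), id=s.name, description="")
        for s in seqs
    ]
    SeqIO.write(records, handle, "fasta-2line")
    return handle.getvalue()


def read_fasta_file(path, **kwargs) -> list[AptamerSequence]:
    with open(path) as fh:
        return parse_fasta(fh.read(), **kwargs)


def write_fasta_file(path, seqs: Sequence[AptamerSequence]) -> None:
    with open(path, "w") as fh:
        fh.write(write_fasta(seqs))
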