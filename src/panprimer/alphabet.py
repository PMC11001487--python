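"""IUPAC nucleotide algebra for degenerate DNA sequences.

A degenerate base is a one-letter IUPAC code denoting a set of possible
nucleotides (R = A/G, N = A/C/G/T, ...). Its *fold* is the size of that set.
The degeneracy of a primer -- the number of distinct oligo species in the
synthesized mix -- is the product of the per-position folds.

DNA only: ``U`` is rejected on input. Gaps are ``-`` (a ``.`` is normalized
to ``-``); input is case-insensitive and normalized to uppercase.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

GAP = "-"

#: IUPAC code -> set of concrete bases it denotes. The gap maps to the
#: empty set and is never counted toward degeneracy.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    GAP: frozenset(),
}

#: base-set -> smallest IUPAC code covering exactly that set.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: elementwise complement of each code's base set, as a code.
COMPLEMENT: dict[str, str] = {
    code: SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


class AlphabetError(ValueError):
    """An input character is not a valid IUPAC DNA code."""


@dataclass(frozen=True)
class IupacBase:
    """One IUPAC nucleotide code with its degeneracy algebra."""

    code: str

    @property
    def base_set(self) -> frozenset[str]:
        return IUPAC_SETS[self.code]

    @property
    def fold(self) -> int:
        return len(self.base_set)

    @property
    def is_gap(self) -> bool:
        return self.code == GAP

    def complement(self) -> "IupacBase":
        return IupacBase(COMPLEMENT[self.code])


def normalize(seq: str, *, allow_gaps: bool = True, context: str = "") -> str:
    """Uppercase *seq*, map ``.`` to ``-``, and validate the alphabet.

    Raises :class:`AlphabetError` naming the offending position (0-based)
    and, when given, the *context* (e.g. a FASTA record id).
    """
    out = []
    for i, ch in enumerate(seq):
        c = ch.upper()
        if c == ".":
            c = GAP
        if c == "U":
            raise AlphabetError(
                f"{context + ': ' if context else ''}uracil 'U' at position {i}: "
                "RNA input is not supported, use DNA (T)"
            )
        if c not in IUPAC_SETS or (c == GAP and not allow_gaps):
            raise AlphabetError(
                f"{context + ': ' if context else ''}invalid character "
                f"{ch!r} at position {i}"
            )
        out.append(c)
    return "".join(out)


def fold(code: str) -> int:
    return len(IUPAC_SETS[code])


def degeneracy(seq: str) -> int:
    """Product of folds over non-gap positions (1 for the empty sequence)."""
    d = 1
    for c in seq:
        if c != GAP:
            d *= len(IUPAC_SETS[c])
    return d


def complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] if c != GAP else GAP for c in seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) sequence.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    seq = normalize(seq)
    return complement(seq)[::-1]


def expand(seq: str, cap: int = 64) -> set[str]:
    """All concrete A/C/G/T sequences a degenerate sequence denotes.

    Gap characters are dropped. Refuses to expand past *cap* species,
    reporting the measured degeneracy.
    """
    seq = normalize(seq)
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(
            f"degeneracy {d} exceeds expansion cap {cap} for sequence {seq!r}"
        )
    pools = [sorted(IUPAC_SETS[c]) for c in seq if c != GAP]
    return {"".join(p) for p in itertools.product(*pools)}


def gap_free(seq: str) -> str:
    return seq.replace(GAP, "")


def expected_gc_fraction(seq: str) -> float:
    """Expected G+C fraction over the degenerate mix (gaps excluded).

    Each position contributes the fraction of its base set that is G or C:
    S -> 1, W -> 0, other 2-folds -> 0.5, 3-folds -> (#GC members)/3,
    N -> 0.5.
    """
    core = gap_free(seq)
    if not core:
        return 0.0
    total = 0.0
    for c in core:
        s = IUPAC_SETS[c]
        total += len(s & frozenset("GC")) / len(s)
    return total / len(core)


class DegenerateSequence:
    """Ordered 5'->3' list of IUPAC bases with degeneracy algebra.

    Thin wrapper over a normalized string; most of the package operates on
    plain strings and uses the module-level functions.
    """

    __slots__ = ("seq",)

    def __init__(self, seq: str, *, context: str = ""):
        self.seq = normalize(seq, context=context)

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq

    def __eq__(self, other) -> bool:
        if isinstance(other, DegenerateSequence):
            return self.seq == other.seq
        return self.seq == other

    def __hash__(self) -> int:
        return hash(self.seq)

    def __add__(self, other: "DegenerateSequence") -> "DegenerateSequence":
        return DegenerateSequence(self.seq + str(other))

    def __repr__(self) -> str:
        return f"DegenerateSequence({self.seq!r})"

    @property
    def bases(self) -> list[IupacBase]:
        return [IupacBase(c) for c in self.seq]

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.seq)

    def reverse_complement(self) -> "DegenerateSequence":
        return DegenerateSequence(reverse_complement(self.seq))

    def expand(self, cap: int = 64) -> set[str]:
        return expand(self.seq, cap=cap)

    def gap_free(self) -> str:
        return gap_free(self.seq)
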