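"""Minimal-degeneracy consensus from an MSA and conserved-region detection.

The alignment is restructured into per-column profiles (what happens at
each base-pair location across all sequences). Each column receives the
single most common base when it clearly dominates, otherwise the smallest
IUPAC code covering every base above a minor-allele threshold; columns that
are mostly gaps become deletion marks. Maximal runs of non-degenerate,
non-gap consensus columns long enough to host a primer are the conserved
regions -- the preferred placement for primers, since a primer inside one
matches every sequence in the alignment exactly.

Coordinates are 0-based, half-open, measured on the forward consensus from
the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import alphabet
from .alphabet import GAP, IUPAC_SETS, SET_TO_CODE
from .io import SequenceCollection

#: deterministic tie-break order for the top base
BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class ColumnProfile:
    """Base counts at one alignment column.

    Degenerate input codes contribute fractionally (1/fold to each member
    base) so that depth is conserved.
    """

    index: int
    counts: dict[str, float]
    depth: int

    @property
    def top_base(self) -> str:
        return max(BASE_ORDER, key=lambda b: (self.counts.get(b, 0.0), -BASE_ORDER.index(b)))

    @property
    def top_ratio(self) -> float:
        return self.counts.get(self.top_base, 0.0) / self.depth

    @property
    def gap_fraction(self) -> float:
        return self.counts.get(GAP, 0.0) / self.depth


@dataclass
class ConsensusSequence:
    """Per-column profiles plus the chosen IUPAC code for each column."""

    columns: list[ColumnProfile]
    codes: list[str]

    def __post_init__(self):
        if len(self.columns) != len(self.codes):
            raise ValueError("codes and columns must have equal length")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def sequence(self) -> str:
        return "".join(self.codes)

    @property
    def degeneracy(self) -> int:
        return alphabet.degeneracy(self.sequence)


@dataclass(frozen=True)
class ConservedRegion:
    """Maximal degeneracy-free, gap-free run of consensus columns
    (0-based, half-open)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def build_profiles(coll: SequenceCollection) -> list[ColumnProfile]:
    """One profile per alignment column; input must be aligned.

    The reverse-strand view is derivable (reverse order, complemented
    counts), so only the forward profiles are materialized.
    """
    if not coll.is_aligned:
        raise ValueError("build_profiles requires an aligned collection")
    length = len(coll.records[0][1])
    profiles = []
    for i in range(length):
        counts: dict[str, float] = {b: 0.0 for b in "ACGT"}
        counts[GAP] = 0.0
        for _, seq in coll.records:
            c = str(seq)[i]
            if c == GAP:
                counts[GAP] += 1.0
            else:
                members = IUPAC_SETS[c]
                for b in members:
                    counts[b] += 1.0 / len(members)
        profiles.append(ColumnProfile(index=i, counts=counts, depth=len(coll.records)))
    return profiles


def smallest_covering_code(bases: set[str]) -> str:
    """The IUPAC code denoting exactly the given base set."""
    return SET_TO_CODE[frozenset(bases)]


def assign_consensus(
    profiles: list[ColumnProfile],
    majority_threshold: float = 0.9,
    minor_threshold: float = 0.1,
    gap_threshold: float = 0.5,
) -> ConsensusSequence:
    """Choose one (possibly degenerate) code per column.

    A column keeps its single top base when its ratio reaches the majority
    threshold and gaps are scarce; a column whose gap frequency reaches the
    gap threshold becomes a deletion mark; otherwise the smallest IUPAC
    code covering every base at or above the minor-allele threshold is
    chosen (the top base always included).
    """
    if not 0.0 < minor_threshold <= majority_threshold <= 1.0:
        raise ValueError("need 0 < minor_threshold <= majority_threshold <= 1")
    codes = []
    for p in profiles:
        if p.gap_fraction >= gap_threshold:
            codes.append(GAP)
            continue
        if p.top_ratio >= majority_threshold:
            codes.append(p.top_base)
            continue
        members = {
            b for b in "ACGT" if p.counts.get(b, 0.0) / p.depth >= minor_threshold
        }
        members.add(p.top_base)
        codes.append(smallest_covering_code(members))
    return ConsensusSequence(columns=list(profiles), codes=codes)


def find_conserved_regions(
    consensus: ConsensusSequence | str, min_len: int = 18
) -> list[ConservedRegion]:
    """Ordered, disjoint, maximal runs of fold-1 non-gap codes with
    length >= min_len."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = consensus if isinstance(consensus, str) else consensus.sequence
    regions = []
    start = None
    for i, c in enumerate(seq + GAP):  # sentinel terminates the last run
        conserved = i < len(seq) and c != GAP and alphabet.fold(c) == 1
        if conserved and start is None:
            start = i
        elif not conserved and start is not None:
            if i - start >= min_len:
                regions.append(ConservedRegion(start, i))
            start = None
    return regions


@dataclass
class FeasibilityResult:
    feasible: bool
    reason: str
    consensus: str = ""

    def __bool__(self) -> bool:
        return self.feasible


def check_amplicon_feasibility(
    regions: list[ConservedRegion],
    min_amplicon: int,
    consensus: ConsensusSequence | str = "",
    min_primer_len: int = 18,
) -> FeasibilityResult:
    """Can some forward and reverse primer window span >= min_amplicon?

    The amplicon runs from the forward primer's 5' start to the reverse
    primer's 5' start (its window end on the forward strand). Feasible iff
    some region pair -- possibly the same region -- offers that span. An
    infeasible result carries the consensus so the caller can display it
    and abort.
    """
    if min_amplicon < 2 * min_primer_len:
        raise ValueError("min_amplicon must be >= twice the primer minimum")
    seq = consensus if isinstance(consensus, str) else (consensus.sequence if consensus else "")
    if not regions:
        return FeasibilityResult(False, "no conserved regions", seq)
    for i, ri in enumerate(regions):
        for rj in regions[i:]:
            span = rj.end - ri.start
            if span >= min_amplicon:
                return FeasibilityResult(
                    True,
                    f"regions [{ri.start},{ri.end}) and [{rj.start},{rj.end}) "
                    f"span {span} bp",
                    seq,
                )
    return FeasibilityResult(
        False,
        f"no region pair spans the minimum amplicon of {min_amplicon} bp",
        seq,
    )


def regions_to_bed(
    regions: list[ConservedRegion], chrom: str = "consensus"
) -> str:
    """Conserved regions as BED (0-based half-open) for inspection."""
    lines = [
        f"{chrom}\t{r.start}\t{r.end}\tconserved_{k + 1}"
        for k, r in enumerate(regions)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
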