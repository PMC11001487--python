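"""Candidate primer enumeration, penalty ranking, pair optimization, and
the primer-search operation.

Candidates are every window of acceptable length inside the scope
(conserved regions, or a user base-pair range in filtration mode), hard
filtered and penalty scored. Pairing walks the forward x reverse cross
product lazily in exact combined-penalty order (a heap merge over the two
penalty-sorted lists), examining the stream one fixed-size block at a time
and greedily accepting pairs that satisfy the amplicon/Tm/annealing
constraints, never reusing a primer sequence, until five optimized pairs
are found or the stream is exhausted.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

from . import alphabet, thermo
from .consensus import ConsensusSequence, ConservedRegion
from .filters import FilterReport, FilterSettings, evaluate_primer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerCandidate:
    """A windowed oligo that survived all hard filters.

    ``start``/``length`` locate the window on the forward consensus
    (0-based from the 5' end); a reverse candidate's ``sequence`` is the
    reverse-complement strand oligo of that window.
    """

    sequence: str
    orientation: str  # "forward" | "reverse"
    start: int
    length: int
    tm_min: float
    tm_mean: float
    tm_max: float
    penalty: float
    report: FilterReport | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class PairingSettings:
    min_amplicon: int = 100
    tm_pair_max_diff: float = 1.0
    annealing_max_diff: float = 5.0
    #: "pairwise": compare the two primers' annealing temperatures;
    #: "product": compare each primer Tm against the product annealing Tm.
    annealing_rule: str = "pairwise"
    block_size: int = 1600
    max_pairs: int = 5


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_len: int
    tm_diff: float
    annealing_tm: float
    combined_penalty: float


def enumerate_candidates(
    consensus: ConsensusSequence | str,
    regions: list[ConservedRegion] | None = None,
    bp_range: tuple[int, int] | None = None,
    tsettings: thermo.ThermoSettings | None = None,
    fsettings: FilterSettings | None = None,
    mode: str = "conserved",
) -> tuple[list[PrimerCandidate], list[PrimerCandidate]]:
    """Generate, filter and score every candidate window.

    ``mode="conserved"`` draws windows from the given conserved regions;
    ``mode="filtration"`` draws them from the whole consensus (or the
    user's half-open ``bp_range``) and relies on the hard filters alone.
    Returns (forward, reverse) lists of surviving candidates; empty lists
    mean "no primer found".
    """
    tsettings = tsettings or thermo.ThermoSettings()
    fsettings = fsettings or FilterSettings()
    seq = consensus if isinstance(consensus, str) else consensus.sequence
    if mode == "conserved":
        if not regions:
            raise ValueError("conserved mode requires a non-empty region list")
        scopes = [(r.start, r.end) for r in regions]
    elif mode == "filtration":
        lo, hi = bp_range or (0, len(seq))
        if not 0 <= lo < hi <= len(seq):
            raise ValueError(f"bp range [{lo},{hi}) invalid for template of {len(seq)}")
        scopes = [(lo, hi)]
    else:
        raise ValueError(f"unknown enumeration mode {mode!r}")

    rejections: dict[str, int] = {}
    forward: list[PrimerCandidate] = []
    reverse: list[PrimerCandidate] = []
    for lo, hi in scopes:
        for length in range(fsettings.min_len, fsettings.max_len + 1):
            for start in range(lo, hi - length + 1):
                window = seq[start : start + length]
                for orientation in ("forward", "reverse"):
                    oligo = (
                        window
                        if orientation == "forward"
                        else alphabet.reverse_complement(window)
                    )
                    report = evaluate_primer(
                        oligo, tsettings, fsettings, mode="design"
                    )
                    if report.failed:
                        for name in report.failed_names:
                            rejections[name] = rejections.get(name, 0) + 1
                        continue
                    stats = thermo.melting_temperature(oligo, tsettings)
                    cand = PrimerCandidate(
                        sequence=alphabet.gap_free(oligo),
                        orientation=orientation,
                        start=start,
                        length=length,
                        tm_min=stats.min,
                        tm_mean=stats.mean,
                        tm_max=stats.max,
                        penalty=report.penalty,
                        report=report,
                    )
                    (forward if orientation == "forward" else reverse).append(cand)
    for name, n in sorted(rejections.items()):
        logger.info("filter %s rejected %d windows", name, n)
    return rank_candidates(forward), rank_candidates(reverse)


def rank_candidates(cands: list[PrimerCandidate]) -> list[PrimerCandidate]:
    """Stable sort: minimum accrued penalty first, then 5' start, then
    length. Rank is the 1-based position in the returned list."""
    return sorted(cands, key=lambda c: (c.penalty, c.start, c.length))


def amplicon_stats(seq: str, fwd: PrimerCandidate, rev: PrimerCandidate) -> tuple[int, float]:
    """(amplicon length, expected GC%) from the forward 5' start to the
    reverse 5' start in forward coordinates."""
    length = rev.end - fwd.start
    gc = 100.0 * alphabet.expected_gc_fraction(seq[fwd.start : rev.end]) if seq else 50.0
    return length, gc


def pair_constraints(
    fwd: PrimerCandidate,
    rev: PrimerCandidate,
    psettings: PairingSettings | None = None,
    tsettings: thermo.ThermoSettings | None = None,
    template: str = "",
) -> tuple[bool, dict]:
    """Check amplicon size, melting-temperature match and annealing
    compatibility for one candidate pair."""
    psettings = psettings or PairingSettings()
    tsettings = tsettings or thermo.ThermoSettings()
    diag: dict = {}
    if rev.start < fwd.end:
        diag["reason"] = "windows overlap or reverse precedes forward"
        return False, diag
    amplicon_len, gc = amplicon_stats(template, fwd, rev)
    product_tm = thermo.product_annealing_tm(
        gc, tsettings.monovalent_ion, amplicon_len
    )
    tm_diff = abs(fwd.tm_mean - rev.tm_mean)
    diag.update(amplicon_len=amplicon_len, tm_diff=tm_diff, annealing_tm=product_tm)
    if amplicon_len < psettings.min_amplicon:
        diag["reason"] = f"amplicon {amplicon_len} < {psettings.min_amplicon}"
        return False, diag
    if tm_diff > psettings.tm_pair_max_diff:
        diag["reason"] = f"pair Tm difference {tm_diff:.2f} C"
        return False, diag
    if psettings.annealing_rule == "product":
        worst = max(
            abs(fwd.tm_mean - product_tm), abs(rev.tm_mean - product_tm)
        )
    else:  # pairwise annealing difference (Rychlik Ta shares the product term)
        ta_f = 0.3 * fwd.tm_mean + 0.7 * product_tm - 14.9
        ta_r = 0.3 * rev.tm_mean + 0.7 * product_tm - 14.9
        worst = abs(ta_f - ta_r)
    diag["annealing_gap"] = worst
    if worst >= psettings.annealing_max_diff:
        diag["reason"] = f"annealing mismatch {worst:.2f} C"
        return False, diag
    return True, diag


def _pair_stream(forward: list[PrimerCandidate], reverse: list[PrimerCandidate]):
    """Yield (i, j) lazily in exact (penalty sum, i, j) order."""
    if not forward or not reverse:
        return
    heap = [(forward[0].penalty + reverse[0].penalty, 0, 0)]
    while heap:
        _, i, j = heapq.heappop(heap)
        yield i, j
        if j + 1 < len(reverse):
            heapq.heappush(
                heap, (forward[i].penalty + reverse[j + 1].penalty, i, j + 1)
            )
        if j == 0 and i + 1 < len(forward):
            heapq.heappush(
                heap, (forward[i + 1].penalty + reverse[0].penalty, i + 1, 0)
            )


def pair_primers(
    forward: list[PrimerCandidate],
    reverse: list[PrimerCandidate],
    psettings: PairingSettings | None = None,
    tsettings: thermo.ThermoSettings | None = None,
    template: str = "",
) -> list[PrimerPair]:
    """Select up to ``max_pairs`` optimized pairs.

    Both lists must already be penalty-sorted. Pairs are examined in
    combined-penalty order, ``block_size`` at a time; an accepted pair may
    not reuse a forward or reverse sequence already accepted, so the output
    contains only unique primers.
    """
    psettings = psettings or PairingSettings()
    tsettings = tsettings or thermo.ThermoSettings()
    pairs: list[PrimerPair] = []
    used_f: set[str] = set()
    used_r: set[str] = set()
    block: list[tuple[int, int]] = []
    blocks_seen = 0

    def process(block_pairs: list[tuple[int, int]]):
        nonlocal blocks_seen
        blocks_seen += 1
        for i, j in block_pairs:
            if len(pairs) >= psettings.max_pairs:
                return
            f, r = forward[i], reverse[j]
            if f.sequence in used_f or r.sequence in used_r:
                continue
            ok, diag = pair_constraints(f, r, psettings, tsettings, template)
            if not ok:
                continue
            pairs.append(
                PrimerPair(
                    forward=f,
                    reverse=r,
                    amplicon_len=diag["amplicon_len"],
                    tm_diff=diag["tm_diff"],
                    annealing_tm=diag["annealing_tm"],
                    combined_penalty=f.penalty + r.penalty,
                )
            )
            used_f.add(f.sequence)
            used_r.add(r.sequence)

    for ij in _pair_stream(forward, reverse):
        block.append(ij)
        if len(block) == psettings.block_size:
            process(block)
            block = []
            if len(pairs) >= psettings.max_pairs:
                break
    if block and len(pairs) < psettings.max_pairs:
        process(block)
    logger.info("examined %d blocks, accepted %d pairs", blocks_seen, len(pairs))
    return pairs


@dataclass(frozen=True)
class SearchResult:
    query: str
    found: bool
    rank: int | None = None
    orientation: str = "forward"
    report: FilterReport | None = None


def search_primer(
    query: str,
    forward: list[PrimerCandidate],
    reverse: list[PrimerCandidate],
    orientation: str = "forward",
    tsettings: thermo.ThermoSettings | None = None,
    fsettings: FilterSettings | None = None,
) -> SearchResult:
    """Scan the requested candidate list for an exact (case-insensitive)
    sequence match; on a miss, pipeline the query into the testing module
    so the user sees why it failed. No alignment against the template is
    attempted."""
    q = alphabet.normalize(query)
    cands = forward if orientation == "forward" else reverse
    for rank, c in enumerate(cands, start=1):
        if c.sequence == q:
            return SearchResult(q, True, rank, orientation)
    report = evaluate_primer(q, tsettings, fsettings, mode="test")
    return SearchResult(q, False, None, orientation, report)
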