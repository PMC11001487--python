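"""End-to-end orchestration: input -> alignment -> consensus -> candidate
enumeration -> pair optimization -> report.

Two major paths select primers: the conserved-region approach (default for
alignments) and the filtration approach (single sequences, or on request),
mirroring the two branches of the design flowgram. A run that finds no
feasible amplicon is a *user outcome*, not an error: the consensus is
reported with a notice and the exit status stays zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import consensus as cns
from . import io, pairing
from .config import RunConfig
from .filters import FilterReport, evaluate_primer
from .io import AlignRunner, SequenceCollection

logger = logging.getLogger(__name__)


@dataclass
class DesignResult:
    config: RunConfig
    consensus: cns.ConsensusSequence | None = None
    regions: list[cns.ConservedRegion] = field(default_factory=list)
    forward: list[pairing.PrimerCandidate] = field(default_factory=list)
    reverse: list[pairing.PrimerCandidate] = field(default_factory=list)
    pairs: list[pairing.PrimerPair] = field(default_factory=list)
    notice: str = ""
    mode_used: str = ""

    @property
    def report_text(self) -> str:
        return io.format_report(
            settings=self.config.summary(),
            consensus_seq=self.consensus.sequence if self.consensus else "",
            regions=self.regions,
            forward=self.forward,
            reverse=self.reverse,
            pairs=self.pairs,
            notice=self.notice,
        )


def run_design(
    config: RunConfig,
    coll: SequenceCollection | None = None,
    align_runner: AlignRunner | None = None,
) -> DesignResult:
    """Execute a full design run.

    ``coll`` may be supplied directly (tests, library use); otherwise
    ``config.input_path`` is read. Raises on genuine errors (bad input,
    missing aligner); an infeasible design returns a result whose
    ``notice`` explains and whose consensus is still populated.
    """
    if coll is None:
        coll = io.read_input(config.input_path, aligned=config.aligned)
    coll = io.align_if_needed(coll, config.align_mode, runner=align_runner)

    result = DesignResult(config=config)
    profiles = (
        cns.build_profiles(coll)
        if coll.is_aligned or coll.is_single
        else None
    )
    if profiles is None:  # unreachable: align_if_needed aligns or raises
        raise RuntimeError("collection left unaligned")
    result.consensus = cns.assign_consensus(
        profiles,
        config.majority_threshold,
        config.minor_threshold,
        config.gap_threshold,
    )

    mode = config.design_mode
    if mode == "auto":
        mode = "filtration" if coll.is_single else "conserved"
    result.mode_used = mode

    bp_range = None
    if config.range_begin is not None or config.range_end is not None:
        bp_range = (
            config.range_begin or 0,
            config.range_end or len(result.consensus),
        )

    if mode == "conserved":
        result.regions = cns.find_conserved_regions(
            result.consensus, min_len=config.min_len
        )
        feas = cns.check_amplicon_feasibility(
            result.regions,
            config.min_amplicon,
            result.consensus,
            min_primer_len=config.min_len,
        )
        if not feas:
            result.notice = (
                f"design infeasible: {feas.reason}; consensus shown above"
            )
            return result
        result.forward, result.reverse = pairing.enumerate_candidates(
            result.consensus,
            regions=result.regions,
            tsettings=config.thermo,
            fsettings=config.filters,
            mode="conserved",
        )
    else:
        result.forward, result.reverse = pairing.enumerate_candidates(
            result.consensus,
            bp_range=bp_range,
            tsettings=config.thermo,
            fsettings=config.filters,
            mode="filtration",
        )

    if not result.forward or not result.reverse:
        result.notice = io.NO_PRIMER_NOTICE
        return result

    result.pairs = pairing.pair_primers(
        result.forward,
        result.reverse,
        psettings=config.pairing,
        tsettings=config.thermo,
        template=result.consensus.sequence,
    )
    if not result.pairs:
        result.notice = io.NO_PRIMER_NOTICE
    return result


def run_test_mode(
    primers: list[str], config: RunConfig | None = None
) -> list[tuple[str, FilterReport | None, str]]:
    """Evaluate user-supplied primers against every filter.

    Returns (primer, report-or-None, error message) triples; an invalid
    primer yields a per-primer error entry instead of aborting the batch.
    """
    config = config or RunConfig()
    out = []
    for p in primers:
        try:
            report = evaluate_primer(
                p, config.thermo, config.filters, mode="test"
            )
            out.append((p, report, ""))
        except ValueError as exc:
            out.append((p, None, str(exc)))
    return out


def run_search(
    queries: list[str],
    config: RunConfig,
    orientation: str = "forward",
    coll: SequenceCollection | None = None,
    align_runner: AlignRunner | None = None,
) -> tuple[DesignResult, list[pairing.SearchResult]]:
    """Build the candidate lists for the input, then search them for each
    query primer."""
    design = run_design(config, coll=coll, align_runner=align_runner)
    results = [
        pairing.search_primer(
            q,
            design.forward,
            design.reverse,
            orientation=orientation,
            tsettings=config.thermo,
            fsettings=config.filters,
        )
        for q in queries
    ]
    return design, results
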