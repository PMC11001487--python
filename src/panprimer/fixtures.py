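"""Synthetic MSA generator with planted conserved blocks.

Manufactures alignments whose conserved regions are known by construction,
so the whole pipeline is testable without any external data: columns
inside the planted blocks are identical across sequences; every other
column is mutated per sequence at a divergence rate and gapped at a gap
rate. Deterministic under a seed.
"""

from __future__ import annotations

import numpy as np

from .alphabet import GAP, DegenerateSequence
from .io import SequenceCollection

_BASES = np.array(list("ACGT"))


def generate_fixture_msa(
    n_seqs: int = 8,
    length: int = 400,
    conserved_blocks: list[tuple[int, int]] = (),
    divergence_rate: float = 0.5,
    gap_rate: float = 0.05,
    seed: int = 0,
) -> SequenceCollection:
    """Build an aligned collection with planted conserved blocks.

    conserved_blocks : disjoint (start, length) intervals within
        [0, length) whose columns are identical in every sequence.
    divergence_rate : per-sequence, per-column probability that a column
        outside every block carries a substitution (always to a different
        base, so the column is guaranteed polymorphic when it fires).
    gap_rate : per-sequence, per-column probability of a deletion outside
        the blocks (applied after substitution draws).
    """
    blocks = sorted((int(s), int(l)) for s, l in conserved_blocks)
    for (s0, l0), (s1, _) in zip(blocks, blocks[1:]):
        if s0 + l0 > s1:
            raise ValueError(f"overlapping conserved blocks at {s0} and {s1}")
    if blocks and (blocks[0][0] < 0 or blocks[-1][0] + blocks[-1][1] > length):
        raise ValueError("conserved blocks must lie within [0, length)")

    rng = np.random.default_rng(seed)
    template = rng.integers(0, 4, size=length)
    in_block = np.zeros(length, dtype=bool)
    for s, l in blocks:
        in_block[s : s + l] = True

    records = []
    for k in range(n_seqs):
        bases = template.copy()
        mutate = (~in_block) & (rng.random(length) < divergence_rate)
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=length)
        bases[mutate] = (bases[mutate] + shift[mutate]) % 4
        chars = _BASES[bases].copy()
        gaps = (~in_block) & (rng.random(length) < gap_rate)
        chars[gaps] = GAP
        records.append((f"seq{k + 1}", DegenerateSequence("".join(chars))))
    return SequenceCollection(records=records, is_aligned=True)
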