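"""Published benchmark primer panels used as regression fixtures.

Three panels of primers produced by other design tools for nitrogenase
genes (anfD/anfK, nifD/nifK, vnfD/vnfK) and the T4-like phage major capsid
gene (g23), used here as fixed inputs for the primer-testing mode:

* ``PRIMERDESIGN_M_ANFD`` -- five degenerate forward/reverse pairs a
  web-based designer proposed for the iron nitrogenase (anfD) target.
* ``CONSENSUSPRIMER_PANEL`` -- thirty primers a consensus+Primer3 pipeline
  proposed for anfD, nifK and vnfD (ten per gene, pairs flattened in
  printed order; all ten vnfD reverse entries are the same 17-mer).
* ``DEGEPRIME_SPOT_CHECKS`` -- individual primers from a degenerate-window
  enumerator, used to spot-check specific filter labels.

These strings are inputs (printed panels), not outputs of this package.
"""

from __future__ import annotations

#: (sequence, orientation) -- five pairs, the same degenerate forward five
#: times with successively trimmed reverses.
PRIMERDESIGN_M_ANFD: list[tuple[str, str]] = [
    ("WGCACGCCGTGRTSAAGGGC", "forward"),
    ("TGCCAGGTGTCGTAGGTGCAGCCS", "reverse"),
    ("WGCACGCCGTGRTSAAGGGC", "forward"),
    ("GCCAGGTGTCGTAGGTGCAGCCS", "reverse"),
    ("WGCACGCCGTGRTSAAGGGC", "forward"),
    ("CCAGGTGTCGTAGGTGCAGCCS", "reverse"),
    ("WGCACGCCGTGRTSAAGGGC", "forward"),
    ("CAGGTGTCGTAGGTGCAGCCS", "reverse"),
    ("WGCACGCCGTGRTSAAGGGC", "forward"),
    ("AGGTGTCGTAGGTGCAGCCS", "reverse"),
]

#: (gene, sequence) in printed order; ten primers per gene.
CONSENSUSPRIMER_PANEL: list[tuple[str, str]] = [
    ("anfD", "CTTCCAGCTGAAGTACACC"),
    ("anfD", "CACCACAAGATCAACATCG"),
    ("anfD", "TTCCAGCTGAAGTACACC"),
    ("anfD", "CACCACAAGATCAACATCG"),
    ("anfD", "CTTCCAGCTGAAGTACACC"),
    ("anfD", "CCACCACAAGATCAACATC"),
    ("anfD", "TTCCAGCTGAAGTACACC"),
    ("anfD", "CCACCACAAGATCAACATC"),
    ("anfD", "TTCCAGCTGAAGTACACCT"),
    ("anfD", "CACCACAAGATCAACATCG"),
    ("nifK", "TGAAGACCAGCATCAAGAA"),
    ("nifK", "AACAACAAGGTGAACCTGAT"),
    ("nifK", "TGAAGACCAGCATCAAGAA"),
    ("nifK", "ACAACAAGGTGAACCTGAT"),
    ("nifK", "TGAAGACCAGCATCAAGAA"),
    ("nifK", "CTTCAGCAACATGGTGAAG"),
    ("nifK", "GAAGACCAGCATCAAGAAC"),
    ("nifK", "AACAACAAGGTGAACCTGAT"),
    ("nifK", "CTGAAGACCAGCATCAAGAA"),
    ("nifK", "AACAACAAGGTGAACCTGAT"),
    ("vnfD", "GGACTTCGAGAAGGTGATC"),
    ("vnfD", "GTACATGGGCTTCGAGG"),
    ("vnfD", "AGGACTTCGAGAAGGTGAT"),
    ("vnfD", "GTACATGGGCTTCGAGG"),
    ("vnfD", "GAGGACTTCGAGAAGGTG"),
    ("vnfD", "GTACATGGGCTTCGAGG"),
    ("vnfD", "GACTTCGAGAAGGTGATCG"),
    ("vnfD", "GTACATGGGCTTCGAGG"),
    ("vnfD", "AACGAGCTGGAGTTCTTC"),
    ("vnfD", "GTACATGGGCTTCGAGG"),
]

#: the five vnfD forward primers (odd printed rows of the vnfD block).
VNFD_FORWARD_PRIMERS = [
    "GGACTTCGAGAAGGTGATC",
    "AGGACTTCGAGAAGGTGAT",
    "GAGGACTTCGAGAAGGTG",
    "GACTTCGAGAAGGTGATCG",
    "AACGAGCTGGAGTTCTTC",
]

#: the 17-mer every vnfD reverse slot repeats.
VNFD_REVERSE_17MER = "GTACATGGGCTTCGAGG"

#: primer -> filter label expected to appear among its failures.
DEGEPRIME_SPOT_CHECKS: dict[str, str] = {
    "GTGCAGCGAGTGCATCCCGG": "GC content",   # 70% GC
    "GCGAGTGCATCCCGGAGCGC": "Comp. ends",   # GCG... ...CGC
    "CTTCAGCAACATGGTGAAG": "Comp. ends",    # CTT... ...AAG
}
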