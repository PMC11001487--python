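"""Nearest-neighbor DNA thermodynamics: duplex free energy and melting
temperature, plus the GC/length formula for PCR-product annealing
temperature.

Model
-----
Duplex formation enthalpy and entropy are sums over adjacent dinucleotide
"stacks" plus initiation terms for each terminal base (one term for a
terminal G/C, another for a terminal A/T) and, for self-complementary
oligos, a symmetry entropy correction:

    dG_total = sum_i n_i dG_i + dG_init(term G/C) + dG_init(term A/T) + dG_sym

The two-state melting temperature of a non-self-complementary oligo at
total strand concentration ``CT`` is

    Tm [K] = 1000 * dH / (dS + R * ln(CT / b))

with ``b = 4`` (1 for self-complementary duplexes), followed by conversion
to Celsius and the monovalent-salt correction ``+16.6 * log10([Na+])``.
The shipped parameter table is the unified oligonucleotide set referenced
to 1 M NaCl; it lives in ``data/nn_unified.tsv`` and can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

from . import alphabet

#: gas constant, cal/(mol*K)
GAS_CONSTANT = 1.987

#: reference temperature for dG, Kelvin (37 C)
REFERENCE_T = 310.15

KELVIN = 273.15


@dataclass(frozen=True)
class NNParameterTable:
    """Per-dinucleotide dH/dS stacks plus initiation and symmetry terms.

    ``stacks`` maps all 16 dinucleotides; reverse-complement pairs carry
    identical parameters. dH in kcal/mol, dS in cal/(mol*K).
    """

    stacks: dict[str, tuple[float, float]]
    init_gc: tuple[float, float]
    init_at: tuple[float, float]
    sym: tuple[float, float]
    reference_temperature: float = REFERENCE_T
    version: str = "1"

    def stack_dg(self, dinuc: str, temperature: float = REFERENCE_T) -> float:
        dh, ds = self.stacks[dinuc]
        return dh - temperature * ds / 1000.0


def load_nn_table(name: str = "nn_unified.tsv") -> NNParameterTable:
    """Load a parameter table shipped under ``panprimer/data``."""
    stacks: dict[str, tuple[float, float]] = {}
    init_gc = init_at = sym = (0.0, 0.0)
    version = "?"
    text = resources.files("panprimer").joinpath(f"data/{name}").read_text()
    for line in text.splitlines():
        if line.startswith("#"):
            if "version" in line:
                version = line.rstrip().rsplit(None, 1)[-1]
            continue
        if not line.strip():
            continue
        term, dh, ds = line.split("\t")
        entry = (float(dh), float(ds))
        if term == "init_GC":
            init_gc = entry
        elif term == "init_AT":
            init_at = entry
        elif term == "sym":
            sym = entry
        else:
            stacks[term] = entry
    missing = {a + b for a in "ACGT" for b in "ACGT"} - stacks.keys()
    if missing:
        raise ValueError(f"NN table {name} missing stacks: {sorted(missing)}")
    return NNParameterTable(stacks, init_gc, init_at, sym, version=version)


_DEFAULT_TABLE: NNParameterTable | None = None


def default_table() -> NNParameterTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_nn_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class ThermoSettings:
    """Global thermodynamic run parameters.

    monovalent_ion : molar Na+/K+ concentration (default 50 mM)
    primer_conc    : total primer strand concentration CT (default 50 nM)
    tm_min, tm_max : acceptable primer melting range, Celsius
    symmetry_divisor : ``b`` for non-self-complementary duplexes
    """

    monovalent_ion: float = 0.05
    primer_conc: float = 50e-9
    tm_min: float = 50.0
    tm_max: float = 65.0
    symmetry_divisor: float = 4.0
    gas_constant: float = GAS_CONSTANT
    expansion_cap: int = 64


def is_self_complementary(seq: str) -> bool:
    return seq == alphabet.reverse_complement(seq)


def enthalpy_entropy(
    seq: str, table: NNParameterTable | None = None
) -> tuple[float, float]:
    """Total (dH kcal/mol, dS cal/mol/K) for a concrete duplex, including
    initiation and (when self-complementary) symmetry terms."""
    table = table or default_table()
    if len(seq) < 2:
        raise ValueError("need at least 2 bases for a nearest-neighbor stack")
    bad = [c for c in seq if c not in "ACGT"]
    if bad:
        raise ValueError(
            f"degenerate or gap characters {bad} in {seq!r}: expand first"
        )
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        sh, ss = table.stacks[seq[i : i + 2]]
        dh += sh
        ds += ss
    for end in (seq[0], seq[-1]):
        ih, is_ = table.init_gc if end in "GC" else table.init_at
        dh += ih
        ds += is_
    if is_self_complementary(seq):
        dh += table.sym[0]
        ds += table.sym[1]
    return dh, ds


def delta_g(
    seq: str,
    table: NNParameterTable | None = None,
    temperature: float = REFERENCE_T,
) -> float:
    """Duplex formation free energy (kcal/mol) at *temperature* (K)."""
    dh, ds = enthalpy_entropy(seq, table)
    return dh - temperature * ds / 1000.0


def tm_concrete(
    seq: str,
    settings: ThermoSettings | None = None,
    table: NNParameterTable | None = None,
) -> float:
    """Melting temperature (Celsius) of one concrete oligo."""
    settings = settings or ThermoSettings()
    dh, ds = enthalpy_entropy(seq, table)
    b = 1.0 if is_self_complementary(seq) else settings.symmetry_divisor
    conc_term = settings.gas_constant * math.log(settings.primer_conc / b)
    tm_kelvin = dh * 1000.0 / (ds + conc_term)
    return tm_kelvin - KELVIN + 16.6 * math.log10(settings.monovalent_ion)


class TmStats(NamedTuple):
    """min/mean/max melting temperature over the concrete expansions of a
    degenerate primer (all three equal when degeneracy is 1)."""

    min: float
    mean: float
    max: float


def melting_temperature(
    seq: str,
    settings: ThermoSettings | None = None,
    table: NNParameterTable | None = None,
) -> TmStats:
    """Aggregate Tm over all concrete expansions of a degenerate primer.

    Hard filtering uses min/max (every species must sit inside the
    acceptable range); ranking and pair matching use the mean.
    """
    settings = settings or ThermoSettings()
    core = alphabet.gap_free(alphabet.normalize(seq))
    if len(core) < 8:
        raise ValueError(f"primer too short for Tm estimation: {len(core)} bp")
    tms = sorted(
        tm_concrete(s, settings, table)
        for s in alphabet.expand(core, cap=settings.expansion_cap)
    )
    return TmStats(tms[0], sum(tms) / len(tms), tms[-1])


def product_annealing_tm(
    gc_percent: float, monovalent: float, product_len: int
) -> float:
    """Annealing temperature (Celsius) of a PCR product from its GC% and
    length: ``81.5 + 0.41*%GC + 16.6*log10([K+]) - 675/len``."""
    if not 0.0 <= gc_percent <= 100.0:
        raise ValueError("gc_percent must be within [0, 100]")
    if product_len < 1:
        raise ValueError("product_len must be >= 1")
    return (
        81.5
        + 0.41 * gc_percent
        + 16.6 * math.log10(monovalent)
        - 675.0 / product_len
    )
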