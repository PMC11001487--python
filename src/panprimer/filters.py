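"""Hard quality filters and penalty scoring for candidate primers.

Hard filters (any failure disqualifies a primer):

* ``Degeneracy`` -- no degenerate code in the terminal trimers, no N,
  at most one 3-fold and two 2-fold codes.
* ``Deletions``  -- no deletion mark in the terminal trimers, at most three
  consecutive and six total, and the gap-free length must stay above the
  size minimum.
* ``GC content`` -- expected GC fraction within 40-60%.
* ``Repeats``    -- tandem k-mer duplications (k = 2, 3, 4): any
  dinucleotide repeated in place more than twice beyond its first copy,
  any trinucleotide more than once, or any tetranucleotide at all,
  disqualifies.
* ``Comp. ends`` -- the 5' terminal trimer must not be the reverse
  complement of the 3' terminal trimer (self-complementary primer ends
  promote dimer formation).
* ``Size``       -- gap-free length within [min_len, max_len].
* ``Temp``       -- every concrete expansion's Tm inside [tm_min, tm_max]
  (hard in test mode; converted to a penalty in design mode).

Penalty rules (never disqualify, only rank primers lower): triloop and
tetraloop hairpin motifs, a too-stable 3' terminal 5-mer (dG < -3
kcal/mol), a 3' GC clamp heavier than 3 G/C in the last five bases, and --
in design mode -- degrees Celsius outside the melting range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import alphabet, thermo
from .alphabet import GAP, IUPAC_SETS

#: canonical filter-name vocabulary used in test-mode reports
HARD_FILTERS = (
    "Degeneracy",
    "Deletions",
    "GC content",
    "Repeats",
    "Comp. ends",
    "Size",
    "Temp",
)

_GC = frozenset("GC")


@dataclass(frozen=True)
class FilterSettings:
    """Tunable filter thresholds and penalty weights."""

    min_len: int = 18
    max_len: int = 30
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_two_fold: int = 2
    max_three_fold: int = 1
    max_consecutive_deletions: int = 3
    max_total_deletions: int = 6
    # tandem k-mer duplication allowances: extra in-place copies permitted
    max_tandem_repeats: dict[int, int] = field(
        default_factory=lambda: {2: 2, 3: 1, 4: 0}
    )
    clamp_window: int = 5
    clamp_max_gc: int = 3
    dimer_dg_threshold: float = -3.0
    hairpin_weight: float = 1.0
    dimer_weight: float = 1.0
    clamp_weight: float = 1.0
    tm_weight_per_degree: float = 1.0


@dataclass(frozen=True)
class FilterOutcome:
    passed: bool
    detail: str = ""


@dataclass
class FilterReport:
    """Aggregated hard-filter outcomes and accrued penalty for one primer."""

    primer: str
    outcomes: dict[str, FilterOutcome]
    penalty: float = 0.0
    penalty_components: dict[str, float] = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return any(not o.passed for o in self.outcomes.values())

    @property
    def failed_names(self) -> list[str]:
        return [n for n, o in self.outcomes.items() if not o.passed]

    def summary(self) -> str:
        verdict = "FAIL" if self.failed else "pass"
        names = ", ".join(self.failed_names) or "-"
        return f"{self.primer}\t{verdict}\t{names}\tpenalty={self.penalty:.2f}"


# ---------------------------------------------------------------- hard filters


def filter_degeneracy(primer: str, settings: FilterSettings | None = None) -> FilterOutcome:
    settings = settings or FilterSettings()
    core = alphabet.gap_free(primer)
    ends = core[:3] + core[-3:]
    if any(alphabet.fold(c) > 1 for c in ends):
        return FilterOutcome(False, "degenerate code within a terminal trimer")
    if "N" in core:
        return FilterOutcome(False, "contains N (4-fold degenerate)")
    three = sum(1 for c in core if alphabet.fold(c) == 3)
    two = sum(1 for c in core if alphabet.fold(c) == 2)
    if three > settings.max_three_fold:
        return FilterOutcome(False, f"{three} three-fold degenerate bases")
    if two > settings.max_two_fold:
        return FilterOutcome(False, f"{two} two-fold degenerate bases")
    return FilterOutcome(True)


def filter_deletions(primer: str, settings: FilterSettings | None = None) -> FilterOutcome:
    settings = settings or FilterSettings()
    if GAP not in primer:
        return FilterOutcome(True)
    if GAP in primer[:3] or GAP in primer[-3:]:
        return FilterOutcome(False, "deletion within a terminal trimer")
    run = max_run = 0
    for c in primer:
        run = run + 1 if c == GAP else 0
        max_run = max(max_run, run)
    if max_run > settings.max_consecutive_deletions:
        return FilterOutcome(False, f"{max_run} consecutive deletions")
    total = primer.count(GAP)
    if total > settings.max_total_deletions:
        return FilterOutcome(False, f"{total} total deletions")
    if len(primer) - total < settings.min_len:
        return FilterOutcome(
            False,
            f"gap-free length {len(primer) - total} below minimum {settings.min_len}",
        )
    return FilterOutcome(True)


def filter_gc(primer: str, settings: FilterSettings | None = None) -> FilterOutcome:
    settings = settings or FilterSettings()
    frac = alphabet.expected_gc_fraction(primer)
    if not settings.gc_min <= frac <= settings.gc_max:
        return FilterOutcome(False, f"GC {100 * frac:.1f}% outside "
                             f"[{100 * settings.gc_min:.0f}, {100 * settings.gc_max:.0f}]%")
    return FilterOutcome(True)


def tandem_repeat_extras(seq: str, k: int) -> int:
    """Maximal number of in-place extra copies of any k-mer.

    ``ATATAT`` has the 2-mer AT in three consecutive copies, i.e. two extra
    copies beyond the first. Overlapping frames are all scanned.
    """
    best = 0
    n = len(seq)
    for i in range(n - 2 * k + 1):
        copies = 1
        j = i
        while j + 2 * k <= n and seq[j : j + k] == seq[j + k : j + 2 * k]:
            copies += 1
            j += k
        best = max(best, copies - 1)
    return best


def filter_repeats(primer: str, settings: FilterSettings | None = None) -> FilterOutcome:
    settings = settings or FilterSettings()
    core = alphabet.gap_free(primer)
    try:
        expansions = alphabet.expand(core)
    except ValueError:
        expansions = [core]  # over the cap: score the code string literally
    for k, allowed in sorted(settings.max_tandem_repeats.items()):
        worst = max(tandem_repeat_extras(s, k) for s in expansions)
        if worst > allowed:
            return FilterOutcome(
                False, f"{k}-mer repeated {worst}x in tandem (allowed {allowed})"
            )
    return FilterOutcome(True)


def filter_complementary_ends(primer: str, settings: FilterSettings | None = None) -> FilterOutcome:
    core = alphabet.gap_free(primer)
    if len(core) < 6:
        return FilterOutcome(True, "too short to evaluate")
    head = alphabet.expand(core[:3], cap=64)
    tail_rc = {alphabet.reverse_complement(s) for s in alphabet.expand(core[-3:], cap=64)}
    if head & tail_rc:
        return FilterOutcome(
            False, f"5' trimer {core[:3]} complementary to 3' trimer {core[-3:]}"
        )
    return FilterOutcome(True)


def filter_size(primer: str, settings: FilterSettings | None = None) -> FilterOutcome:
    settings = settings or FilterSettings()
    n = len(alphabet.gap_free(primer))
    if n < settings.min_len:
        return FilterOutcome(False, f"{n} bp below minimum {settings.min_len}")
    if n > settings.max_len:
        return FilterOutcome(False, f"{n} bp above maximum {settings.max_len}")
    return FilterOutcome(True)


def filter_tm_range(
    primer: str,
    settings: thermo.ThermoSettings | None = None,
    table: thermo.NNParameterTable | None = None,
) -> FilterOutcome:
    settings = settings or thermo.ThermoSettings()
    core = alphabet.gap_free(primer)
    if len(core) < 8 or alphabet.degeneracy(core) > settings.expansion_cap:
        return FilterOutcome(True, "Tm not evaluated")
    stats = thermo.melting_temperature(core, settings, table)
    if stats.min < settings.tm_min or stats.max > settings.tm_max:
        return FilterOutcome(
            False,
            f"Tm {stats.min:.1f}-{stats.max:.1f} C outside "
            f"[{settings.tm_min:.0f}, {settings.tm_max:.0f}] C",
        )
    return FilterOutcome(True, f"Tm {stats.min:.1f}-{stats.max:.1f} C")


# ------------------------------------------------------------- penalty rules


def _sets(seq: str) -> list[frozenset[str]]:
    return [IUPAC_SETS[c] for c in seq]


def _complement_set(s: frozenset[str]) -> frozenset[str]:
    return frozenset({"A": "T", "T": "A", "C": "G", "G": "C"}[b] for b in s)


def hairpin_penalty(primer: str, settings: FilterSettings | None = None) -> float:
    """One penalty unit per window matching a hairpin-prone motif.

    Triloop: 5-bp window whose first and last bases are complementary with
    G at the second and A at the second-to-last position. Tetraloop: the
    same geometry on a 6-bp window. For degenerate primers a window counts
    when any expansion matches.
    """
    settings = settings or FilterSettings()
    core = alphabet.gap_free(primer)
    sets = _sets(core)
    hits = 0
    for i in range(len(core) - 4):
        w = sets[i : i + 5]
        if (_complement_set(w[0]) & w[4]) and "G" in w[1] and "A" in w[3]:
            hits += 1
    for i in range(len(core) - 5):
        w = sets[i : i + 6]
        if (_complement_set(w[0]) & w[5]) and "G" in w[1] and "A" in w[4]:
            hits += 1
    return hits * settings.hairpin_weight


def end_dimer_penalty(
    primer: str,
    settings: FilterSettings | None = None,
    table: thermo.NNParameterTable | None = None,
) -> float:
    """Penalty for a too-stable 3' terminal 5-mer.

    The Gibbs free energy of the last five bases is measured (worst case
    over expansions); a duplex more stable than the threshold (default -3
    kcal/mol, strict) promotes primer dimers and is penalized.
    """
    settings = settings or FilterSettings()
    core = alphabet.gap_free(primer)
    if len(core) < 5:
        return 0.0
    worst = min(
        thermo.delta_g(s, table) for s in alphabet.expand(core[-5:], cap=1024)
    )
    return settings.dimer_weight if worst < settings.dimer_dg_threshold else 0.0


def gc_clamp_penalty(primer: str, settings: FilterSettings | None = None) -> float:
    """Penalty for more than ``clamp_max_gc`` possible G/C bases among the
    3'-terminal ``clamp_window`` bases (worst case over expansions)."""
    settings = settings or FilterSettings()
    core = alphabet.gap_free(primer)
    window = core[-settings.clamp_window:]
    worst = sum(1 for c in window if IUPAC_SETS[c] & _GC)
    return settings.clamp_weight if worst > settings.clamp_max_gc else 0.0


def tm_range_penalty(
    primer: str,
    tsettings: thermo.ThermoSettings | None = None,
    fsettings: FilterSettings | None = None,
    table: thermo.NNParameterTable | None = None,
) -> float:
    """Design-mode penalty: degrees Celsius the mean Tm sits outside the
    acceptable melting range."""
    tsettings = tsettings or thermo.ThermoSettings()
    fsettings = fsettings or FilterSettings()
    core = alphabet.gap_free(primer)
    if len(core) < 8 or alphabet.degeneracy(core) > tsettings.expansion_cap:
        return 0.0
    mean = thermo.melting_temperature(core, tsettings, table).mean
    excess = max(0.0, tsettings.tm_min - mean, mean - tsettings.tm_max)
    return excess * fsettings.tm_weight_per_degree


# ------------------------------------------------------------------ evaluate


def evaluate_primer(
    primer: str,
    tsettings: thermo.ThermoSettings | None = None,
    fsettings: FilterSettings | None = None,
    *,
    mode: str = "test",
    table: thermo.NNParameterTable | None = None,
) -> FilterReport:
    """Run every hard filter and scoring rule on one primer.

    ``mode="test"`` treats an out-of-range melting temperature as a hard
    ``Temp`` failure (the behavior of the standalone primer-testing mode);
    ``mode="design"`` converts it into a penalty so that candidate ranking
    can still order near-miss primers.
    """
    if mode not in ("test", "design"):
        raise ValueError(f"unknown mode {mode!r}")
    tsettings = tsettings or thermo.ThermoSettings()
    fsettings = fsettings or FilterSettings()
    if not primer:
        raise alphabet.AlphabetError("empty primer")
    primer = alphabet.normalize(primer)
    if not alphabet.gap_free(primer):
        raise alphabet.AlphabetError("primer contains only gaps")

    outcomes = {
        "Degeneracy": filter_degeneracy(primer, fsettings),
        "Deletions": filter_deletions(primer, fsettings),
        "GC content": filter_gc(primer, fsettings),
        "Repeats": filter_repeats(primer, fsettings),
        "Comp. ends": filter_complementary_ends(primer, fsettings),
        "Size": filter_size(primer, fsettings),
    }
    if mode == "test":
        outcomes["Temp"] = filter_tm_range(primer, tsettings, table)

    components = {
        "hairpin": hairpin_penalty(primer, fsettings),
        "end_dimer": end_dimer_penalty(primer, fsettings, table),
        "gc_clamp": gc_clamp_penalty(primer, fsettings),
    }
    if mode == "design":
        components["tm_range"] = tm_range_penalty(primer, tsettings, fsettings, table)

    return FilterReport(
        primer=primer,
        outcomes=outcomes,
        penalty=sum(components.values()),
        penalty_components=components,
    )
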