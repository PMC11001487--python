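"""Run configuration: explicit settings object plus a flat key/value
config-file loader. Precedence is CLI flags > config file > defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .filters import FilterSettings
from .pairing import PairingSettings
from .thermo import ThermoSettings


@dataclass
class RunConfig:
    """Everything a design run needs, with the package defaults.

    Numeric defaults: melting range 50-65 C, 50 mM monovalent ion, 50 nM
    primer, primer length 18-30 bp, minimum amplicon 100 bp, pair block
    size 1600, at most five pairs.
    """

    input_path: str = ""
    output_path: str = ""
    aligned: bool | None = None  # None = infer
    align_mode: str = "global"  # global | local
    design_mode: str = "auto"  # auto | conserved | filtration
    range_begin: int | None = None
    range_end: int | None = None
    tm_min: float = 50.0
    tm_max: float = 65.0
    monovalent: float = 0.05
    primer_conc: float = 50e-9
    min_len: int = 18
    max_len: int = 30
    min_amplicon: int = 100
    block_size: int = 1600
    max_pairs: int = 5
    majority_threshold: float = 0.9
    minor_threshold: float = 0.1
    gap_threshold: float = 0.5
    annealing_rule: str = "pairwise"
    seed: int = 0

    def __post_init__(self):
        for name in ("tm_min", "tm_max", "monovalent", "primer_conc",
                     "min_len", "max_len", "min_amplicon", "block_size",
                     "max_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.range_begin is not None and self.range_end is not None:
            if not 0 <= self.range_begin < self.range_end:
                raise ValueError("range must be a valid half-open interval")

    @property
    def thermo(self) -> ThermoSettings:
        return ThermoSettings(
            monovalent_ion=self.monovalent,
            primer_conc=self.primer_conc,
            tm_min=self.tm_min,
            tm_max=self.tm_max,
        )

    @property
    def filters(self) -> FilterSettings:
        return FilterSettings(min_len=self.min_len, max_len=self.max_len)

    @property
    def pairing(self) -> PairingSettings:
        return PairingSettings(
            min_amplicon=self.min_amplicon,
            block_size=self.block_size,
            max_pairs=self.max_pairs,
            annealing_rule=self.annealing_rule,
        )

    def summary(self) -> dict:
        return {
            "tm_range_C": f"{self.tm_min}-{self.tm_max}",
            "monovalent_M": self.monovalent,
            "primer_conc_M": self.primer_conc,
            "primer_len_bp": f"{self.min_len}-{self.max_len}",
            "min_amplicon_bp": self.min_amplicon,
            "block_size": self.block_size,
            "max_pairs": self.max_pairs,
            "consensus_thresholds": (
                f"majority={self.majority_threshold} "
                f"minor={self.minor_threshold} gap={self.gap_threshold}"
            ),
            "design_mode": self.design_mode,
        }


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}


def load_config_file(path: str | Path) -> dict:
    """Parse a flat ``key: value`` (or ``key = value``) text file into a
    dict of RunConfig overrides; unknown keys raise."""
    overrides: dict = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sep = ":" if ":" in line else "="
        if sep not in line:
            raise ValueError(f"{path}:{ln}: expected 'key: value', got {raw!r}")
        key, value = (s.strip() for s in line.split(sep, 1))
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
        overrides[key] = _coerce(key, value)
    return overrides


def _coerce(key: str, value: str):
    current = RunConfig.__dataclass_fields__[key].default
    if isinstance(current, bool) or value.lower() in ("true", "false"):
        return value.lower() == "true"
    for cast in (int, float):
        try:
            if isinstance(current, cast) or current is None:
                return cast(value)
        except ValueError:
            pass
    try:
        return int(value)
    except ValueError:
        try:
            return float(value)
        except ValueError:
            return value


def make_config(file_path: str | Path | None = None, **cli_overrides) -> RunConfig:
    """Assemble a RunConfig with CLI > file > defaults precedence."""
    values: dict = {}
    if file_path:
        values.update(load_config_file(file_path))
    values.update({k: v for k, v in cli_overrides.items() if v is not None})
    return RunConfig(**values)
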