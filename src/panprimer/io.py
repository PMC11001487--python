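"""Reading FASTA/Clustal inputs, the external-aligner adapter, and the
sectioned text report writer.

Formats go through Biopython (SeqIO/AlignIO); this module adds alphabet
validation, aligned-state inference and the error handling the pipeline
contract requires. Alignment itself is delegated to an external MAFFT
executable -- never reimplemented -- behind an injectable runner so tests
can substitute a fake.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Callable, Iterable

from Bio import AlignIO, SeqIO

from . import alphabet
from .alphabet import GAP, DegenerateSequence


class EmptyInputError(ValueError):
    pass


class FormatError(ValueError):
    pass


class AlignerNotFoundError(RuntimeError):
    pass


@dataclass
class SequenceCollection:
    """Ordered (identifier, sequence) records, possibly aligned."""

    records: list[tuple[str, DegenerateSequence]]
    is_aligned: bool = False

    def __post_init__(self):
        if not self.records:
            raise EmptyInputError("sequence collection is empty")
        if self.is_aligned:
            lengths = {len(s) for _, s in self.records}
            if len(lengths) > 1:
                raise FormatError(
                    f"aligned collection has unequal lengths: {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_single(self) -> bool:
        return len(self.records) == 1


def _infer_aligned(seqs: list[str]) -> bool:
    """Equal lengths plus at least one gap character.

    Equal-length unaligned collections exist, so equal length alone is not
    treated as alignment evidence; an explicit flag overrides inference.
    """
    if len(seqs) < 2:
        return False
    if len({len(s) for s in seqs}) != 1:
        return False
    return any(GAP in s for s in seqs)


def read_fasta(path: str | Path, *, aligned: bool | None = None) -> SequenceCollection:
    """Read a (multi-)FASTA file, validating the IUPAC alphabet.

    ``aligned`` forces the aligned state; by default it is inferred
    (equal lengths and at least one gap).
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, DegenerateSequence(str(rec.seq), context=rec.id)))
    if not records:
        raise EmptyInputError(f"empty file or no FASTA records: {path}")
    seqs = [str(s) for _, s in records]
    is_aligned = _infer_aligned(seqs) if aligned is None else aligned
    return SequenceCollection(records=records, is_aligned=is_aligned)


def read_clustal(path: str | Path) -> SequenceCollection:
    """Read a Clustal-format MSA (interleaved blocks, optional residue
    counts, conservation lines ignored)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"empty file: {path}")
    header = text.lstrip().splitlines()[0]
    if not header.upper().startswith("CLUSTAL"):
        raise FormatError(f"{path}: missing CLUSTAL header line")
    extra = header.split()[1:]
    known = {"W", "O", "X", "FORMAT", "MULTIPLE", "SEQUENCE", "ALIGNMENT"}
    unknown = [
        tok for tok in extra
        if not (tok.upper() in known or tok.replace(".", "").replace("(", "")
                .replace(")", "").isdigit() or tok.startswith("(") or tok[0].isdigit())
    ]
    if unknown:
        import warnings

        warnings.warn(f"unrecognized Clustal header tokens: {unknown}")
    try:
        aln = AlignIO.read(StringIO(text), "clustal")
    except ValueError as exc:
        raise FormatError(f"{path}: Clustal parse error: {exc}") from exc
    records = [
        (rec.id, DegenerateSequence(str(rec.seq), context=rec.id)) for rec in aln
    ]
    return SequenceCollection(records=records, is_aligned=True)


def read_input(path: str | Path, *, aligned: bool | None = None) -> SequenceCollection:
    """Dispatch on content: Clustal if the file starts with a CLUSTAL
    header, FASTA otherwise."""
    path = Path(path)
    head = path.read_text()[:200].lstrip()[:30].upper() if path.exists() else ""
    if head.startswith("CLUSTAL"):
        return read_clustal(path)
    return read_fasta(path, aligned=aligned)


def write_fasta(coll: SequenceCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in coll.records:
            fh.write(f">{name}\n{seq}\n")


# ------------------------------------------------------------------ aligner

#: runner signature: (fasta_text, mode) -> aligned fasta text
AlignRunner = Callable[[str, str], str]


def _mafft_runner(fasta_text: str, mode: str) -> str:
    exe = shutil.which("mafft")
    if exe is None:
        raise AlignerNotFoundError(
            "MAFFT executable not found on PATH; install MAFFT or supply a "
            "pre-aligned input (Clustal, or gapped FASTA with --aligned)"
        )
    flag = "--globalpair" if mode == "global" else "--localpair"
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        fh.write(fasta_text)
        tmp = fh.name
    try:
        proc = subprocess.run(
            [exe, flag, "--maxiterate", "1000", "--quiet", tmp],
            capture_output=True,
            text=True,
            check=True,
        )
    finally:
        Path(tmp).unlink(missing_ok=True)
    return proc.stdout


def align_if_needed(
    coll: SequenceCollection,
    mode: str = "global",
    runner: AlignRunner | None = None,
) -> SequenceCollection:
    """Return an aligned collection, delegating to MAFFT when needed.

    Already-aligned (or single-sequence) input passes through unchanged,
    so the operation is idempotent.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"alignment mode must be global or local, got {mode!r}")
    if coll.is_aligned or coll.is_single:
        return coll
    runner = runner or _mafft_runner
    fasta_text = "".join(f">{n}\n{s}\n" for n, s in coll.records)
    out = runner(fasta_text, mode)
    aligned = [
        (rec.id, DegenerateSequence(str(rec.seq), context=rec.id))
        for rec in SeqIO.parse(StringIO(out), "fasta")
    ]
    if not aligned:
        raise FormatError("aligner produced no output records")
    return SequenceCollection(records=aligned, is_aligned=True)


# ------------------------------------------------------------------- report

REPORT_HEADER = "# panprimer report v1"
NO_PRIMER_NOTICE = "no primer found"


def format_report(
    settings: dict,
    consensus_seq: str = "",
    regions: Iterable = (),
    forward: Iterable = (),
    reverse: Iterable = (),
    pairs: Iterable = (),
    notice: str = "",
) -> str:
    """Render the sectioned text report (the ``.dgp`` output format).

    Tab-separated tables under bracketed section headers: settings,
    consensus, conserved regions, the ranked primer lists (sequence,
    0-based index, length, Tm, penalty) and the pair table (amplicon
    length, annealing temperature).
    """
    out = [REPORT_HEADER, "", "[settings]"]
    out += [f"{k}\t{v}" for k, v in settings.items()]
    out += ["", "[consensus]", consensus_seq or "-"]
    out += ["", "[conserved-regions]", "start\tend\tlength"]
    out += [f"{r.start}\t{r.end}\t{r.length}" for r in regions]
    for title, cands in (("forward-primers", forward), ("reverse-primers", reverse)):
        out += ["", f"[{title}]", "rank\tsequence\tindex\tlength\ttm_min\ttm_mean\ttm_max\tpenalty"]
        for rank, c in enumerate(cands, start=1):
            out.append(
                f"{rank}\t{c.sequence}\t{c.start}\t{c.length}\t"
                f"{c.tm_min:.2f}\t{c.tm_mean:.2f}\t{c.tm_max:.2f}\t{c.penalty:.3f}"
            )
    out += ["", "[pairs]",
            "pair\tforward\tf_index\tf_length\treverse\tr_index\tr_length\t"
            "amplicon\ttm_diff\tannealing_tm\tpenalty"]
    wrote_pair = False
    for k, p in enumerate(pairs, start=1):
        wrote_pair = True
        out.append(
            f"{k}\t{p.forward.sequence}\t{p.forward.start}\t{p.forward.length}\t"
            f"{p.reverse.sequence}\t{p.reverse.start}\t{p.reverse.length}\t"
            f"{p.amplicon_len}\t{p.tm_diff:.2f}\t{p.annealing_tm:.2f}\t"
            f"{p.combined_penalty:.3f}"
        )
    if not wrote_pair:
        out.append(NO_PRIMER_NOTICE)
    if notice:
        out += ["", f"[notice]", notice]
    return "\n".join(out) + "\n"


def write_report(path: str | Path, **kwargs) -> None:
    Path(path).write_text(format_report(**kwargs))


def read_report_primers(path_or_text: str | Path) -> dict[str, list[str]]:
    """Recover the primer strings from a written report (round-trip
    support for downstream tooling and tests)."""
    text = (
        Path(path_or_text).read_text()
        if isinstance(path_or_text, Path)
        else (Path(path_or_text).read_text() if "\n" not in str(path_or_text) and Path(str(path_or_text)).exists() else str(path_or_text))
    )
    section = ""
    out: dict[str, list[str]] = {"forward": [], "reverse": [], "pairs_forward": [], "pairs_reverse": []}
    for line in text.splitlines():
        if line.startswith("["):
            section = line.strip("[]")
            continue
        if not line or line.startswith(("#", "rank\t", "pair\t", "start\t")):
            continue
        cells = line.split("\t")
        if section == "forward-primers" and len(cells) >= 2:
            out["forward"].append(cells[1])
        elif section == "reverse-primers" and len(cells) >= 2:
            out["reverse"].append(cells[1])
        elif section == "pairs" and len(cells) >= 5:
            out["pairs_forward"].append(cells[1])
            out["pairs_reverse"].append(cells[4])
    return out
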