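"""Sequence I/O: FASTA alignments, column trimming, ancestral-record files.

The ancestral record is the tab-delimited interchange format produced by an
ancestral-state-reconstruction step and consumed by everything downstream:

    line 1   guide tree (Newick, branch lengths set, internal nodes labeled)
    line 2   (blank; ignored on read)
    line 3   tab-separated per-site replacement rates r_i
    line 4   (blank; ignored on read)
    line 5+  one ``name<TAB>sequence`` per tree node, tips and internals

Residue positions everywhere in this package are 1-based columns of the
trimmed alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import Tree, parse_newick, write_newick

__all__ = [
    "AMINO_ACIDS",
    "Alignment",
    "AncestralRecord",
    "RecordFormatError",
    "read_fasta",
    "write_fasta",
    "trim_alignment",
    "read_ancestral_record",
    "write_ancestral_record",
]

#: The 20 canonical amino acids, PAML residue order.
AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")
_AA_SET = frozenset(AMINO_ACIDS)


class RecordFormatError(ValueError):
    """Malformed FASTA or ancestral-record input."""


@dataclass(frozen=True)
class Alignment:
    """Ordered named sequences of equal length over a fixed residue alphabet."""

    entries: tuple[tuple[str, str], ...]
    alphabet: tuple[str, ...] = AMINO_ACIDS

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise RecordFormatError("duplicate sequence names in alignment")
        lengths = {len(s) for _, s in self.entries}
        if len(lengths) > 1:
            raise RecordFormatError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def width(self) -> int:
        return len(self.entries[0][1]) if self.entries else 0

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def sequence(self, name: str) -> str:
        for n, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class AncestralRecord:
    """Labeled guide tree + per-site rates + one sequence per node."""

    tree: Tree
    site_rates: tuple[float, ...]
    sequences: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        node_names = set(self.tree.nodes)
        seq_names = set(self.sequences)
        if seq_names != node_names:
            missing = sorted(node_names - seq_names)
            extra = sorted(seq_names - node_names)
            parts = []
            if missing:
                parts.append(f"missing sequences for node(s) {', '.join(missing)}")
            if extra:
                parts.append(f"sequences for unknown node(s) {', '.join(extra)}")
            raise RecordFormatError("; ".join(parts))
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise RecordFormatError(f"node sequences have unequal lengths: {sorted(lengths)}")
        L = lengths.pop()
        if len(self.site_rates) != L:
            raise RecordFormatError(
                f"{len(self.site_rates)} site rates for sequences of length {L}"
            )
        if any(r <= 0 for r in self.site_rates):
            raise RecordFormatError("site rates must be positive")

    @property
    def length(self) -> int:
        return len(self.site_rates)

    def tip_alignment(self) -> Alignment:
        return Alignment(tuple((t, self.sequences[t]) for t in self.tree.tips()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AncestralRecord):
            return NotImplemented
        return (
            self.tree == other.tree
            and self.sequences == other.sequences
            and len(self.site_rates) == len(other.site_rates)
            and all(abs(a - b) <= 1e-9 * max(1.0, abs(a)) for a, b in zip(self.site_rates, other.site_rates))
        )

    __hash__ = None  # type: ignore[assignment]


# --- FASTA -------------------------------------------------------------------


def read_fasta(path: str | Path) -> Alignment:
    """Read a FASTA alignment; sequences uppercased, record order preserved.

    Unequal sequence lengths or duplicate names raise
    :class:`RecordFormatError` (via :class:`Alignment` validation).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise RecordFormatError(f"no FASTA records in {path}")
    return Alignment(tuple((r.id, str(r.seq).upper()) for r in records))


def write_fasta(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in aln.entries]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # Biopython wraps at 60 columns


# --- trimming ----------------------------------------------------------------


def trim_alignment(aln: Alignment) -> tuple[Alignment, list[int]]:
    """Drop every column containing a gap or ambiguous character.

    A column survives iff every residue in it is one of the 20 uppercase
    canonical amino acids; anything else ('-', '.', 'X', 'B', 'Z', 'J', 'U',
    'O', '*', '?', lowercase, ...) disqualifies the column.  Returns the
    trimmed alignment and the kept original column indices (1-based,
    strictly increasing).
    """
    keep = [
        i
        for i in range(aln.width)
        if all(seq[i] in _AA_SET for _, seq in aln.entries)
    ]
    trimmed = Alignment(
        tuple((name, "".join(seq[i] for i in keep)) for name, seq in aln.entries),
        aln.alphabet,
    )
    return trimmed, [i + 1 for i in keep]


# --- ancestral record --------------------------------------------------------


def read_ancestral_record(path: str | Path) -> AncestralRecord:
    """Read and validate an ancestral-record file (layout in module docstring).

    A missing or blank rate line falls back to rate 1.0 at every site, with
    a warning — some reconstruction programs omit per-site rates.
    """
    lines = Path(path).read_text().split("\n")
    if not lines or not lines[0].strip():
        raise RecordFormatError(f"{path}: line 1: missing guide tree")
    try:
        tree = parse_newick(lines[0].strip())
    except ValueError as exc:
        raise RecordFormatError(f"{path}: line 1: {exc}") from exc

    rate_line = lines[2].strip() if len(lines) > 2 else ""

    sequences: dict[str, str] = {}
    for lineno, raw in enumerate(lines[4:], start=5):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise RecordFormatError(f"{path}: line {lineno}: expected 'name<TAB>sequence'")
        name, seq = parts
        if name in sequences:
            raise RecordFormatError(f"{path}: line {lineno}: duplicate sequence name {name!r}")
        sequences[name] = seq.upper()

    if not sequences:
        raise RecordFormatError(f"{path}: no sequence lines found (expected from line 5)")
    L = len(next(iter(sequences.values())))

    if rate_line:
        try:
            site_rates = tuple(float(x) for x in rate_line.split("\t"))
        except ValueError as exc:
            raise RecordFormatError(f"{path}: line 3: unreadable rate value: {exc}") from exc
    else:
        warnings.warn(f"{path}: no per-site rates on line 3; defaulting all rates to 1.0")
        site_rates = (1.0,) * L

    if len(site_rates) != L:
        raise RecordFormatError(
            f"{path}: line 3: {len(site_rates)} rates but sequences have length {L}"
        )
    try:
        return AncestralRecord(tree=tree, site_rates=site_rates, sequences=sequences)
    except RecordFormatError as exc:
        raise RecordFormatError(f"{path}: {exc}") from exc


def write_ancestral_record(record: AncestralRecord, path: str | Path) -> None:
    """Write the tab-delimited record; tips first (tree order), then internals."""
    with open(path, "w") as fh:
        fh.write(write_newick(record.tree) + "\n")
        fh.write("\n")
        fh.write("\t".join(format(r, ".9g") for r in record.site_rates) + "\n")
        fh.write("\n")
        for name in record.tree.tips() + record.tree.internals():
            fh.write(f"{name}\t{record.sequences[name]}\n")
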