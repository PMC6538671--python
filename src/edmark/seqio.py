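"""Input/output layer and core data model.

Everything downstream of this module consumes only the types defined here:
reference panels (aligned or unaligned FASTA plus an optional taxonomy table),
primers and primer pairs, and paired sequencing reads.  Coordinates are always
0-based, half-open, on the plus strand as written in the FASTA.

Conventions enforced loudly rather than silently repaired:

* sequences are restricted to IUPAC nucleotide codes plus ``-`` as the only
  gap character (``.`` is rejected);
* FASTQ is Phred+33 with qualities in [0, 60] (the MiSeq convention);
* record ids must be unique within a panel; nothing is dropped or renamed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import yaml
from Bio import SeqIO

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"
_VALID_CHARS = IUPAC_CODES | {GAP}

#: IUPAC code -> set of concrete bases it stands for.
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)


class SeqFormatError(ValueError):
    """Malformed sequence input (bad characters, duplicate ids, ...)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_seq(seq: str, where: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SeqFormatError(f"{where}: empty sequence")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise SeqFormatError(
            f"{where}: invalid characters {sorted(bad)!r}; "
            "only IUPAC nucleotide codes and '-' are accepted"
        )
    return seq


@dataclass
class SeqRecord:
    """A named nucleotide sequence with an optional taxon label."""

    id: str
    seq: str
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("record with empty id")
        self.seq = _check_seq(self.seq, f"record {self.id!r}")

    @property
    def degapped(self) -> str:
        return self.seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferencePanel:
    """A set of reference sequences, optionally as a multiple alignment.

    ``aligned`` is set iff all sequences have equal length.  For aligned
    panels, gap-only columns are permitted but reported via
    :meth:`gap_only_columns`.
    """

    records: list[SeqRecord]
    aligned: bool = field(init=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqFormatError(f"duplicate record ids: {dupes}")
        lengths = {len(r) for r in self.records}
        self.aligned = len(lengths) == 1 and bool(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def alignment_length(self) -> int:
        if not self.aligned:
            raise ValueError("panel is not aligned")
        return len(self.records[0])

    def gap_only_columns(self) -> list[int]:
        """Indices of alignment columns that are gap in every record."""
        n = self.alignment_length
        return [
            j for j in range(n)
            if all(r.seq[j] == GAP for r in self.records)
        ]

    def taxon_of(self, record_id: str) -> str | None:
        for r in self.records:
            if r.id == record_id:
                return r.taxon
        raise KeyError(record_id)


@dataclass
class Primer:
    """An adapter-free oligo, written 5'->3' in its own sense.

    ``orientation`` is ``"forward"`` (anneals to the minus strand, extends
    along the plus strand) or ``"reverse"`` (anneals to the plus strand).
    An optional 5' ``adapter`` tail is carried but never used for matching.
    """

    name: str
    seq: str
    orientation: str
    adapter: str | None = None

    def __post_init__(self) -> None:
        self.seq = _check_seq(self.seq, f"primer {self.name!r}")
        if GAP in self.seq:
            raise SeqFormatError(f"primer {self.name!r}: gaps not allowed")
        if len(self.seq) < 10:
            raise SeqFormatError(
                f"primer {self.name!r}: length {len(self.seq)} < 10"
            )
        if self.orientation not in ("forward", "reverse"):
            raise SeqFormatError(
                f"primer {self.name!r}: orientation must be "
                f"'forward' or 'reverse', got {self.orientation!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PrimerPair:
    """A forward/reverse primer pair delimiting a variable core region."""

    fwd: Primer
    rev: Primer
    max_core_len: int = 200

    def __post_init__(self) -> None:
        if self.fwd.orientation != "forward":
            raise SeqFormatError("fwd primer must have orientation 'forward'")
        if self.rev.orientation != "reverse":
            raise SeqFormatError("rev primer must have orientation 'reverse'")


@dataclass
class Read:
    """A sequencing read with per-base Phred scores."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise SeqFormatError(
                f"read {self.id!r}: {len(self.seq)} bases vs "
                f"{len(self.quals)} quality scores"
            )
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise SeqFormatError(f"read {self.id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    r1: Read
    r2: Read


# ---------------------------------------------------------------------------
# FASTA / taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (header line, then ``id<TAB>taxon``)."""
    path = Path(path)
    table: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise SeqFormatError(f"{path}: empty taxonomy table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise SeqFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rid, taxon = parts
            if rid in table:
                raise SeqFormatError(f"{path}:{lineno}: duplicate id {rid!r}")
            table[rid] = taxon
    return table


def read_fasta(path: str | Path, taxonomy_path: str | Path | None = None) -> ReferencePanel:
    """Load a FASTA file (aligned or not) into a :class:`ReferencePanel`.

    The ``aligned`` flag is set iff every record has the same length.  If a
    taxonomy table is given, every id in it must exist in the FASTA; FASTA
    records without a taxonomy entry keep ``taxon=None``.
    """
    path = Path(path)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else {}
    records = [
        SeqRecord(id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    panel = ReferencePanel(records)  # uniqueness checked here
    known = set(panel.ids)
    missing = sorted(set(taxonomy) - known)
    if missing:
        raise SeqFormatError(
            f"taxonomy ids absent from FASTA: {missing}"
        )
    for r in panel.records:
        r.taxon = taxonomy.get(r.id)
    return panel


def write_fasta(panel: ReferencePanel | Sequence[SeqRecord], path: str | Path) -> None:
    records = panel.records if isinstance(panel, ReferencePanel) else list(panel)
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# FASTQ (paired, Phred+33)
# ---------------------------------------------------------------------------

def _parse_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):  # Biopython enforces +33 range
        quals = rec.letter_annotations["phred_quality"]
        yield Read(id=rec.id, seq=str(rec.seq).upper(), quals=list(quals))


def read_fastq_pair(path_r1: str | Path, path_r2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files, paired by order.

    Raises if one file has more records than the other.
    """
    it1, it2 = _parse_fastq(path_r1), _parse_fastq(path_r2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            longer = path_r2 if r1 is sentinel else path_r1
            raise SeqFormatError(
                f"unpaired trailing record(s) in {longer}: "
                "R1/R2 files differ in record count"
            )
        yield ReadPair(r1=r1, r2=r2)


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in reads:
            qline = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qline}\n")


def write_fastq_pair(pairs: Sequence[ReadPair], path_r1: str | Path, path_r2: str | Path) -> None:
    write_fastq([p.r1 for p in pairs], path_r1)
    write_fastq([p.r2 for p in pairs], path_r2)


# ---------------------------------------------------------------------------
# Tables, trees, primer configs
# ---------------------------------------------------------------------------

def write_counts_table(table, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a taxon x sample counts DataFrame as TSV (index label 'taxon')."""
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index_label="taxon")


def read_counts_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col="taxon", comment="#")


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (skbio TreeNode) as Newick."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def read_primer_config(path: str | Path) -> list[PrimerPair]:
    """Read primer pairs from a YAML config.

    Schema::

        primer_pairs:
          - name: myMarker
            fwd: CTTACAGCAAACCTGACAGCAG
            rev: TTGGTGTGCCATTATACGTTTTCTTG
            fwd_adapter: ACACTCTTTCCCTACACGACGCTCTTCCGATCT   # optional
            rev_adapter: GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT  # optional
            max_core_len: 200                                # optional

    An empty file yields an empty list.  Unknown keys are rejected.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) if raw.strip() else None
    if data is None:
        return []
    if not isinstance(data, dict) or set(data) - {"primer_pairs"}:
        raise SeqFormatError(f"{path}: expected a top-level 'primer_pairs' list")
    pairs = []
    allowed = {"name", "fwd", "rev", "fwd_adapter", "rev_adapter", "max_core_len"}
    for i, entry in enumerate(data.get("primer_pairs") or []):
        unknown = set(entry) - allowed
        if unknown:
            raise SeqFormatError(
                f"{path}: primer pair #{i}: unknown keys {sorted(unknown)}"
            )
        for key in ("name", "fwd", "rev"):
            if key not in entry:
                raise SeqFormatError(f"{path}: primer pair #{i}: missing {key!r}")
        name = entry["name"]
        fwd = Primer(
            name=f"{name}-F", seq=entry["fwd"], orientation="forward",
            adapter=entry.get("fwd_adapter"),
        )
        rev = Primer(
            name=f"{name}-R", seq=entry["rev"], orientation="reverse",
            adapter=entry.get("rev_adapter"),
        )
        pairs.append(PrimerPair(fwd=fwd, rev=rev,
                                max_core_len=int(entry.get("max_core_len", 200))))
    return pairs
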