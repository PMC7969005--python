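"""Sequence records, coordinate conventions and plain-text readers/writers.

Coordinate convention used throughout the package: genomic/intronic positions
are 1-based and inclusive, and position 1 is the first intron nucleotide (the
G of the GT donor).  A branch point written "dBP+N" is the adenine at intron
position N, i.e. N nucleotides downstream of the 5' splice site.  The distance
of position N to the 3' splice site is ``length - N + 1``.

The internal canonical alphabet is DNA (T); RNA input is converted on read and
can be emitted back as RNA on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "NucSeq",
    "QualRead",
    "IntronModel",
    "FastaFormatError",
    "PairSyncError",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "revcomp",
    "write_table",
    "read_table",
]

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_IUPAC_RNA = set("ACGURYSWKMBDHVN")


class FastaFormatError(ValueError):
    """Malformed FASTA input (the message names the offending line)."""


class PairSyncError(ValueError):
    """Mate files out of sync (the message names the record index)."""


@dataclass(frozen=True)
class NucSeq:
    """A nucleotide sequence with an explicit DNA/RNA alphabet mode.

    Invariants: non-empty, uppercase IUPAC letters only, and U and T are
    never mixed within one sequence.
    """

    bases: str
    alphabet_mode: str = "DNA"

    def __post_init__(self) -> None:
        if self.alphabet_mode not in ("DNA", "RNA"):
            raise ValueError(f"alphabet_mode must be DNA or RNA, got {self.alphabet_mode!r}")
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if not bases:
            raise ValueError("empty sequence")
        if "U" in bases and "T" in bases:
            raise ValueError("sequence mixes U and T")
        allowed = _IUPAC_DNA if self.alphabet_mode == "DNA" else _IUPAC_RNA
        bad = set(bases) - allowed
        if bad:
            raise ValueError(f"invalid {self.alphabet_mode} characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def to_dna(self) -> "NucSeq":
        return NucSeq(self.bases.replace("U", "T"), "DNA")

    def to_rna(self) -> "NucSeq":
        return NucSeq(self.bases.replace("T", "U"), "RNA")

    def revcomp(self) -> "NucSeq":
        if self.alphabet_mode == "RNA":
            return NucSeq(str(Seq(self.bases).reverse_complement_rna()), "RNA")
        return NucSeq(str(Seq(self.bases).reverse_complement()), "DNA")


def as_dna(seq: "NucSeq | str") -> str:
    """Canonical uppercase DNA form of a DNA- or RNA-form sequence."""
    if isinstance(seq, NucSeq):
        return seq.to_dna().bases
    s = str(seq).upper()
    return NucSeq(s, "RNA" if "U" in s else "DNA").to_dna().bases


def revcomp(seq: "NucSeq | str", alphabet_mode: str = "DNA") -> NucSeq:
    """Reverse complement; an involution that preserves length."""
    if isinstance(seq, str):
        seq = NucSeq(seq, alphabet_mode)
    return seq.revcomp()


@dataclass
class QualRead:
    """A sequencing read with per-base phred qualities (phred+33 on disk)."""

    id: str
    seq: str
    phred: np.ndarray

    def __post_init__(self) -> None:
        self.phred = np.asarray(self.phred, dtype=np.int64)
        if len(self.phred) != len(self.seq):
            raise ValueError(
                f"read {self.id}: {len(self.phred)} qualities for {len(self.seq)} bases"
            )
        if len(self.phred) and self.phred.min() < 0:
            raise ValueError(f"read {self.id}: negative phred score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class IntronModel:
    """An intron with 1-based coordinates and annotated branch-point adenines.

    ``donor_pos`` is always 1 (first intron nucleotide) and ``acceptor_pos``
    always equals the intron length.  Unless ``permissive`` is set the first
    two bases must be GT and the last two AG.
    """

    seq: str
    dbps: list[int] = field(default_factory=list)
    permissive: bool = False

    def __post_init__(self) -> None:
        self.seq = str(NucSeq(self.seq).to_dna())
        if not self.permissive:
            if self.seq[:2] != "GT":
                raise ValueError(f"intron does not start with GT: {self.seq[:2]}")
            if self.seq[-2:] != "AG":
                raise ValueError(f"intron does not end with AG: {self.seq[-2:]}")
        for p in self.dbps:
            if not 1 <= p <= len(self.seq):
                raise ValueError(f"branch point position {p} outside [1, {len(self.seq)}]")
        self.dbps = sorted(self.dbps)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def donor_pos(self) -> int:
        return 1

    @property
    def acceptor_pos(self) -> int:
        return self.length

    def base(self, pos: int) -> str:
        """Base at 1-based intron position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside [1, {self.length}]")
        return self.seq[pos - 1]

    def dist_3ss(self, pos: int) -> int:
        """Distance from position ``pos`` to the 3'ss, inclusive of both ends."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside [1, {self.length}]")
        return self.length - pos + 1


def read_fasta(path: str | Path, alphabet_mode: str = "DNA") -> list[tuple[str, NucSeq]]:
    """Read a FASTA file, preserving record order.

    Sequences are uppercased and converted to the requested alphabet.
    Malformed input raises :class:`FastaFormatError` naming the line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            header_seen = True
            if not line[1:].strip():
                raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
        elif not header_seen:
            raise FastaFormatError(f"{path}: sequence before first header at line {lineno}")

    records: list[tuple[str, NucSeq]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaFormatError(f"{path}: empty record {rec.id!r}")
        seq = NucSeq(str(rec.seq))
        records.append((rec.id, seq.to_rna() if alphabet_mode == "RNA" else seq.to_dna()))
    return records


def write_fasta(records: Iterable[tuple[str, "NucSeq | str"]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def _strip_mate_suffix(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> list[tuple[QualRead, QualRead]]:
    """Read record-synchronised paired FASTQ files (phred+33).

    Pair ids must match after stripping /1 and /2 mate suffixes; a mismatch
    raises :class:`PairSyncError` citing the 1-based record index.
    """
    it1 = SeqIO.parse(str(path_r1), "fastq")
    it2 = SeqIO.parse(str(path_r2), "fastq")
    pairs: list[tuple[QualRead, QualRead]] = []
    idx = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        idx += 1
        if r1 is None or r2 is None:
            raise PairSyncError(f"mate files desynchronised at record {idx}: one file ended early")
        if _strip_mate_suffix(r1.id) != _strip_mate_suffix(r2.id):
            raise PairSyncError(
                f"mate id mismatch at record {idx}: {r1.id!r} vs {r2.id!r}"
            )
        pairs.append(
            (
                QualRead(r1.id, str(r1.seq).upper(),
                         np.array(r1.letter_annotations["phred_quality"])),
                QualRead(r2.id, str(r2.seq).upper(),
                         np.array(r2.letter_annotations["phred_quality"])),
            )
        )
    return pairs


def write_fastq_pairs(
    pairs: Iterable[tuple[QualRead, QualRead]], path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write read pairs as two phred+33 FASTQ files."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r1, r2 in pairs:
            for fh, r in ((f1, r1), (f2, r2)):
                qual = "".join(chr(q + 33) for q in r.phred)
                fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_table(records, path: str | Path) -> None:
    """Write homogeneous records as a TSV with a header row.

    ``records`` may be a DataFrame or an iterable of mappings/dataclasses.
    Round-trips bit-exactly through :func:`read_table`.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
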