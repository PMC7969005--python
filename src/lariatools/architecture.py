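"""3' splice-site architecture: branch-point motifs, U2 duplexes, AGEZ, PPT.

Branch points (BPs) are found as trinucleotide motifs ending in the BP
adenine (UAA is the optimal mammalian context, UUA/UGA/UCA suboptimal).
A BP whose distance from the 5'ss falls strictly below the ~50-nt steric
threshold — too close for simultaneous U1/U2 snRNP assembly — is flagged as
a *distant* branch point (dBP).

U2 snRNA:BP duplex strength is scored by counting hydrogen bonds in the
canonical register: intron positions -5..-1 and +1 around the BP adenine pair
antiparallel with the 6-nt GUAGUA box, the BP adenine itself bulged out.
Watson-Crick G:C pairs count 3 bonds, A:U pairs 2, G:U wobbles 2, anything
else 0.  An extended U2 segment (beyond the box) may be supplied to also
score the extended register; it has no default because the extended pairing
mode is preparation-specific.

The AG-exclusion zone (AGEZ) is the AG-dinucleotide-free stretch upstream of
the 3'ss AG; it is measured from the G of the nearest upstream internal AG to
the intron end (the terminal 3'ss AG itself is excluded from the search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import IntronModel, NucSeq, as_dna

__all__ = [
    "BranchPointHit",
    "U2DuplexModel",
    "AgezResult",
    "PptProfile",
    "Edit",
    "DEFAULT_BP_MOTIFS",
    "scan_bp_motifs",
    "count_u2_hbonds",
    "enumerate_dbp_candidates",
    "agez",
    "ppt_profile",
    "motif_density",
    "apply_variant",
]

#: Trinucleotide BP motif classes (DNA form, last base is the BP adenine).
DEFAULT_BP_MOTIFS = frozenset({"TAA", "TGA", "TCA", "TTA"})

#: Hydrogen bonds per base pair (both strands in DNA form; U == T).
HBONDS: Mapping[tuple[str, str], int] = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 2, ("T", "G"): 2,  # G:U wobble
}

DEFAULT_STERIC_THRESHOLD = 50


@dataclass(frozen=True)
class U2DuplexModel:
    """The U2 snRNA segment that base-pairs with the branch-point region.

    ``core_box`` is the 6-nt branch-point-interacting box (DNA form of
    GUAGUA), written 5'->3'.  ``extended_seq`` is an optional longer U2
    segment containing the core box; ``core_offset`` is the 0-based index of
    the core box within it.  In the core register the intron positions
    -5..-1, +1 around the BP adenine pair antiparallel with the box and the
    BP adenine is bulged (never paired).
    """

    core_box: str = "GTAGTA"
    extended_seq: str | None = None
    core_offset: int | None = None

    def __post_init__(self) -> None:
        core = as_dna(self.core_box)
        object.__setattr__(self, "core_box", core)
        if len(core) != 6:
            raise ValueError("core_box must be 6 nt")
        if self.extended_seq is not None:
            ext = as_dna(self.extended_seq)
            object.__setattr__(self, "extended_seq", ext)
            off = self.core_offset
            if off is None:
                off = ext.find(core)
                if off < 0:
                    raise ValueError("core_box not found in extended_seq")
                object.__setattr__(self, "core_offset", off)
            elif ext[off : off + 6] != core:
                raise ValueError("extended_seq does not carry core_box at core_offset")


@dataclass
class BranchPointHit:
    """A branch-point adenine and its local context metrics."""

    bp_pos: int                 # 1-based intron position of the BP adenine
    motif3: str                 # trinucleotide at positions -2..0
    dist_5ss: int               # == bp_pos
    dist_3ss: int               # length - bp_pos + 1
    hbond_core: int | None = None
    hbond_extended: int | None = None
    is_dbp: bool = False


@dataclass
class AgezResult:
    agez_len: int
    upstream_ag_pos: int | None  # position of the G of the nearest upstream AG


@dataclass
class PptProfile:
    """Windowed base-composition profile of a (poly)pyrimidine tract."""

    windows: pd.DataFrame            # start, frac_u, frac_c, frac_g, frac_a, frac_py, frac_ug, label
    segments: list[tuple[str, int, int]]  # (label, start, end) 1-based inclusive
    window_len: int
    rich_threshold: float


def _pair_bonds(a: str, b: str) -> int:
    return HBONDS.get((a, b), 0)


def scan_bp_motifs(
    intron: IntronModel,
    motif_classes: Iterable[str] = DEFAULT_BP_MOTIFS,
    duplex: U2DuplexModel | None = None,
    steric_threshold: int = DEFAULT_STERIC_THRESHOLD,
    allow_non_a: bool = False,
) -> list[BranchPointHit]:
    """Scan an intron for branch-point trinucleotide motifs.

    Each hit's ``motif3`` occupies intron positions bp_pos-2..bp_pos, the last
    base being the BP nucleotide (an adenine unless ``allow_non_a`` permits
    the putative low-usage uridine BP class).  Hits are sorted by position.
    H-bond counts are attached when the flanks allow scoring.
    """
    if intron.length == 0:
        raise ValueError("empty intron")
    motifs = {as_dna(m) for m in motif_classes}
    for m in motifs:
        if len(m) != 3:
            raise ValueError(f"motif classes must be trinucleotides, got {m!r}")
        if not allow_non_a and not m.endswith("A"):
            raise ValueError(f"motif {m!r} does not end in the BP adenine")
    seq = intron.seq
    duplex = duplex or U2DuplexModel()
    hits: list[BranchPointHit] = []
    for i in range(3, intron.length + 1):  # i = bp_pos
        tri = seq[i - 3 : i]
        if tri not in motifs:
            continue
        core = ext = None
        if i - 5 >= 1 and i + 1 <= intron.length:
            core, ext = count_u2_hbonds(seq, i, duplex)
        hits.append(
            BranchPointHit(
                bp_pos=i,
                motif3=tri,
                dist_5ss=i,
                dist_3ss=intron.dist_3ss(i),
                hbond_core=core,
                hbond_extended=ext,
                is_dbp=i < steric_threshold,
            )
        )
    return hits


def count_u2_hbonds(
    intron_seq: "str | NucSeq", bp_pos: int, duplex: U2DuplexModel | None = None
) -> tuple[int, int | None]:
    """Count hydrogen bonds of the U2:branch-point duplex at ``bp_pos``.

    Returns ``(hbond_core, hbond_extended)``; the extended count is None
    unless the duplex model carries an extended U2 segment.  The count is
    invariant under the DNA/RNA form of the same sequence.
    """
    duplex = duplex or U2DuplexModel()
    seq = as_dna(str(intron_seq))
    n = len(seq)
    if bp_pos - 5 < 1 or bp_pos + 1 > n:
        raise ValueError(
            f"bp_pos {bp_pos} needs >=5 upstream and >=1 downstream nucleotides"
        )

    def register_bonds(u2: str, core_off: int) -> int:
        # u2 written 5'->3'; the core box occupies u2[core_off:core_off+6].
        # Antiparallel pairing maps intron position (bp_pos + 1) onto the
        # first (5'-most) core base and upstream intron positions onto
        # successive 3'-ward U2 bases; the BP adenine is bulged.
        total = 0
        for k, u2_base in enumerate(u2):
            # offset within the core register: k == core_off pairs intron +1
            delta = k - core_off          # 0 -> +1; 1 -> -1; 2 -> -2; ...
            if delta == 0:
                ipos = bp_pos + 1
            elif delta > 0:
                ipos = bp_pos - delta     # -1, -2, ... (BP adenine skipped)
            else:
                ipos = bp_pos + 1 - delta  # +2, +3, ... further downstream
            if not 1 <= ipos <= n:
                continue
            total += _pair_bonds(seq[ipos - 1], u2_base)
        return total

    core = register_bonds(duplex.core_box, 0)
    ext = None
    if duplex.extended_seq is not None:
        ext = register_bonds(duplex.extended_seq, duplex.core_offset)
    return core, ext


def enumerate_dbp_candidates(
    intron: IntronModel,
    steric_threshold: int = DEFAULT_STERIC_THRESHOLD,
    motif_classes: Iterable[str] = DEFAULT_BP_MOTIFS,
    duplex: U2DuplexModel | None = None,
) -> list[BranchPointHit]:
    """Branch-point hits with the distant-BP flag set by the steric rule.

    A hit is a dBP when its 5'ss distance is strictly below the threshold
    (the published threshold is ~50 nt).
    """
    return scan_bp_motifs(
        intron, motif_classes, duplex=duplex, steric_threshold=steric_threshold
    )


def agez(intron: IntronModel) -> AgezResult:
    """AG-exclusion-zone length of an intron.

    Searches positions 1..length-2 for the start of an internal AG (the
    terminal 3'ss AG is outside this range); the zone runs from the G of the
    nearest such AG to the intron end: ``agez_len = length - pos(G)``.  With
    no internal AG the whole intron is the zone.
    """
    if intron.length < 4:
        raise ValueError("intron too short for an AGEZ")
    seq = intron.seq
    last_ag_start = None
    for p in range(1, intron.length - 1):  # 1-based start of the dinucleotide
        if seq[p - 1 : p + 1] == "AG":
            last_ag_start = p
    if last_ag_start is None:
        return AgezResult(agez_len=intron.length, upstream_ag_pos=None)
    g_pos = last_ag_start + 1
    return AgezResult(agez_len=intron.length - g_pos, upstream_ag_pos=g_pos)


_RICH_PAIRS = (("UU", ("T", "T")), ("UC", ("T", "C")), ("UG", ("T", "G")))


def ppt_profile(
    seq: "str | NucSeq", window_len: int = 10, rich_threshold: float = 0.6
) -> PptProfile:
    """Sliding-window base composition with UC-/UU-/UG-rich segment calls.

    Windows advance in steps of 1.  A window is XY-rich when the joint X+Y
    fraction exceeds ``rich_threshold`` and (for distinct X, Y) each base
    exceeds 0.2; UU-rich means the U fraction alone exceeds the threshold.
    Labels are assigned in priority order UU > UC > UG; adjacent windows with
    the same label merge into segments.
    """
    s = as_dna(str(seq))
    n = len(s)
    if window_len > n:
        raise ValueError(f"window_len {window_len} longer than sequence ({n} nt)")
    arr = np.frombuffer(s.encode(), dtype="S1")
    ind = {b: (arr == b.encode()).astype(float) for b in "ACGT"}
    kernel = np.ones(window_len)
    frac = {b: np.convolve(ind[b], kernel, mode="valid") / window_len for b in "ACGT"}

    starts = np.arange(1, n - window_len + 2)
    labels = []
    for i in range(len(starts)):
        f = {b: frac[b][i] for b in "ACGT"}
        label = "other"
        for name, (x, y) in _RICH_PAIRS:
            if x == y:
                if f[x] > rich_threshold:
                    label = f"{name}-rich"
                    break
            elif f[x] + f[y] > rich_threshold and f[x] > 0.2 and f[y] > 0.2:
                label = f"{name}-rich"
                break
        labels.append(label)

    windows = pd.DataFrame(
        {
            "start": starts,
            "frac_u": frac["T"],
            "frac_c": frac["C"],
            "frac_g": frac["G"],
            "frac_a": frac["A"],
            "frac_py": frac["T"] + frac["C"],
            "frac_ug": frac["T"] + frac["G"],
            "label": labels,
        }
    )

    segments: list[tuple[str, int, int]] = []
    for i, lab in enumerate(labels):
        if lab == "other":
            continue
        start = int(starts[i])
        end = start + window_len - 1
        if segments and segments[-1][0] == lab and start <= segments[-1][2] + 1:
            segments[-1] = (lab, segments[-1][1], end)
        else:
            segments.append((lab, start, end))
    return PptProfile(windows, segments, window_len, rich_threshold)


def motif_density(seq: "str | NucSeq", motifs: Iterable[str]) -> tuple[int, float]:
    """Count overlapping motif occurrences and their per-nucleotide density."""
    motifs = {as_dna(m) for m in motifs}
    if not motifs:
        raise ValueError("motifs must be non-empty")
    s = as_dna(str(seq))
    count = 0
    for m in motifs:
        start = 0
        while True:
            i = s.find(m, start)
            if i < 0:
                break
            count += 1
            start = i + 1  # overlapping occurrences count
    return count, count / len(s)


@dataclass(frozen=True)
class Edit:
    """A substitution, insertion or deletion at a 1-based coordinate.

    op 'sub': replace ``ref`` (guard) at ``pos`` with ``alt``.
    op 'ins': insert ``alt`` after position ``pos`` (pos 0 = prepend).
    op 'del': delete ``ref`` (guard) starting at ``pos``.
    """

    op: str
    pos: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.op not in ("sub", "ins", "del"):
            raise ValueError(f"unknown edit op {self.op!r}")


def apply_variant(seq: "str | NucSeq", edits: Sequence[Edit]) -> tuple[str, list[str]]:
    """Apply substitution/insertion/deletion edits to a sequence.

    Edits are applied right-to-left so stated coordinates stay valid.  A
    reference-base mismatch raises (guards against coordinate drift).
    Returns the edited sequence and a human-readable edit log.
    """
    s = as_dna(str(seq))
    log: list[str] = []
    for e in sorted(edits, key=lambda e: e.pos, reverse=True):
        if e.op == "ins":
            if not 0 <= e.pos <= len(s):
                raise IndexError(f"insertion position {e.pos} outside [0, {len(s)}]")
            s = s[: e.pos] + e.alt.upper() + s[e.pos :]
            log.append(f"ins@{e.pos}:+{e.alt.upper()}")
            continue
        if not 1 <= e.pos <= len(s):
            raise IndexError(f"position {e.pos} outside [1, {len(s)}]")
        if e.op == "sub":
            ref, alt = e.ref.upper(), e.alt.upper()
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError("substitution needs single ref and alt bases")
            if s[e.pos - 1] != ref:
                raise ValueError(
                    f"reference mismatch at {e.pos}: expected {ref}, observed {s[e.pos - 1]}"
                )
            if ref == alt:
                raise ValueError(f"substitution at {e.pos} does not change the base")
            s = s[: e.pos - 1] + alt + s[e.pos :]
            log.append(f"sub@{e.pos}:{ref}>{alt}")
        else:  # del
            ref = e.ref.upper()
            if not ref:
                raise ValueError("deletion needs the deleted reference bases")
            obs = s[e.pos - 1 : e.pos - 1 + len(ref)]
            if obs != ref:
                raise ValueError(
                    f"reference mismatch at {e.pos}: expected {ref}, observed {obs}"
                )
            s = s[: e.pos - 1] + s[e.pos - 1 + len(ref) :]
            log.append(f"del@{e.pos}:-{ref}")
    if not s:
        raise ValueError("edits removed the whole sequence")
    return s, log[::-1]
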