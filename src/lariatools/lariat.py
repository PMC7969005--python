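"""Lariat amplicon sequencing: QC, pair merging, junction alignment, usage.

Reverse transcription across the 2'-5' branch of an intron lariat yields
cDNAs in which the intron segment ending at the branch-point (BP) adenine is
joined head-on to the intron 5' start.  Aligning merged read pairs against a
panel of such synthetic junction references — one per candidate BP — assigns
each read to a BP.  The RT frequently stumbles at the branch, leaving
diagnostic A>T substitutions or 1-nt indels exactly at the junction; these
are classified, not penalised away.

Read processing follows the published pipeline rules: reads must have fewer
than 8 bases under phred 10; pairs merge with >=20 nt overlap and <=15
overlap mismatches; merged reads under 195 nt are discarded; alignment
permits a single indel with gap-open 11 and extension/mismatch penalties 4.

Alignment is exact: every placement with at most one indel run is enumerated
(offsets x indel kind x indel length x split point) with numpy prefix-sum
mismatch counts and cost-bound pruning, so the reported cost equals the
brute-force optimum by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import IntronModel, NucSeq, QualRead

__all__ = [
    "AlignPenalties",
    "LariatReference",
    "BranchAlignment",
    "UsageTable",
    "qc_filter_read",
    "merge_pairs",
    "build_lariat_reference",
    "align_branch_read",
    "placement_cost",
    "quantify_usage",
    "compare_usage",
    "compare_bin_fractions",
]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class AlignPenalties:
    """Edit costs of the junction aligner (published pipeline values)."""

    mismatch: int = 4
    gap_open: int = 11
    gap_ext: int = 4          # per gapped base; a 1-nt indel costs open + ext = 15
    min_flank: int = 5        # aligned nt required on each side of the junction


@dataclass(frozen=True)
class LariatReference:
    """Synthetic lariat-junction sequence for one branch point.

    ``seq`` = intron[bp_pos-up_len+1 .. bp_pos] ++ intron[1 .. down_len];
    ``junction_index`` (1-based, == up_len) is the BP base itself.
    """

    bp_pos: int
    up_len: int
    down_len: int
    seq: str
    junction_index: int


@dataclass
class BranchAlignment:
    """Best-reference placement of one merged read."""

    read_id: str
    bp_pos: int
    cost: int
    branch_event: str           # 'match' | 'A>T' | 'indel'
    left_flank: int             # aligned nt at ref positions <= junction
    right_flank: int            # aligned nt at ref positions  > junction
    ref_start: int              # 0-based offset of the read in the reference
    indel: tuple[str, int, int] | None = None  # (kind, ref_pos, length)


def qc_filter_read(read: QualRead, max_lowq: int = 8, q_thresh: int = 10) -> bool:
    """True iff the read has fewer than ``max_lowq`` bases under ``q_thresh``."""
    return int(np.count_nonzero(read.phred < q_thresh)) < max_lowq


def merge_pairs(
    r1: QualRead,
    r2: QualRead,
    min_overlap: int = 20,
    max_mismatch: int = 15,
    min_merged_len: int = 195,
) -> QualRead | None:
    """Merge a read pair into the sequenced fragment, or None.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally.  The overlap is the longest suffix of r1 matching a prefix of
    revcomp(r2) with at most ``max_mismatch`` mismatches (longest wins; equal
    lengths cannot tie).  Disagreeing overlap positions take the
    higher-quality base (r1 on quality ties).  Merges shorter than
    ``min_merged_len`` are discarded.
    """
    s1 = _encode(r1.seq)
    s2 = _encode(r2.seq.translate(_COMPLEMENT))[::-1]
    q1, q2 = r1.phred, r2.phred[::-1]
    l1, l2 = len(s1), len(s2)
    for ov in range(min(l1, l2), min_overlap - 1, -1):
        a, b = s1[l1 - ov :], s2[:ov]
        if int(np.count_nonzero(a != b)) <= max_mismatch:
            qa, qb = q1[l1 - ov :], q2[:ov]
            take_b = qb > qa
            cons = np.where(take_b, b, a)
            cons_q = np.maximum(qa, qb)
            seq = (
                s1[: l1 - ov].tobytes() + cons.astype(np.uint8).tobytes() + s2[ov:].tobytes()
            ).decode()
            qual = np.concatenate([q1[: l1 - ov], cons_q, q2[ov:]])
            if len(seq) < min_merged_len:
                return None
            return QualRead(r1.id, seq, qual)
    return None


def build_lariat_reference(
    intron: IntronModel, bp_pos: int, up_len: int, down_len: int
) -> LariatReference:
    """Join the intron segment ending at the BP to the intron 5' start."""
    if up_len < 1 or down_len < 1:
        raise ValueError("up_len and down_len must be positive")
    if bp_pos < up_len:
        raise ValueError(f"bp_pos {bp_pos} < up_len {up_len}: upstream flank overruns the intron")
    if down_len > intron.length:
        raise ValueError(f"down_len {down_len} exceeds intron length {intron.length}")
    if not 1 <= bp_pos <= intron.length:
        raise ValueError(f"bp_pos {bp_pos} outside the intron")
    seq = intron.seq[bp_pos - up_len : bp_pos] + intron.seq[:down_len]
    return LariatReference(bp_pos, up_len, down_len, seq, junction_index=up_len)


# ---------------------------------------------------------------------------
# exact <=1-indel alignment


def _best_placement(r: np.ndarray, t: np.ndarray, pen: AlignPenalties, bound: float):
    """Exact minimum-cost placement of read r within reference t.

    The read is globally aligned (free reference ends) with at most one
    interior indel run.  Returns (cost, s, kind, k, i) with kind in
    {'none','del','ins'}; 'del' skips k reference bases after read split i,
    'ins' leaves k read bases unaligned after split i.  Ties resolve toward
    no indel, then smaller s, k, i.  Returns None if nothing beats ``bound``.
    """
    m, n = len(r), len(t)
    best = None  # (cost, kind_rank, s, k, i)

    def consider(cost, kind_rank, s, k, i):
        nonlocal best
        cand = (cost, kind_rank, s, k, i)
        if cost < bound and (best is None or cand < best):
            best = cand

    if m <= n:  # no-indel placements
        if m == n:
            consider(pen.mismatch * int(np.count_nonzero(r != t)), 0, 0, 0, 0)
        else:
            win = np.lib.stride_tricks.sliding_window_view(t, m)
            mm = np.count_nonzero(win != r, axis=1)
            s = int(mm.argmin())
            consider(pen.mismatch * int(mm[s]), 0, s, 0, 0)
            # keep the smallest offset among equal-cost placements
            for s2 in np.flatnonzero(mm == mm[s]):
                consider(pen.mismatch * int(mm[s2]), 0, int(s2), 0, 0)
                break

    ceiling = best[0] if best is not None else bound

    # deletion: read skips k reference bases between split i and i+1
    if m >= 2:
        for k in range(1, n - m + 1):
            if pen.gap_open + pen.gap_ext * k >= ceiling:
                break
            for s in range(0, n - m - k + 1):
                gap_cost = pen.gap_open + pen.gap_ext * k
                if gap_cost >= ceiling:
                    break
                aL = np.cumsum(r != t[s : s + m])            # prefix mism of left part
                right = r != t[s + k : s + k + m]
                aR = np.cumsum(right[::-1])[::-1]            # suffix mism incl. index i
                i_arr = np.arange(1, m)
                costs = gap_cost + pen.mismatch * (aL[i_arr - 1] + aR[i_arr])
                j = int(costs.argmin())
                consider(int(costs[j]), 1, s, k, int(i_arr[j]))
                ceiling = min(ceiling, best[0] if best else ceiling)

    # insertion: k read bases unaligned between reference positions s+i, s+i+1
    if m >= 3:
        for k in range(1, m - 1):
            if pen.gap_open + pen.gap_ext * k >= ceiling:
                break
            if m - k > n:
                continue
            for s in range(0, n - (m - k) + 1):
                gap_cost = pen.gap_open + pen.gap_ext * k
                if gap_cost >= ceiling:
                    break
                span = m - k
                aL = np.cumsum(r[:span] != t[s : s + span])
                right = r[k:] != t[s : s + span]             # index i compares r[i+k] vs t[s+i]
                aR = np.cumsum(right[::-1])[::-1]
                i_arr = np.arange(1, span)
                costs = gap_cost + pen.mismatch * (aL[i_arr - 1] + aR[i_arr])
                j = int(costs.argmin())
                consider(int(costs[j]), 2, s, k, int(i_arr[j]))
                ceiling = min(ceiling, best[0] if best else ceiling)

    if best is None:
        return None
    cost, kind_rank, s, k, i = best
    return cost, s, ("none", "del", "ins")[kind_rank], k, i


def _junction_details(m, s, kind, k, i, u):
    """Flank coverage and read index aligned at 1-based ref position u."""
    if kind == "none":
        left = min(max(u - s, 0), m)
        read_at = u - 1 - s if 0 <= u - 1 - s < m else None
    elif kind == "del":  # deleted ref interval: s+i+1 .. s+i+k
        left = min(max(u - s, 0), i) + min(max(u - (s + i + k), 0), m - i)
        if u <= s + i:
            read_at = u - 1 - s if u - 1 - s >= 0 else None
        elif u > s + i + k:
            read_at = u - 1 - s - k
        else:
            read_at = None  # junction base deleted
    else:  # ins: read bases i..i+k-1 sit between ref s+i and s+i+1
        span = m - k
        left = min(max(u - s, 0), span)
        if u - 1 - s < 0 or u - 1 - s >= span:
            read_at = None
        elif u - s <= i:
            read_at = u - 1 - s
        else:
            read_at = u - 1 - s + k
    aligned = m if kind != "ins" else m - k
    right = aligned - left
    return left, right, read_at


def placement_cost(read_seq: str, ref_seq: str, penalties: AlignPenalties | None = None) -> int | None:
    """Minimum edit cost of placing a read within a reference (<=1 indel).

    Free reference ends, the read fully aligned, at most one interior indel
    run; None when no placement exists.  Exposed for validation against
    exhaustive enumeration.
    """
    pen = penalties or AlignPenalties()
    res = _best_placement(_encode(read_seq), _encode(ref_seq), pen, np.inf)
    return None if res is None else res[0]


def _del_near_junction(ref_seq: str, pos: int, u: int) -> bool:
    """True if a 1-nt deletion at 1-based ``pos`` (or any sequence-equivalent
    placement within the same homopolymer run) touches the junction.

    A deletion inside a run of identical bases can be placed anywhere in the
    run at equal cost; the aligner reports the leftmost placement, so the
    whole run must be checked against the junction window {u-1, u, u+1}.
    """
    base = ref_seq[pos - 1]
    lo = hi = pos
    while lo > 1 and ref_seq[lo - 2] == base:
        lo -= 1
    while hi < len(ref_seq) and ref_seq[hi] == base:
        hi += 1
    return lo <= u + 1 and hi >= u - 1


def _ins_near_junction(ref_seq: str, ins_base: str, breakpoint: int, u: int) -> bool:
    """True if a 1-nt insertion after ref position ``breakpoint`` (or any
    equivalent placement sliding through matching reference bases) touches
    the junction window {u-1, u, u+1}."""
    lo = hi = breakpoint
    while lo > 0 and ref_seq[lo - 1] == ins_base:
        lo -= 1
    while hi < len(ref_seq) and ref_seq[hi] == ins_base:
        hi += 1
    return lo <= u + 1 and hi >= u - 1


def align_branch_read(
    read: QualRead,
    references: Sequence[LariatReference],
    penalties: AlignPenalties | None = None,
) -> BranchAlignment | None:
    """Assign a merged read to its best lariat-junction reference.

    The lowest-cost reference wins; cost ties break toward the smallest
    bp_pos.  The read must cover the junction with at least ``min_flank``
    aligned nt on each side, else None.  An A>T substitution or a 1-nt indel
    at the junction is recorded as the branch event.
    """
    if not references:
        raise ValueError("no references")
    u0 = references[0].up_len
    d0 = references[0].down_len
    for ref in references:
        if ref.up_len != u0 or ref.down_len != d0:
            raise ValueError("references must share up_len and down_len")
    pen = penalties or AlignPenalties()
    r = _encode(read.seq)
    m = len(r)

    best = None  # (cost, bp_pos, ref, placement)
    bound = np.inf
    # quick equal-length screen tightens the pruning bound before enumeration
    for ref in references:
        t = _encode(ref.seq)
        if len(t) == m:
            bound = min(bound, pen.mismatch * int(np.count_nonzero(r != t)) + 1)
    for ref in sorted(references, key=lambda x: x.bp_pos):
        t = _encode(ref.seq)
        placement = _best_placement(r, t, pen, bound)
        if placement is None:
            continue
        cost = placement[0]
        if best is None or cost < best[0]:
            best = (cost, ref.bp_pos, ref, placement)
            bound = min(bound, cost + 1)  # later refs must strictly beat it
    if best is None:
        return None
    cost, bp_pos, ref, (cost_, s, kind, k, i) = best
    u = ref.junction_index
    left, right, read_at = _junction_details(m, s, kind, k, i, u)
    if left < pen.min_flank or right < pen.min_flank:
        return None

    event = "match"
    indel = None
    if kind == "del":
        indel = ("del", s + i + 1, k)
        if k == 1 and _del_near_junction(ref.seq, s + i + 1, u):
            event = "indel"
    elif kind == "ins":
        indel = ("ins", s + i, k)
        if k == 1 and _ins_near_junction(ref.seq, chr(r[i]), s + i, u):
            event = "indel"
    if event == "match" and read_at is not None:
        if ref.seq[u - 1] == "A" and chr(r[read_at]) == "T":
            event = "A>T"
    return BranchAlignment(
        read_id=read.id,
        bp_pos=bp_pos,
        cost=cost,
        branch_event=event,
        left_flank=left,
        right_flank=right,
        ref_start=s,
        indel=indel,
    )


# ---------------------------------------------------------------------------
# usage tables and statistics


class UsageTable:
    """Counts of lariat-supporting reads per branch point per condition.

    Rows are conditions, columns are BP positions (dBP bins); fractions are
    per-row and sum to 1 wherever the row total is positive.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = counts

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence[int]], bins: Sequence[int]) -> "UsageTable":
        return cls(pd.DataFrame(data, index=list(bins)).T)

    def fractions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        frac = self.counts.div(totals.replace(0, np.nan), axis=0)
        return frac

    def pool(self, pooling: Mapping[int, int]) -> "UsageTable":
        """Merge columns, e.g. {41: 36} adds the dBP+41 bin into dBP+36."""
        counts = self.counts.copy()
        for src, dst in pooling.items():
            if src not in counts.columns or dst not in counts.columns:
                raise KeyError(f"pooling {src}->{dst}: unknown bin")
            counts[dst] = counts[dst] + counts[src]
            counts = counts.drop(columns=[src])
        return UsageTable(counts)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("condition").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "UsageTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(int)
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, UsageTable) and self.counts.equals(other.counts)


def quantify_usage(
    alignments: Mapping[str, Iterable[BranchAlignment | None]],
    bins: Sequence[int],
) -> UsageTable:
    """Tabulate aligned reads per BP bin for each condition.

    Reads that failed the junction-coverage rule (None) are excluded; an
    alignment to a BP outside ``bins`` raises.
    """
    bins = list(bins)
    data = {}
    for condition, alns in alignments.items():
        row = dict.fromkeys(bins, 0)
        for aln in alns:
            if aln is None:
                continue
            if aln.bp_pos not in row:
                raise ValueError(f"alignment to unknown bin {aln.bp_pos}")
            row[aln.bp_pos] += 1
        data[condition] = [row[b] for b in bins]
    return UsageTable.from_dict(data, bins)


def compare_usage(
    table: "UsageTable | pd.DataFrame",
    pooling: Mapping[int, int] | None = None,
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a usage table.

    Optional column pooling is applied first (the published 3x3 comparison
    pools the minor dBP+41 bin into dBP+36).  df = (rows-1)(cols-1).
    """
    if isinstance(table, pd.DataFrame):
        table = UsageTable(table)
    if pooling:
        table = table.pool(pooling)
    counts = table.counts.to_numpy()
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row or column total: chi-square undefined")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def compare_bin_fractions(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = True
) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test on replicate bin fractions.

    With ``welch`` the Welch-Satterthwaite df is used.  Two zero-variance
    groups with equal means give (0, df, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)
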