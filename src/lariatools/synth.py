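"""Seeded generators for every input class the analyses consume.

Each generator is a pure function of its arguments including the seed:
identical parameters give bit-identical output.  The generators emulate the
study conditions — an intron with a distant-BP cluster near the 5'ss, a long
U/C-rich polypyrimidine megatract and an AG-exclusion zone reaching the
3'ss; paired 150-nt lariat amplicon reads with the RT branch-crossing error
signature (A>T substitutions, 1-nt indels at the junction); hexamer
enhancer/silencer score tables with planted codon effects; Hill binding
curves; and paired modified/control probing lanes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .architecture import agez as _agez
from .architecture import scan_bp_motifs
from .lariat import LariatReference, UsageTable, build_lariat_reference
from .seqio import IntronModel, QualRead
from .splicecode import ALL_HEXAMERS, HexamerScoreTable
from .probing import hill_curve

import pandas as pd

__all__ = [
    "BranchErrorModel",
    "SimulatedLariatReads",
    "DEFAULT_MEGAPPT_COMPOSITION",
    "simulate_intron",
    "simulate_lariat_reads",
    "simulate_hexamer_table",
    "simulate_binding_curve",
    "simulate_reactivity",
    "simulate_usage_counts",
]

#: megaPPT base composition (DNA form; U==T): strongly U-rich, C next.
DEFAULT_MEGAPPT_COMPOSITION: Mapping[str, float] = {"T": 0.5, "C": 0.3, "G": 0.15, "A": 0.05}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BranchErrorModel:
    """RT branch-crossing and sequencing error rates for read simulation.

    The published experiments report the phenomenon (diagnostic A>T
    mismatches and small indels at the junction), not rates; the defaults
    are plausible working values and are configuration, not data.
    """

    p_sub: float = 0.3      # junction adenine read as T
    p_indel: float = 0.05   # 1-nt insertion/deletion at the junction
    seq_error: float = 0.002  # uniform per-base sequencing error

    def __post_init__(self) -> None:
        if not 0 <= self.p_sub + self.p_indel <= 1:
            raise ValueError("p_sub + p_indel must lie in [0, 1]")
        if not 0 <= self.seq_error < 1:
            raise ValueError("seq_error must lie in [0, 1)")


def _draw_bases(rng: np.random.Generator, n: int, composition: Mapping[str, float]) -> list[str]:
    bases = list(composition)
    probs = np.array([composition[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    return list(rng.choice(bases, size=n, p=probs))


def simulate_intron(
    length: int,
    dbp_positions: Sequence[int],
    megappt_composition: Mapping[str, float] | None = None,
    agez_target: int | None = None,
    seed: int = 0,
    max_tries: int = 50,
) -> IntronModel:
    """Generate a GT..AG intron with planted dBPs, megaPPT and AGEZ.

    TAA motifs are planted so their adenine sits at each requested dBP
    position; everything between the cluster and the 3'ss is drawn from the
    megaPPT composition.  No AG dinucleotide occurs within the last
    ``agez_target`` nucleotides except the terminal 3'ss AG; when the target
    is shorter than the intron an AG is placed at the zone boundary so the
    realised AGEZ equals the target, or — when the exact boundary falls
    inside a planted motif or the donor site — at the nearest feasible
    upstream position, making the realised AGEZ the smallest attainable
    value >= the target.  The result is self-checked with the scanner
    modules; infeasible constraints raise after ``max_tries`` attempts.
    """
    dbps = sorted(int(p) for p in dbp_positions)
    if agez_target is None:
        agez_target = length
    if not 1 <= agez_target <= length:
        raise ValueError("agez_target outside [1, length]")
    comp = dict(megappt_composition or DEFAULT_MEGAPPT_COMPOSITION)
    for p in dbps:
        if p < 5 or p > length - 2:
            raise ValueError(f"dBP position {p} leaves no room for GT..AG ends")
    for a, b in zip(dbps, dbps[1:]):
        if b - a < 3:
            raise ValueError("dBP positions closer than the 3-nt motif length")
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        arr = _draw_bases(rng, length, comp)
        arr[0], arr[1] = "G", "T"
        arr[-2], arr[-1] = "A", "G"
        protected = {1, 2, length - 1, length}  # positions repairs must not touch
        for p in dbps:
            arr[p - 3 : p] = ["T", "A", "A"]
            protected.update((p - 2, p - 1, p))
        boundary_g = length - agez_target  # ideal G of the nearest internal AG
        if agez_target < length:
            g = boundary_g
            while g >= 3 and ((g - 1) in protected or g in protected):
                g -= 1  # slide upstream out of planted motifs (AGEZ grows)
            if g < 3:
                raise ValueError(
                    f"no feasible AGEZ boundary at or upstream of position {boundary_g}"
                )
            arr[g - 2], arr[g - 1] = "A", "G"
            protected.update((g - 1, g))
            boundary_g = g
        # scrub AGs inside the exclusion zone (G position > boundary_g,
        # terminal AG excluded); replace the G with a pyrimidine.
        ok = True
        for gpos in range(max(boundary_g + 1, 2), length - 1):
            if arr[gpos - 2] == "A" and arr[gpos - 1] == "G":
                if gpos in protected or (gpos - 1) in protected:
                    ok = False
                    break
                arr[gpos - 1] = "C"
        if not ok:
            continue
        intron = IntronModel("".join(arr), dbps=list(dbps))
        res = _agez(intron)
        if agez_target < length:
            if res.agez_len != length - boundary_g:
                continue
        elif res.upstream_ag_pos is not None:
            continue
        found = {h.bp_pos for h in scan_bp_motifs(intron, {"TAA"})}
        if not set(dbps) <= found:
            continue
        return intron
    raise ValueError(
        f"could not satisfy intron constraints in {max_tries} attempts "
        f"(length={length}, dbps={dbps}, agez_target={agez_target})"
    )


def _apply_seq_errors(frag: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return frag
    hit = rng.random(len(frag)) < rate
    if not hit.any():
        return frag
    out = frag.copy()
    idx = np.flatnonzero(hit)
    shift = rng.integers(1, 4, size=len(idx))
    cur = np.searchsorted(_BASES, out[idx])
    out[idx] = _BASES[(cur + shift) % 4]
    return out


@dataclass
class SimulatedLariatReads:
    """Read pairs plus the ground truth and references they were drawn from."""

    pairs: list[tuple[QualRead, QualRead]]
    truth: list[int]                      # per-read dBP assignment
    references: list[LariatReference]     # shared up_len/down_len panel


def simulate_lariat_reads(
    intron: IntronModel,
    usage: Mapping[int, float],
    n_reads: int,
    error_model: BranchErrorModel | None = None,
    read_len: int = 150,
    up_len: int | None = None,
    down_len: int | None = None,
    base_quality: int = 36,
    seed: int = 0,
) -> SimulatedLariatReads:
    """Draw paired 150-nt reads from lariat junctions of the given intron.

    Each fragment is the lariat reference of a dBP sampled from ``usage``;
    at the junction the BP adenine becomes T with probability ``p_sub`` or
    gains a 1-nt indel with probability ``p_indel``.  Read 1 covers the
    fragment 5' end, read 2 the 3' end in sequencing orientation, with
    enough overlap for pair merging to reconstruct the fragment.  The
    reference panel used for the draw is returned so downstream alignment
    uses identical up_len/down_len.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    em = error_model or BranchErrorModel()
    bps = sorted(usage)
    probs = np.array([usage[b] for b in bps], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"usage probabilities sum to {probs.sum()}, expected 1")
    if up_len is None:
        up_len = min(bps)
    if down_len is None:
        down_len = min(intron.length, max(2 * read_len - 30 - up_len, read_len))
    refs = {b: build_lariat_reference(intron, b, up_len, down_len) for b in bps}
    frag_len = up_len + down_len
    if frag_len > 2 * read_len - 1:
        raise ValueError("fragment too long for overlapping read pairs")

    ref_arrays = {
        b: np.frombuffer(refs[b].seq.encode(), dtype=np.uint8).copy() for b in bps
    }
    comp = bytes.maketrans(b"ACGT", b"TGCA")
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(bps), size=n_reads, p=probs)
    event_draw = rng.random(n_reads)
    pairs: list[tuple[QualRead, QualRead]] = []
    truth: list[int] = []
    for i in range(n_reads):
        b = bps[choice[i]]
        frag = ref_arrays[b].copy()
        j = up_len - 1  # 0-based junction (BP base)
        if event_draw[i] < em.p_sub:
            frag[j] = ord("T")
        elif event_draw[i] < em.p_sub + em.p_indel:
            if rng.random() < 0.5:
                frag = np.delete(frag, j)
            else:
                frag = np.insert(frag, j + 1, rng.choice(_BASES))
        frag = _apply_seq_errors(frag, em.seq_error, rng)
        r1 = frag[:read_len]
        r2 = frag[-read_len:][::-1]
        r2 = np.frombuffer(r2.tobytes().translate(comp), dtype=np.uint8)
        qual = np.full(read_len, base_quality)
        pairs.append(
            (
                QualRead(f"read{i}/1", r1.tobytes().decode(), qual[: len(r1)]),
                QualRead(f"read{i}/2", r2.tobytes().decode(), qual[: len(r2)]),
            )
        )
        truth.append(b)
    return SimulatedLariatReads(pairs, truth, [refs[b] for b in bps])


def simulate_hexamer_table(
    planted: Mapping[str, float] | None = None,
    sd_noise: float = 0.2,
    thresholds: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> HexamerScoreTable:
    """All 4096 hexamers scored by planted codon effects plus Gaussian noise.

    A planted effect e for a trinucleotide adds +e to the enhancer score and
    -e to the silencer score of every hexamer containing it in any of its
    four overlapping windows (independent noise on each score).  Hexamers
    with enhancer score above ``thresholds[0]`` are labelled ESE, those with
    silencer score above ``thresholds[1]`` ESS (enhancer label wins when
    both qualify), the rest neutral.
    """
    planted = {k.upper().replace("U", "T"): float(v) for k, v in dict(planted or {}).items()}
    rng = np.random.default_rng(seed)
    effects = np.array(
        [
            sum(planted.get(h[i : i + 3], 0.0) for i in range(4))
            for h in ALL_HEXAMERS
        ]
    )
    ese = effects + rng.normal(0.0, sd_noise, len(ALL_HEXAMERS))
    ess = -effects + rng.normal(0.0, sd_noise, len(ALL_HEXAMERS))
    labels = np.where(ese > thresholds[0], "ESE", np.where(ess > thresholds[1], "ESS", "neutral"))
    return HexamerScoreTable(
        pd.DataFrame(
            {
                "hexamer": ALL_HEXAMERS,
                "ese_score": ese,
                "ess_score": ess,
                "label": labels,
            }
        )
    )


def simulate_binding_curve(
    b_max: float,
    k_d: float,
    n: float,
    concentrations: Sequence[float] = (0.0, 0.01, 0.03, 0.07, 0.15, 0.3, 0.6, 1.2),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """(L, B) points from the Hill isotherm with Gaussian noise, clipped to [0, 1].

    The default concentration series matches an EMSA titration ladder in uM.
    """
    if k_d <= 0 or n <= 0:
        raise ValueError("K_d and n must be positive")
    L = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    B = hill_curve(L, b_max, k_d, n)
    if noise_sd > 0:
        B = np.clip(B + rng.normal(0.0, noise_sd, len(L)), 0.0, 1.0)
    return np.column_stack([L, B])


def simulate_reactivity(
    structure: str,
    unpaired_boost: float = 3.0,
    noise_sd: float = 0.05,
    baseline: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (modified, control) lanes for a dot-bracket structure.

    The control lane is flat baseline plus noise; the modified lane is
    boosted ``unpaired_boost``-fold at unpaired ('.') positions.  Unbalanced
    brackets raise.
    """
    depth = 0
    for i, ch in enumerate(structure):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {i + 1}")
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if depth != 0:
        raise ValueError(f"{depth} unclosed '(' in structure")
    n = len(structure)
    if n == 0:
        raise ValueError("empty structure")
    rng = np.random.default_rng(seed)
    unpaired = np.array([ch == "." for ch in structure])
    control = np.clip(baseline + rng.normal(0.0, noise_sd, n), 0.0, None)
    modified = np.where(unpaired, baseline * unpaired_boost, baseline)
    modified = np.clip(modified + rng.normal(0.0, noise_sd, n), 0.0, None)
    return modified, control


def simulate_usage_counts(
    row_totals: Sequence[int],
    usage_vectors: Sequence[Sequence[float]],
    bins: Sequence[int],
    conditions: Sequence[str] | None = None,
    seed: int = 0,
) -> UsageTable:
    """Multinomial clone-count tables with the given per-condition usage."""
    if len(row_totals) != len(usage_vectors):
        raise ValueError("row_totals and usage_vectors must have equal length")
    rng = np.random.default_rng(seed)
    rows = {}
    conditions = list(conditions or (f"condition_{i + 1}" for i in range(len(row_totals))))
    for name, total, u in zip(conditions, row_totals, usage_vectors):
        u = np.asarray(u, dtype=float)
        if not np.isclose(u.sum(), 1.0):
            raise ValueError(f"usage vector for {name} sums to {u.sum()}")
        rows[name] = rng.multinomial(total, u)
    return UsageTable.from_dict(rows, bins)
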