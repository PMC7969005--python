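"""Codon-level analysis of exonic splicing enhancers/silencers and metals.

Exonic splicing enhancer (ESE) and silencer (ESS) hexamers carry quantitative
ESEseq/ESSseq activity scores.  Every hexamer contains exactly four
overlapping trinucleotide windows (positions 1-3, 2-4, 3-5, 4-6); counting
codons over all four windows is the single most important convention in this
module — it is what makes an ESE set of 1182 hexamers contribute 4x1182 =
4728 codon observations, and an ESS set of 1090 contribute 4360.

Per-codon fold excesses (ESE frequency over ESS frequency) and their natural
log ratios rank codons by splicing-regulatory strength.  Weighting
per-amino-acid log ratios by the residue frequencies of metal-ion binding
sites yields a per-metal gradient that can be compared against the
Irving-Williams stability series Mg/Ca < Mn < Fe < Co < Ni < Cu/Zn.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .seqio import NucSeq, as_dna

__all__ = [
    "HexamerScoreTable",
    "CodonCountTable",
    "MetalResidueFrequencies",
    "GradientResult",
    "ALL_CODONS",
    "ALL_HEXAMERS",
    "STOP_CODONS",
    "IRVING_WILLIAMS_SERIES",
    "standard_genetic_code",
    "codon_counts",
    "fold_excess",
    "rank_codons",
    "aa_log_ratio",
    "metal_gradient",
    "preference_index",
    "window_score",
]

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)
ALL_HEXAMERS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=6)
)
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Stability order of divalent first-row metal complexes (weak -> tight).
IRVING_WILLIAMS_SERIES: tuple[str, ...] = ("Mg", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn")


def standard_genetic_code() -> dict[str, str]:
    """Codon -> one-letter amino acid ('*' for stops), standard table."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


class HexamerScoreTable:
    """4096-row table of hexamer ESEseq/ESSseq scores and set labels."""

    def __init__(self, df: pd.DataFrame):
        required = {"hexamer", "ese_score", "ess_score", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if df["hexamer"].duplicated().any():
            raise ValueError("duplicate hexamers")
        if len(df) > 4096:
            raise ValueError("more than 4096 hexamers")
        bad = ~df["label"].isin(["ESE", "ESS", "neutral"])
        if bad.any():
            raise ValueError(f"unknown labels: {sorted(df.loc[bad, 'label'].unique())}")
        for h in df["hexamer"]:
            if len(h) != 6 or set(h) - set("ACGT"):
                raise ValueError(f"not a DNA hexamer: {h!r}")
        self.df = df.reset_index(drop=True)

    def hexamers(self, label: str) -> set[str]:
        return set(self.df.loc[self.df["label"] == label, "hexamer"])

    def score_map(self) -> dict[str, tuple[float, float]]:
        return {
            h: (e, s)
            for h, e, s in zip(self.df["hexamer"], self.df["ese_score"], self.df["ess_score"])
        }

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HexamerScoreTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class CodonCountTable:
    """Codon counts over a hexamer set; total == 4 x number of hexamers."""

    counts: Mapping[str, int]
    total: int
    set_label: str = ""

    def __post_init__(self) -> None:
        full = dict.fromkeys(ALL_CODONS, 0)
        for codon, n in dict(self.counts).items():
            codon = as_dna(codon)
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError("negative count")
            full[codon] = int(n)
        self.counts = full
        if self.total <= 0:
            raise ValueError("total must be positive")

    def frequency(self, codon: str) -> float:
        return self.counts[codon] / self.total


@dataclass
class MetalResidueFrequencies:
    """Per-metal amino-acid frequencies at metal-binding sites.

    Frequencies are renormalised to sum to 1 over the residues available for
    each metal before any weighting.  ``source`` tags the provenance
    (fragment-transformation | MetalPDB | synthetic).
    """

    freqs: Mapping[str, Mapping[str, float]]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        norm: dict[str, dict[str, float]] = {}
        for metal, aa_freqs in dict(self.freqs).items():
            aa_freqs = {aa: float(f) for aa, f in dict(aa_freqs).items()}
            if any(f < 0 for f in aa_freqs.values()):
                raise ValueError(f"negative frequency for {metal}")
            total = sum(aa_freqs.values())
            if total <= 0:
                raise ValueError(f"no residue mass for {metal}")
            norm[metal] = {aa: f / total for aa, f in aa_freqs.items()}
        self.freqs = norm

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "MetalResidueFrequencies":
        df = pd.read_csv(path, sep="\t")
        freqs: dict[str, dict[str, float]] = {}
        for metal, sub in df.groupby("metal"):
            freqs[str(metal)] = dict(zip(sub["aa"], sub["freq"]))
        return cls(freqs, source=source or "table")


@dataclass
class GradientResult:
    """Per-metal weighted log-ratio averages and their rank correlation."""

    averages: "pd.Series"        # indexed by metal in series order
    spearman_rho: float
    spearman_p: float
    aa_log_ratios: Mapping[str, float] = field(default_factory=dict)


def codon_counts(hexamers: Iterable[str], set_label: str = "") -> CodonCountTable:
    """Count the four overlapping trinucleotide windows of every hexamer."""
    counts = dict.fromkeys(ALL_CODONS, 0)
    n_hex = 0
    for h in hexamers:
        h = as_dna(h)
        if len(h) != 6 or set(h) - set("ACGT"):
            raise ValueError(f"not a DNA hexamer: {h!r}")
        n_hex += 1
        for i in range(4):
            counts[h[i : i + 3]] += 1
    if n_hex == 0:
        raise ValueError("empty hexamer set")
    return CodonCountTable(counts, total=4 * n_hex, set_label=set_label)


def fold_excess(
    counts_ese: CodonCountTable, counts_ess: CodonCountTable, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-codon ESE/ESS fold excess and natural-log ratio.

    fold = (n_ese/total_ese) / (n_ess/total_ess), reported raw (inf when the
    ESS count is zero, flagged).  The log ratio adds ``pseudocount`` to both
    counts only when either count is zero.
    """
    rows = []
    for codon in ALL_CODONS:
        ne, ns = counts_ese.counts[codon], counts_ess.counts[codon]
        fe = counts_ese.frequency(codon)
        fs = counts_ess.frequency(codon)
        if ns == 0:
            fold = np.inf if ne > 0 else np.nan
        else:
            fold = fe / fs
        if ne == 0 or ns == 0:
            log_ratio = float(
                np.log(
                    ((ne + pseudocount) / counts_ese.total)
                    / ((ns + pseudocount) / counts_ess.total)
                )
            )
            flagged = True
        else:
            log_ratio = float(np.log(fold))
            flagged = False
        rows.append(
            {
                "codon": codon,
                "n_ese": ne,
                "n_ess": ns,
                "fold": fold,
                "log_ratio": log_ratio,
                "pseudocounted": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def rank_codons(log_ratios: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """All 64 codons ranked by descending log ratio; stop codons flagged.

    Ties break alphabetically for a deterministic order.
    """
    s = pd.Series(dict(log_ratios))
    if len(s) != 64 or set(s.index) != set(ALL_CODONS):
        raise ValueError("expected log ratios for all 64 codons")
    df = s.rename("log_ratio").rename_axis("codon").reset_index()
    df = df.sort_values(["log_ratio", "codon"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, 65)
    df["is_stop"] = df["codon"].isin(STOP_CODONS)
    return df


def aa_log_ratio(
    counts_ese: CodonCountTable,
    counts_ess: CodonCountTable,
    genetic_code: Mapping[str, str] | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-amino-acid ESE/ESS ratio, synonymous counts summed before dividing.

    Stop codons are excluded.  Returns ratio and log_ratio per residue
    (one-letter codes); a single-codon residue equals that codon's ratio.
    """
    code = dict(genetic_code) if genetic_code is not None else standard_genetic_code()
    by_aa: dict[str, list[str]] = {}
    for codon, aa in code.items():
        if aa == "*":
            continue
        by_aa.setdefault(aa, []).append(codon)
    rows = []
    for aa, codons in sorted(by_aa.items()):
        ne = sum(counts_ese.counts[c] for c in codons)
        ns = sum(counts_ess.counts[c] for c in codons)
        if ne == 0 or ns == 0:
            ne_, ns_ = ne + pseudocount, ns + pseudocount
            flagged = True
        else:
            ne_, ns_ = ne, ns
            flagged = False
        ratio = (ne_ / counts_ese.total) / (ns_ / counts_ess.total)
        rows.append(
            {
                "aa": aa,
                "n_ese": ne,
                "n_ess": ns,
                "ratio": ratio,
                "log_ratio": float(np.log(ratio)),
                "pseudocounted": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("aa")


def metal_gradient(
    aa_log_ratios: Mapping[str, float] | pd.Series,
    freqs: MetalResidueFrequencies,
    series_order: Sequence[str] = IRVING_WILLIAMS_SERIES,
) -> GradientResult:
    """Residue-frequency-weighted log-ratio average per metal.

    For each metal the weights are renormalised over the residues present in
    both the frequency table and the log-ratio table; the Spearman rank
    correlation of the averages against the series position is reported
    (negative when enhancer-leaning residues bind the weak end of the
    series, as for Ca/Mg-coordinating aspartate).
    """
    ratios = dict(pd.Series(dict(aa_log_ratios)))
    averages = {}
    for metal in series_order:
        if metal not in freqs.freqs:
            raise KeyError(f"no residue frequencies for metal {metal!r}")
        w = {aa: f for aa, f in freqs.freqs[metal].items() if aa in ratios}
        total = sum(w.values())
        if total == 0:
            raise ValueError(f"no residue overlap for metal {metal!r}")
        averages[metal] = sum(f / total * ratios[aa] for aa, f in w.items())
    avg = pd.Series(averages).loc[list(series_order)]
    if np.allclose(avg, avg.iloc[0]):
        rho, p = np.nan, np.nan  # constant averages carry no rank signal
    else:
        rho, p = stats.spearmanr(np.arange(len(series_order)), avg.to_numpy())
    return GradientResult(avg, float(rho), float(p), aa_log_ratios=ratios)


def _aa_frequencies(hexamers: Sequence[str], code: Mapping[str, str]) -> dict[str, float]:
    """Amino-acid frequencies over the two in-frame codons, stops excluded."""
    counts: dict[str, int] = {}
    total = 0
    for h in hexamers:
        for codon in (h[:3], h[3:]):
            aa = code[codon]
            if aa == "*":
                continue
            counts[aa] = counts.get(aa, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {aa: n / total for aa, n in counts.items()}


def preference_index(
    tested_hexamers: Sequence[str],
    pool: Sequence[str],
    codon_usage: Mapping[str, float],
    n_random: int = 1000,
    seed: int = 0,
    genetic_code: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hexamer preference index per amino acid.

    index(aa) = (f_tested(aa) - mean f_random(aa)) / sd f_random(aa), where
    the ``n_random`` same-size randomised sets are drawn from ``pool`` with
    hexamer weights proportional to the product of the in-frame codon-usage
    probabilities (hexamers with an in-frame stop get weight 0), so the null
    reflects genomic codon usage.  A zero null sd leaves the index undefined
    (NaN, flagged).
    """
    if n_random < 2:
        raise ValueError("n_random must be >=2 (sd undefined otherwise)")
    code = dict(genetic_code) if genetic_code is not None else standard_genetic_code()
    pool = list(pool)
    tested = list(tested_hexamers)
    pool_set = set(pool)
    for h in tested:
        if h not in pool_set:
            raise ValueError(f"tested hexamer {h!r} not in pool")
    usage = {c: float(v) for c, v in dict(codon_usage).items()}
    weights = np.array(
        [usage.get(h[:3], 0.0) * usage.get(h[3:], 0.0) for h in pool], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("codon usage gives zero weight to the whole pool")
    weights = weights / weights.sum()

    f_tested = _aa_frequencies(tested, code)
    aas = sorted({aa for aa in code.values() if aa != "*"})
    rng = np.random.default_rng(seed)
    samples = np.zeros((n_random, len(aas)))
    pool_arr = np.array(pool)
    for r in range(n_random):
        draw = rng.choice(pool_arr, size=len(tested), replace=False, p=weights)
        f = _aa_frequencies(list(draw), code)
        samples[r] = [f.get(aa, 0.0) for aa in aas]
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    rows = []
    for j, aa in enumerate(aas):
        ft = f_tested.get(aa, 0.0)
        undefined = sd[j] == 0
        rows.append(
            {
                "aa": aa,
                "f_tested": ft,
                "f_random_mean": mean[j],
                "f_random_sd": sd[j],
                "index": np.nan if undefined else (ft - mean[j]) / sd[j],
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows).set_index("aa")


def window_score(
    seq: "str | NucSeq",
    center_start: int,
    center_end: int,
    table: HexamerScoreTable,
    window: int = 25,
) -> float:
    """Mean ESEseq/ESSseq score ratio of all hexamers in a motif-centred window.

    The ``window``-nt segment is centred on the midpoint of the 1-based
    inclusive motif span and truncated at the sequence ends; all
    ``len(segment) - 5`` hexamers are scored.
    """
    s = as_dna(str(seq))
    if window < 6:
        raise ValueError("window must be at least 6 nt")
    if not 1 <= center_start <= center_end <= len(s):
        raise ValueError("motif span outside the sequence")
    mid = (center_start + center_end) // 2
    half = window // 2
    start = max(1, mid - half)
    end = min(len(s), start + window - 1)
    start = max(1, end - window + 1)  # re-anchor if truncated on the right
    segment = s[start - 1 : end]
    if len(segment) < 6:
        raise ValueError(f"segment shorter than 6 nt ({len(segment)})")
    scores = table.score_map()
    ratios = []
    for i in range(len(segment) - 5):
        h = segment[i : i + 6]
        if h not in scores:
            raise KeyError(f"hexamer {h} missing from the score table")
        e, sscore = scores[h]
        ratios.append(e / sscore)
    return float(np.mean(ratios))
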