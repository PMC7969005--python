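# lariatools

Analyses of how a pair of mutually exclusive exons (MXEs) is kept mutually
exclusive by the architecture of the short intron between them — the case
studied here is the calcium-sensitive/insensitive isoform switch of *OGDH*,
the E1 subunit of the 2-oxoglutarate dehydrogenase complex.  The package is
aimed at splicing and regulatory-genomics researchers who want to rerun,
test or extend three linked computational analyses:

1. **Distant branch-point (dBP) mapping from lariat amplicon sequencing.**
   Reverse transcription across the 2′–5′ branch of an intron lariat yields
   cDNAs in which the intron segment ending at the branch-point adenine is
   joined to the intron 5′ end.  Paired 150-nt reads are merged (≥20 nt
   overlap, ≤15 overlap mismatches, merged length ≥195 nt), aligned to
   synthetic junction references with at most one indel (gap open 11,
   extension/mismatch 4), and tabulated per dBP.  Diagnostic A>T
   substitutions and 1-nt indels at the junction — the RT's signature of a
   genuine branch — are classified, not penalised away.  Usage tables are
   compared with Pearson χ² contingency tests and t-tests on replicate bin
   fractions.

2. **3′ splice-site architecture.** Branch-point motif scanning (URA
   trinucleotides ending in the BP adenine), the strict <50-nt steric rule
   that defines a *distant* BP, hydrogen-bond scoring of the U2
   snRNA:branch-point duplex (GUAGUA box, BP adenine bulged; G:C=3,
   A:U=2, G:U=2), the AG-exclusion zone (AGEZ), and windowed UC-/UU-/UG-rich
   segmentation of the polypyrimidine megatract.

3. **The codon-level splicing code and the metallome.** Codon counting over
   the four overlapping trinucleotide windows of splicing enhancer/silencer
   (ESE/ESS) hexamers, per-codon fold excesses
   `(n_ESE/N_ESE)/(n_ESS/N_ESS)` and log ratios, per-amino-acid
   aggregation, residue-frequency-weighted averages per metal, and their
   rank correlation against the Irving–Williams affinity series
   Mg²⁺/Ca²⁺ < Mn²⁺ < Fe²⁺ < Co²⁺ < Ni²⁺ < Cu²⁺/Zn²⁺.  Chemical-probing
   reactivity profiles and Hill binding fits
   (`B = B_max·Lⁿ/(Lⁿ + K_dⁿ)`) support the structural side of the
   analysis.

A seeded synthetic-data module (`lariatools.synth`) generates every input
class — introns with planted dBP clusters and AGEZs, lariat read pairs with
the RT error model, hexamer score tables with planted codon effects,
binding curves and probing lanes — so the whole pipeline is testable
without downloads.  `lariatools.study_data` carries the published clone and
codon count tables the statistics are recomputed from.

## Worked example

```python
from lariatools import lariat, study_data, synth

# simulate a lariat amplicon experiment with the human dBP layout
intron = synth.simulate_intron(260, (25, 31, 36, 41), agez_target=200, seed=7)
sim = synth.simulate_lariat_reads(
    intron, {25: 0.35, 31: 0.38, 36: 0.24, 41: 0.03}, n_reads=4000, seed=11
)
merged = (lariat.merge_pairs(r1, r2) for r1, r2 in sim.pairs)
alns = [lariat.align_branch_read(m, sim.references) for m in merged if m]
table = lariat.quantify_usage({"sim": alns}, [r.bp_pos for r in sim.references])
print(table.fractions().round(3))

chi2, df, p = lariat.compare_usage(study_data.human_usage_table())
print(f"chi2 = {chi2:.2f}, df = {df}, p = {p:.2f}")
```

prints

```
       25     31     36     41
sim  0.354  0.388  0.232  0.025
chi2 = 7.11, df = 6, p = 0.31
```

— the recovered usage fractions match the generating vector to within
binomial noise, and the three-condition human clone-count table gives
χ² = 7.11 on 6 degrees of freedom (p = 0.31): the relative usage of the
four dBPs is insensitive to depleting TIA-1/TIAR or overexpressing PUF60.

The numbered drivers under `analysis/` run the same steps as narrative
scripts (simulate → quantify → architecture → splicing code → probing) and
write their tables under `results/`.

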