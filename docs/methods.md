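# Methods

## Coordinates and sequence model

All intronic coordinates are 1-based and inclusive; position 1 is the first
intron nucleotide (the G of the GT donor).  A distant branch point written
"dBP+N" is the adenine at intron position N.  The distance from position N
to the 3′ splice site is `length − N + 1`, so a branch point at 25 in a
131-nt intron is 107 nt from the acceptor.  The internal canonical alphabet
is DNA (U is folded into T on input); every scanner is invariant under the
DNA/RNA form of the same sequence.  FASTQ qualities are phred+33.

## Lariat amplicon pipeline

A lariat reference for branch point *b* is
`intron[b−up+1 .. b] ++ intron[1 .. down]`, the junction (the BP base
itself) at index `up`.  All references in a panel share `up`/`down` so
alignment costs are comparable across branch points.

Read processing applies the published pipeline constants as defaults: a
read passes QC when it has fewer than 8 bases under phred 10; pairs merge at
the longest overlap ≥20 nt with ≤15 mismatches (disagreements resolved to
the higher-quality base, ties to read 1); merged reads shorter than 195 nt
are discarded; alignment allows a single indel with gap-open 11 and
extension/mismatch penalties of 4.  A 1-nt indel therefore costs 15 — the
open penalty plus one extension; whether the first gapped base pays
extension is a convention, exposed through `AlignPenalties`.

The aligner enumerates every placement of the read inside a reference with
free reference ends and at most one interior indel run, using prefix-sum
mismatch counts and a cost ceiling that prunes indel lengths which cannot
beat the current best.  This makes the reported cost *exactly* the optimum
over the ≤1-indel alignment space (the test suite checks equality against
an independent brute-force enumeration), while staying fast enough for
40 000-read studies (~0.1 ms per read).  Cost ties across references break
toward the smallest branch-point position; within a reference, toward no
indel, then the smallest offset, indel length and split point — output is
deterministic.

A read counts toward a branch point only when it covers the junction with
at least 5 aligned nt on each side (`min_flank`, a configuration key: the
published pipeline does not state a value).  Branch events are classified
at the junction: an A read as T is the RT's diagnostic substitution; a 1-nt
indel touching the junction window {u−1, u, u+1} is the RT's slippage
signature.  Because an indel inside a homopolymer run can be placed
anywhere in the run at equal cost and the aligner reports the leftmost
placement, classification checks every sequence-equivalent placement of the
indel against the junction window.

Usage tables are compared with the Pearson chi-square without continuity
correction, df = (rows−1)(columns−1).  The published pooled comparison
("without dBP+41") is implemented as pooling the dBP+41 column *into*
dBP+36 — this reproduces the printed 3×3 statistic (3.59), whereas dropping
the column does not.  Replicate bin fractions are compared with unpaired
two-tailed t-tests, optionally with the Welch–Satterthwaite df.

## Splice-site architecture

Branch-point motifs are trinucleotides ending in the BP adenine (UAA
optimal; UUA/UGA/UCA suboptimal; non-A branch nucleotides such as the
putative low-usage uridine class require an explicit flag).  A hit is a
*distant* BP when its 5′ss distance is strictly below the steric threshold
(default 50 nt — "below ~50 nt" is read as a strict inequality).

U2:BP duplex strength is the hydrogen-bond count over the canonical
register: intron positions −5..−1 and +1 pair antiparallel with the 6-nt
GUAGUA box and the BP adenine is bulged, never paired.  The bond table is
G:C = 3, A:U = 2, G:U wobble = 2, otherwise 0 (configurable).  The yeast
consensus UACUAAC scores 14 (2+2+3+2+2+3).  An *extended* U2 segment can be
supplied to score the extended register — bases 5′ of the box pair intron
positions +2, +3, …, bases 3′ of it pair −6, −7, … — but has no default:
the extended segment and shifted-register conventions differ between
preparations, so it is a required configuration value.

The AG-exclusion zone is measured to the G of the internal AG nearest the
acceptor (the terminal 3′ss AG excluded from the search); with no internal
AG the whole intron is the zone, which keeps the degenerate case
well-defined.  PPT segmentation slides a 10-nt window in steps of 1 and
labels a window UU-rich when the U fraction alone exceeds 0.6, UC- or
UG-rich when the joint fraction exceeds 0.6 with each base above 0.2
(priority UU > UC > UG; thresholds are configuration keys — the qualitative
"UC-/UU-/UG-rich" description is not quantified in the source analyses).
Adjacent same-label windows merge into segments; different labels may
overlap by up to window−1 nt, reflecting windowed calls.

Motif densities count overlapping occurrences.  The variant engine applies
substitutions, insertions and deletions right-to-left so stated coordinates
stay valid, and refuses reference-base mismatches to guard against
coordinate drift.

## Splicing code and metal gradients

The single most important convention in the codon analysis: every hexamer
contributes its **four overlapping trinucleotide windows** (positions 1–3,
2–4, 3–5, 4–6).  This is forced by the published window totals — 1182
enhancer hexamers give 4728 = 4×1182 codon observations and 1090 silencer
hexamers give 4360.

Fold excess is the ratio of frequencies,
`(n_ESE/4728)/(n_ESS/4360)`, reported raw (infinite when the silencer count
is zero, flagged).  Natural-log ratios add a pseudocount of 0.5 to both
counts only when either count is zero — several silencer counts are single
digits, and the raw fold is what the published table prints.  Amino-acid
ratios sum synonymous codon counts before dividing (whether codon-usage
weighting applies at this step is an open convention; summation is the
default strategy), and exclude stop codons.

Metal gradients weight per-amino-acid log ratios by metal-binding residue
frequencies, renormalised over the residues present in both tables, and
report the Spearman correlation of the per-metal averages against the
position in the Irving–Williams series (Mg, Ca, Mn, Fe, Co, Ni, Cu, Zn;
the Cu/Zn order is configurable since their complex stabilities flip in
some compilations).  Perfect recovery of the planted arrangement is −1:
averages fall from the weak to the tight end of the series.

The hexamer preference index draws `n_random` same-size sets from the
hexamer pool with weights proportional to the product of the two in-frame
codon-usage probabilities (hexamers with an in-frame stop get weight 0) and
reports `(f_tested − mean f_random)/sd f_random` per amino acid.  The
original randomisation scheme is not fully specified; in-frame weighting is
this package's choice, and a zero null sd flags the index as undefined
rather than inventing a value.

Windowed scoring centres a 25-nt segment (configurable) on the midpoint of
a motif, truncates at sequence ends, scores all `len − 5` hexamers and
returns the mean ESEseq/ESSseq score ratio.

## Probing and binding

Reactivity is `normalize(modified) − normalize(control)` after unit-total
lane scaling (an outlier-robust top-10%-after-top-2% rule is available as a
flag).  The subtraction direction is exposed as a flag because the
prose description of the published protocol reads as control-minus-modified,
which would invert standard practice; the default here is
modified − control (positive = flexible/unpaired).  An optional floor
(e.g. −1) clips values for display only.

Hill fits minimise squared error over `B = B_max·Lⁿ/(Lⁿ + K_dⁿ)` with a
deterministic coarse log-grid over (K_d, n) — B_max solved linearly at each
node, clamped to (0, 1.2] to allow calibration slack above a bound fraction
of 1 — followed by local least-squares refinement.  The grid avoids the
initialisation sensitivity of a single local optimiser; grid bounds default
to [L_min/10, L_max·10] and are configuration keys.  On the 8-point EMSA
concentration ladder with 5% Gaussian noise the median relative K_d error
is ~0.11, which is noise-limited: an optimiser started at the true
parameters achieves the same error.

Pearson correlations report the classical regression F-test p on n−2 df
(identical to the two-sided t-test with `t = r·√((n−2)/(1−r²))`); binomial
tests are exact tail sums.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their arguments including the seed.

*Introns* are built GT..AG with TAA motifs planted at the requested dBP
positions, the downstream region drawn from a megaPPT composition (default
U 0.5 / C 0.3 / G 0.15 / A 0.05), and no AG inside the requested exclusion
zone.  When feasible an AG is placed exactly at the zone boundary so the
realised AGEZ equals the target; when the boundary falls inside a planted
motif (as for the human layout, where position 41 is a dBP adenine) the AG
slides to the nearest feasible upstream position and the realised AGEZ is
the smallest attainable value ≥ the target.  Every simulated intron is
self-checked with the package's own scanners before being returned.

*Lariat reads* sample a branch point from the usage vector, copy its
junction reference, apply the RT branch-crossing error (A→T with
probability 0.3, a 1-nt indel with probability 0.05 — plausible working
rates for the reported phenomenon, not measured values; configuration
keys), add uniform sequencing error (0.2%), and emit overlapping 150-nt
pairs so merging reconstructs the fragment.  Real libraries additionally
carry position-dependent quality decay, PCR duplicates and adapter
artefacts, none of which are modelled — recovery results on synthetic reads
therefore demonstrate correctness of the pipeline arithmetic, not
robustness to every failure mode of real sequencing.

The end-to-end recovery study uses a 260-nt synthetic intron carrying the
human dBP layout (25/31/36/41).  A 131-nt intron — the natural human
size — cannot yield lariat amplicons passing the 195-nt merged-length
filter (the maximal junction fragment is bp_pos + length ≈ 156 nt), because
the real amplicons extend into vector/minigene sequence absent from a bare
intron model; lengthening the simulated intron reproduces the fragment
geometry the filter assumes while preserving the cluster layout.

*Hexamer tables* give every one of the 4096 hexamers an enhancer and a
silencer score: a planted codon effect e adds +e to the enhancer score and
−e to the silencer score of every hexamer containing that trinucleotide in
any of its four windows, plus independent Gaussian noise; labels come from
symmetric score thresholds.  This is a planted-effect construction for
recovery testing, not a generative model of the published score
distributions.

*Binding curves* add clipped Gaussian noise to the Hill isotherm at the
EMSA titration ladder (0, 0.01, 0.03, 0.07, 0.15, 0.3, 0.6, 1.2 µM).
*Probing lanes* boost unpaired (dot) positions of a dot-bracket structure
by a constant factor over a flat baseline — no transcript-position decay,
no band compression.

*Usage count tables* are per-condition multinomial draws, which is exactly
the null of the chi-square comparison; the type-I calibration study uses
the published human row totals (39/43/50 informative clones) and the
published marginal usage vector, dropping the occasional all-zero dBP+41
column before testing because the chi-square contract requires positive
margins (the rate stays at the nominal 5% within ±2 points).

## Problem sizes of the recomputation studies

The bundled studies use 40 000 simulated read pairs for usage recovery,
1 000 null tables for calibration, 100 titrations for Hill recovery, 60
random read/reference cases for aligner-oracle agreement and 500 random
introns for the AGEZ oracle — sizes at which the binomial error bands are
narrow relative to the tested tolerances while a full rerun stays fast on a
laptop.

## Known limitations

- The aligner is specialised for short amplicon panels (free reference
  ends, one indel run); it is not a general read mapper.
- Shifted or non-canonical U2 pairing registers are out of scope; only the
  bulged-adenine canonical register is scored, plus a user-supplied
  extended segment.
- SVM-based branch-point scores, partition-function accessibility values
  and probing-guided structure prediction are external inputs where needed,
  never recomputed.
- The chicken-vs-human "all clones" 2×4 comparison is reported by
  `compare_usage` as Pearson χ² = 101.97 on the printed counts; the
  published companion value for that comparison is not reproducible by a
  Pearson or continuity-corrected statistic and is excluded from the
  recomputed headline set (the controls-only comparison, which does
  reproduce, is included).
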