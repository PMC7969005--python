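#!/usr/bin/env python
"""Characterise the 3' splice-site architecture of the synthetic intron.

On the intron written by 01_simulate_lariat_dataset.py: scans for
branch-point motifs and flags distant BPs by the ~50-nt steric rule, scores
U2 snRNA:BP duplex hydrogen bonds per hit, measures the AG-exclusion zone,
profiles the megaPPT into UC-/UU-/UG-rich segments, and reports the density
of BP-like URA motifs (the statistic used to gauge how readily transposon
sequence can supply spurious branch points).
"""

import argparse
from pathlib import Path

import pandas as pd

from lariatools.architecture import agez, enumerate_dbp_candidates, motif_density, ppt_profile
from lariatools.seqio import IntronModel, read_fasta, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    (_, seq), = read_fasta(args.out_dir / "intron.fa")
    intron = IntronModel(str(seq))

    hits = enumerate_dbp_candidates(intron)
    hits_df = pd.DataFrame(
        [
            {
                "bp_pos": h.bp_pos, "motif": h.motif3, "dist_5ss": h.dist_5ss,
                "dist_3ss": h.dist_3ss, "hbond_core": h.hbond_core, "is_dbp": h.is_dbp,
            }
            for h in hits
        ]
    )
    write_table(hits_df, args.out_dir / "branch_point_hits.tsv")

    zone = agez(intron)
    prof = ppt_profile(intron.seq[max(zone.upstream_ag_pos or 1, 1) :], window_len=10)
    segs = pd.DataFrame(prof.segments, columns=["label", "start", "end"])
    write_table(segs, args.out_dir / "ppt_segments.tsv")
    count, density = motif_density(intron.seq, {"TAA", "TGA"})

    n_dbp = int(hits_df["is_dbp"].sum())
    print(f"{len(hits)} BP motif hits, {n_dbp} below the 50-nt steric threshold (dBPs)")
    print(hits_df[hits_df["is_dbp"]].to_string(index=False))
    print(f"\nAGEZ: {zone.agez_len} nt (nearest internal AG ends at {zone.upstream_ag_pos})")
    print(f"PPT segments downstream of the AG boundary: {len(segs)}")
    print(segs.head(10).to_string(index=False))
    print(f"\nURA motif density: {count} motifs, one per {1/density:.0f} nt "
          f"({100*density:.1f}%)")


if __name__ == "__main__":
    main()
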