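#!/usr/bin/env python
"""Chemical-probing reactivities and EMSA Hill fits on synthetic data.

Simulates paired modified/control lanes for a hairpin that displays two
branch-point adenines in its terminal loop, computes the difference
reactivity profile, and runs the Hill-fit recovery study over noisy
synthetic titrations at the EMSA concentration ladder.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lariatools.probing import hill_fit, reactivity
from lariatools.seqio import write_table
from lariatools.studies import hill_recovery_study
from lariatools.synth import simulate_binding_curve, simulate_reactivity


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    # hairpin with an 8-nt terminal loop (dBP adenines exposed in the loop)
    structure = "((((((((........))))))))"
    mod, ctrl = simulate_reactivity(structure, unpaired_boost=3.0, noise_sd=0.05, seed=args.seed)
    r = reactivity(mod, ctrl)
    write_table(
        pd.DataFrame({"pos": np.arange(1, len(r) + 1), "structure": list(structure), "reactivity": r}),
        args.out_dir / "reactivity_profile.tsv",
    )
    loop = [i for i, ch in enumerate(structure) if ch == "."]
    print(f"hairpin {structure}")
    print(f"mean reactivity loop {np.mean(r[loop]):+.4f} vs stem "
          f"{np.mean(np.delete(r, loop)):+.4f}")

    curve = simulate_binding_curve(0.9, 0.15, 1.5, noise_sd=0.05, seed=args.seed)
    fit = hill_fit(curve)
    print(f"\nsingle titration fit: B_max={fit.b_max:.3f}, K_d={fit.k_d:.3f} uM, "
          f"n={fit.n:.2f} (true 0.9 / 0.15 / 1.5)")

    rec = hill_recovery_study(n_curves=100, noise_sd=0.05, seed=args.seed)
    print(f"recovery over {rec['n_curves']} curves at {rec['noise_sd']:.0%} noise: "
          f"median relative K_d error {rec['median_rel_kd_error']:.3f}")


if __name__ == "__main__":
    main()
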