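#!/usr/bin/env python
"""Jukes-Cantor insertion-age distribution of repeat-element copies.

Copies of a 10-kb consensus are simulated at two age peaks (d = 0.02, an
ancient burst at d = 0.20) and dated back from their observed proportion of
differences p via d = -(3/4) ln(1 - (4/3) p).  The histogram of corrected
ages recovers both bursts.  Writes results/te_age.tsv and (if matplotlib is
importable) a figure under results/figures/.
"""

import argparse
from pathlib import Path

import numpy as np

from kelpscan.mol_evolution import te_age_distribution
from kelpscan.synthetic_data import simulate_te_decay


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ages = [0.02] * 150 + [0.20] * 150
    copies, _ = simulate_te_decay(10_000, ages, seed=args.seed,
                                  family_id="LTR-sim")
    hist = te_age_distribution(copies, bin_width=0.01)
    hist.to_csv(args.out / "te_age.tsv", sep="\t", index=False)

    ds = np.array([c.d for c in copies])
    print(f"{len(copies)} copies dated; recovered peaks "
          f"{ds[:150].mean():.4f} (true 0.02) and {ds[150:].mean():.4f} "
          f"(true 0.20) -> {args.out}/te_age.tsv")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        finite = hist[np.isfinite(hist.bin_low)]
        ax.bar(finite.bin_low, finite["count"], width=0.01, align="edge",
               color="#356044", edgecolor="white")
        ax.set_xlabel("JC-corrected substitutions/site (relative age)")
        ax.set_ylabel("copies")
        ax.set_title("Repeat insertion-age distribution")
        fig.tight_layout()
        figdir = args.out / "figures"
        figdir.mkdir(exist_ok=True)
        fig.savefig(figdir / "te_age_distribution.png", dpi=150)
        print(f"figure -> {figdir}/te_age_distribution.png")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
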