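#!/usr/bin/env python
"""Decode fragment-analysis peaks into chromosome XVI genotype calls.

Reads the peak table written by 01_simulate_collection.py, applies the
dual-dye co-migration rules and the diploid/aneuploid conventions, and
writes the per-strain genotype table (alleles, zygosity, copy number,
configuration label, rearrangement flag).
"""

import argparse
from pathlib import Path

from ssu1_checkup import io as io_mod
from ssu1_checkup.panel import load_panel
from ssu1_checkup.pipeline import call_genotypes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--peaks", type=Path, default=Path("results/synthetic/peaks.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/chr16_genotypes.tsv"))
    args = ap.parse_args()

    panel = load_panel()
    peaks = io_mod.read_peak_table(args.peaks)
    df = call_genotypes(peaks, panel)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)

    n_cr = int(df["has_CR"].sum())
    n_aneu = int((df["zygosity"] == "aneuploid").sum())
    n_na = int((df["zygosity"] == "no_amplification").sum())
    print(
        f"called {len(df)} strains: {n_cr} carry >=1 rearrangement, "
        f"{n_aneu} aneuploid, {n_na} without amplification -> {args.out}"
    )


if __name__ == "__main__":
    main()
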