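#!/usr/bin/env python
"""Generate the synthetic strain collection every later stage consumes.

The original survey's 586-strain collection is not deposited, so the
analysis runs on a generated stand-in with known ground truth: clonal
lineages of microsatellite genotypes, fragment-analysis peak tables for
their chromosome XVI alleles, strain metadata, and the SO2-dose growth
design.  Outputs land in results/synthetic/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ssu1_checkup import io as io_mod
from ssu1_checkup.panel import load_panel
from ssu1_checkup.simulate import (
    SimConfig,
    gen_growth_curves,
    gen_microsat_population,
    gen_peak_table,
    gen_templates,
)

CEN16_BY_LINEAGE = [
    ("XVI-wt^991", "XVI-wt^991"),
    ("VIII-t-XVI^555", "VIII-t-XVI^555"),
    ("XVI-wt^991", "VIII-t-XVI^555"),
    ("XV-t-XVI^496", "inv-XVI^781"),
    ("VIII-t-XVI^388", "VIII-t-XVI^388"),
    ("XVI-wt^991", "XV-t-XVI^496"),
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel = load_panel()
    cfg = SimConfig(seed=args.seed, n_lineages=6, clone_size=8)
    table, truth = gen_microsat_population(cfg)
    io_mod.write_genotype_table(table, args.out / "genotypes.tsv")
    truth.events.to_csv(args.out / "truth_events.tsv", sep="\t", index=False)

    genotypes = [
        (s, CEN16_BY_LINEAGE[lin % len(CEN16_BY_LINEAGE)])
        for s, lin in truth.lineage.items()
    ]
    peaks = gen_peak_table(genotypes, panel, cfg)
    io_mod.write_peak_table(peaks, args.out / "peaks.tsv")

    pd.DataFrame(
        [
            {
                "strain_id": s,
                "lineage": lin,
                "population": "starter" if lin % 3 == 0 else "natural",
                "environment": "cellar" if lin % 2 == 0 else "vineyard",
                "matrix": ("white", "red", "sweet")[lin % 3],
            }
            for s, lin in truth.lineage.items()
        ]
    ).to_csv(args.out / "metadata.tsv", sep="\t", index=False)

    io_mod.write_templates_fasta(gen_templates(panel, seed=args.seed),
                                 args.out / "templates.fasta")

    gcfg = SimConfig(seed=args.seed, n_strains_per_config=3, n_replicates=3)
    curves, gtruth = gen_growth_curves(gcfg)
    io_mod.write_growth_table(curves, args.out / "growth.tsv")
    gtruth.to_csv(args.out / "growth_truth.tsv", sep="\t", index=False)

    print(
        f"wrote {len(table)} strains over {cfg.n_lineages} lineages, "
        f"{len(peaks)} peaks, {len(curves)} growth curves -> {args.out}"
    )


if __name__ == "__main__":
    main()
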