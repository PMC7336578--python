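#!/usr/bin/env python
"""Population statistics of the chromosome XVI (SSU1-promoter) alleles.

Joins the genotype calls with strain metadata, computes allele frequencies
under the diploid assumption, homozygosity percentages, rearrangement
occurrence by subpopulation, and chi-square comparisons between starters and
natural isolates.  Also verifies the class-aggregate arithmetic of the
published survey rows shipped with the package.
"""

import argparse
from pathlib import Path

import pandas as pd

from ssu1_checkup import reference
from ssu1_checkup.allele_stats import (
    aggregate_by_class,
    chi2_compare,
    cr_occurrence,
    genotype_label_table,
    allele_frequencies,
    homozygosity_pct,
)
from ssu1_checkup.panel import load_panel
from ssu1_checkup.pipeline import _join_records


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--genotypes", type=Path, default=Path("results/chr16_genotypes.tsv"))
    ap.add_argument("--metadata", type=Path, default=Path("results/synthetic/metadata.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel = load_panel()
    geno = pd.read_csv(args.genotypes, sep="\t")
    meta = pd.read_csv(args.metadata, sep="\t", dtype=str)
    records = _join_records(geno, meta, panel)

    freq = allele_frequencies(records, by="population")
    freq.to_csv(args.out / "allele_frequencies.tsv", sep="\t", index=False)
    hom = homozygosity_pct(records, by="population")
    hom.to_csv(args.out / "homozygosity.tsv", sep="\t", index=False)
    occ = cr_occurrence(records, panel, by="population")
    occ.to_csv(args.out / "cr_occurrence.tsv", sep="\t", index=False)
    labels = genotype_label_table(records, panel, by="environment")
    labels.to_csv(args.out / "genotype_labels_by_environment.tsv", sep="\t", index=False)

    for _, row in occ.iterrows():
        print(f"{row['group']}: {row['pct_with_CR']:.1f}% carry >=1 rearrangement "
              f"(n={row['n_strains']})")

    # starters vs natural chi-square per allele (copy counts)
    wide = freq.pivot_table(index="allele", columns="group", values="count",
                            fill_value=0)
    denom = freq.groupby("group")["denominator"].first()
    rows = []
    for allele in wide.index:
        a = (int(wide.loc[allele].get("starter", 0)),
             int(denom.get("starter", 0) - wide.loc[allele].get("starter", 0)))
        b = (int(wide.loc[allele].get("natural", 0)),
             int(denom.get("natural", 0) - wide.loc[allele].get("natural", 0)))
        res = chi2_compare(a, b, yates=True)
        rows.append({"allele": allele, "chi2": res.statistic, "p": res.p_value,
                     "valid": res.valid})
    pd.DataFrame(rows).to_csv(args.out / "chi2_starter_vs_natural.tsv",
                              sep="\t", index=False)

    # internal-consistency arithmetic of the published survey rows
    ref = reference.ALLELE_SURVEY
    cls = dict(zip(ref["allele"], ref["chrom_class"]))
    agg = aggregate_by_class(dict(zip(ref["allele"], ref["freq_total"])), cls)
    print(f"published survey check: VIII-t-XVI class frequency sums to "
          f"{agg['VIII-t-XVI']:.3f} (printed 0.539)")


if __name__ == "__main__":
    main()
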