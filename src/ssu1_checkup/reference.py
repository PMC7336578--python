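"""Published summary tables from the original SSU1-checkup survey.

The strain collection behind the original survey is not publicly deposited,
so its population-level tables cannot be recomputed from raw data.  What can
be checked offline is their internal arithmetic: class aggregates must equal
the sum of their member-allele rows, and per-group heterogeneity fractions
must follow from integer event counts.  The printed values are stored here
as inputs for those consistency checks.
"""

from __future__ import annotations

import pandas as pd

# Allele-frequency / homozygosity survey rows (392 non-redundant strains:
# 310 natural isolates + 82 starters).  Frequencies are CEN16 allele-copy
# fractions; homozygosity is % of strains homozygous for the allele.
ALLELE_SURVEY = pd.DataFrame(
    [
        # allele, class, freq_total, freq_natural, freq_starters,
        #                hom_total, hom_natural, hom_starters
        ("VIII-t-XVI^388", "VIII-t-XVI", 0.093, 0.021, 0.369, 3.8, 2.1, 10.0),
        ("VIII-t-XVI^478", "VIII-t-XVI", 0.027, 0.034, 0.000, 2.2, 2.8, 0.0),
        ("VIII-t-XVI^555", "VIII-t-XVI", 0.411, 0.464, 0.206, 34.6, 43.2, 3.8),
        ("VIII-t-XVI^631", "VIII-t-XVI", 0.008, 0.010, 0.000, 0.8, 1.0, 0.0),
        ("XV-t-XVI^496", "XV-t-XVI", 0.041, 0.026, 0.100, 1.4, 0.6, 3.6),
        ("inv-XVI^781", "inv-XVI", 0.042, 0.053, 0.000, 4.4, 5.6, 0.0),
        ("XVI-wt^991", "XVI-wt", 0.337, 0.322, 0.394, 21.8, 25.4, 8.5),
    ],
    columns=[
        "allele", "chrom_class",
        "freq_total", "freq_natural", "freq_starters",
        "hom_total", "hom_natural", "hom_starters",
    ],
)

# Published class aggregates for the VIII-t-XVI rows of the same survey.
VIII_T_XVI_CLASS_AGGREGATE = {
    "freq_total": 0.539,
    "freq_natural": 0.529,
    "freq_starters": 0.575,
    "hom_total": 41.4,
}

# Survey population sizes (non-redundant set and its two subpopulations).
POPULATION_SIZES = {"total": 392, "natural": 310, "starters": 82}

# Heterogeneity fractions (%) of the 16 published nearly-isogenic groups:
# per-group VNTR/LOH shares at the 15 microsatellite loci and VNTR/LOH/CR
# shares at the chromosome VIII and chromosome XVI assay loci.
ISOGENIC_SURVEY = pd.DataFrame(
    [
        # group, n, mean_bruvo, ms_vntr, ms_loh, c8_vntr, c8_loh,
        #                       c16_vntr, c16_loh, c16_cr
        (1, 5, 0.09, 2.7, 6.7, 0.0, 0.0, 0.0, 0.0, 0.0),
        (2, 3, 0.04, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (3, 12, 0.03, 1.7, 1.7, 0.0, 0.0, 0.0, 8.3, 0.0),
        (4, 6, 0.006, 2.2, 0.0, 16.7, 50.0, 0.0, 0.0, 0.0),
        (5, 6, 0.105, 7.8, 0.0, 0.0, 0.0, 16.7, 0.0, 0.0),
        (6, 15, 0.05, 3.1, 2.2, 6.7, 0.0, 0.0, 0.0, 6.7),
        (7, 4, 0.07, 1.7, 6.7, 0.0, 0.0, 0.0, 0.0, 0.0),
        (8, 3, 0.05, 0.0, 2.2, 0.0, 0.0, 0.0, 0.0, 0.0),
        (9, 3, 0.02, 0.0, 2.2, 0.0, 0.0, 0.0, 0.0, 33.3),
        (10, 22, 0.06, 1.5, 5.5, 0.0, 0.0, 0.0, 0.0, 0.0),
        (11, 16, 0.014, 2.5, 0.0, 0.0, 0.0, 12.5, 12.5, 0.0),
        (12, 10, 0.037, 2.7, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (13, 4, 0.044, 5.0, 0.0, 25.0, 0.0, 0.0, 0.0, 50.0),
        (14, 3, 0.023, 0.0, 2.2, 0.0, 33.3, 33.3, 0.0, 33.3),
        (15, 4, 0.055, 6.7, 1.7, 0.0, 0.0, 0.0, 0.0, 0.0),
        (16, 9, 0.07, 1.5, 3.0, 11.1, 0.0, 11.1, 0.0, 0.0),
    ],
    columns=[
        "group", "n_strains", "mean_bruvo",
        "microsat_VNTR", "microsat_LOH",
        "chr8_VNTR", "chr8_LOH",
        "chr16_VNTR", "chr16_LOH", "chr16_CR",
    ],
)

# Published TOTAL row of the heterogeneity survey.  The chromosome XVI VNTR
# total (2.9) does not follow from the printed group rows under any simple
# averaging rule (the unweighted mean is 4.6) and is documented here as an
# internal inconsistency of the published table.
ISOGENIC_SURVEY_TOTALS = {
    "microsat_VNTR": 2.4,
    "microsat_LOH": 2.1,
    "chr8_VNTR": 3.7,
    "chr8_LOH": 5.2,
    "chr16_VNTR": 2.9,  # inconsistent with the group rows; see note above
    "chr16_LOH": 1.3,
    "chr16_CR": 7.7,
}
ISOGENIC_TOTALS_CONSISTENT_COLUMNS = [
    "microsat_VNTR", "microsat_LOH", "chr8_VNTR", "chr8_LOH",
    "chr16_LOH", "chr16_CR",
]

# Two-way variance decomposition (% of total sum of squares) of the published
# SO2-tolerance experiment (6 promoter configurations x 4 SO2 doses,
# 5 strains x 6 replicates per cell), with the Levene homoscedasticity p.
GROWTH_ANOVA_SURVEY = pd.DataFrame(
    [
        ("lag_time", 18.4, 23.5, 7.0, 50.7, 0.06),
        ("mu_max", 14.8, 17.0, 2.5, 65.6, 0.002),
    ],
    columns=["trait", "pct_SO2", "pct_chr16", "pct_interaction", "pct_residual", "levene_p"],
)
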