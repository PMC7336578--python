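# ssu1-checkup

Genotyping and population analysis of *SSU1*-promoter chromosomal
rearrangements in wine yeast (*Saccharomyces cerevisiae*), from multiplex
PCR fragment-analysis peaks to ecological allele statistics and
SO₂-tolerance growth kinetics.

## The problem

Sulfite (SO₂) tolerance in wine yeast is largely driven by the expression of
the sulfite efflux pump gene *SSU1*. Three independent chromosomal
rearrangements (CR) place *SSU1* under stronger promoters: the VIII-t-XVI
translocation (*ECM34* promoter tandem repeats), the XV-t-XVI translocation
(*ADH1* promoter) and the inv-XVI inversion (*GCR1* region). The
*SSU1*-checkup assay detects all of them in a single multiplex PCR: each
chromosome arm gets a fluorophore-labelled primer (FAM, ATTO550, HEX,
ATTO565), so wild-type products light up in one dye while
rearrangement-junction products co-migrate in **two** dyes. Every product
primed by the HEX-labelled primer is physically linked to the chromosome XVI
centromere (CEN16), so the set of HEX-containing alleles of a strain is its
chromosome XVI genotype.

This package implements the full computational side of that workflow, for
anyone genotyping strain collections with dye-labelled multiplex panels:

- `ssu1_checkup.panel` — peak decoding (dual-dye co-migration within a ±3 bp
  tolerance), genotype calling under the diploid assumption (one observed
  allele ⇒ homozygote; ≥3 distinct alleles ⇒ aneuploid), configuration
  labels such as `991:555`;
- `ssu1_checkup.insilico` — exact-match in-silico PCR predicting amplicon
  sizes and dye sets on template sequences;
- `ssu1_checkup.popgen` — Bruvo microsatellite distances
  (per allele pair `1 − 2^−k` for `k` repeat steps, minimal matching over a
  diploid genotype), clone collapsing at 0.15 (single-linkage components),
  heterozygosity profiling, k-means grouping with BIC
  (`BIC(k) = n·ln(WSS_k/n) + k·ln n`), neighbor joining;
- `ssu1_checkup.allele_stats` — allele frequencies over CEN16 copies,
  homozygosity percentages, class aggregates, Yates-corrected χ² contrasts,
  CR occurrence by subpopulation/environment/matrix;
- `ssu1_checkup.isogenic` — nearly isogenic groups (Bruvo < 0.106, fewer
  than two VNTR or LOH differences from the modal genotype) and per-group
  VNTR/LOH/CR heterogeneity fractions
  (`100 × events / (strains × loci)`);
- `ssu1_checkup.growth` — OD600 linearisation
  (`y = −0.0018x³ + 0.1464x² + 0.7757x + 0.0386`), Richards growth fits
  `y(t) = K(1 + ν e^{−k(t−t_m)})^{−1/ν}` with μmax taken as the maximum of
  d(ln y)/dt, lag time as the first crossing of twice the inoculum OD, and
  the two-way ANOVA `Y = m + ChrXVI + SO₂ + ChrXVI:SO₂ + E` with variance
  shares and a median-centred Levene test;
- `ssu1_checkup.simulate` — seeded generators for peak tables, clonal
  microsatellite populations, reference-strain templates and growth curves,
  each with ground-truth logs.

## Worked example

```bash
python analysis/01_simulate_collection.py   # synthetic collection, seed 42
python analysis/02_call_genotypes.py
python analysis/03_population_structure.py
python analysis/04_allele_statistics.py
python analysis/05_isogenic_heterogeneity.py
python analysis/06_growth_so2.py
```

prints, among other lines:

```
called 48 strains: 40 carry >=1 rearrangement, 0 aneuploid, 0 without amplification
clone collapsing at 0.15: 6 non-redundant strains, 42 clones removed
BIC selects k = 6 groups among representatives
starter: 50.0% carry >=1 rearrangement (n=16)
natural: 100.0% carry >=1 rearrangement (n=32)
published survey check: VIII-t-XVI class frequency sums to 0.539 (printed 0.539)
lag_time_h: variance shares chr16 33.8%, so2 45.1%, interaction 20.0%, residual 1.1%
```

Read: all 48 simulated strains genotyped; the 6 generating lineages were
recovered exactly by clone collapsing and re-identified by BIC; the CR
carriage split matches the lineage design; the published per-allele survey
rows sum to their printed class aggregate; and in the simulated tolerance
assay the SO₂ dose and the promoter configuration dominate lag-time
variance, as expected from the configured effect sizes.

The same stages are available as a CLI
(`ssu1-checkup simulate|call|popgen|growth|run-all`) and as a single
programmatic entry point (`ssu1_checkup.pipeline.run_pipeline`).

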