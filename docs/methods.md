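# Methods

## Assay model and peak decoding

The multiplex assay is described by an `AllelePanel`: each allele has a
chromosome class (`VIII-wt`, `XV-wt`, `XVI-wt`, `VIII-t-XVI`, `XV-t-XVI`,
`inv-XVI`), an expected product size (or a size range for the wild-type VIII
product, 550–700 bp by default, because its *ECM34* tandem-repeat count
varies between strains) and a dye set. Rearrangement-junction alleles carry
two dyes, wild-type alleles one; any allele whose dye set contains HEX is
CEN16-linked and counts toward the chromosome XVI genotype.

Decoding works in two passes. Dual-dye alleles are matched first and require
co-migrating peaks: one peak in each dye of the allele, both within the size
tolerance of the expectation and within the tolerance of each other (both
labels sit on one physical fragment, so their apparent sizes must agree).
Single-dye alleles are then called from the remaining peaks only, which is
what disambiguates a FAM peak at 555 bp: with a HEX partner it is the
VIII-t-XVI junction, alone it is a wild-type VIII product. Each physical
peak supports at most one call; leftovers are reported unassigned. A peak
equally close to two definitions raises an error rather than being
tie-broken — mis-genotyping is costlier than a re-run. Panel validation
enforces pairwise separation > 2× tolerance within a dye set, which makes
such ties impossible unless the tolerance is widened after validation.

The sizing tolerance defaults to ±3 bp, a typical capillary sizing error
scale for products of 400–1000 bp; it is configurable everywhere.

Genotype calling follows the diploid convention of routine microsatellite
scoring: one distinct CEN16 allele is duplicated into a homozygous pair, two
make a heterozygote, three or more imply an extra chromosome XVI copy
(aneuploidy, copy number = allele count), and zero is recorded as
no-amplification — a flag for a potential uncharacterised rearrangement, not
an error. Reciprocal translocation products (XVI-t-XV, XVI-t-VIII) are not
in the default panel, mirroring the assay's design choice to keep the
chromatogram simple.

Two counting conventions for biallelic combinations coexist in the
literature on this assay: 21 pairs of 7 alleles without repetition and 28
with repetition (homozygotes included). The package works with the 28
unordered pairs and reports labels verbatim, taking no side.

## In-silico PCR

Priming is exact-match only — the assay's primers were validated on
conspecific strains, and a mismatch model would add parameters without
adding discrimination. Product size runs from the 5' end of the forward
primer to the 5' end of the reverse primer, inclusive. All convergent site
pairs up to `max_len` (default 1500 bp) are reported, so tandem-repeat
templates yield product ladders. The packaged reference templates are
synthetic stand-ins: random backgrounds with planted primer sites, re-drawn
if a spurious site appears, sized so each reference strain (SB wild type, GN
with XV-t-XVI, F10 with VIII-t-XVI, P5 with inv-XVI) reproduces exactly its
published amplicon sizes and dye pairs. They are not the deposited allele
sequences; a FASTA loader accepts real sequences when available. The
published VIII-t-XVI repeat arithmetic (two/three/four 76 bp units plus one
47 bp unit) does not reproduce the printed size gaps (90/77/76 bp), so the
templates encode the printed sizes, not a reconstructed repeat structure.

## Bruvo distance and clone structure

Per allele pair the distance is `1 − 2^−k`, with `k` the repeat-step count
obtained by rounding the size difference over the locus motif length
(defaults: 3 bp for the SCAAT-family loci, 2 bp otherwise; the original
survey does not state motif lengths, so they are configurable). A diploid
locus distance is the minimum over the two perfect matchings of the mean
per-pair distance; a genotype distance is the mean over loci typed in both
strains (pairwise-complete averaging — the genome-addition/loss variants for
mixed ploidy are out of scope). Strains typed at fewer than 12 of 15 loci
are dropped before any distance computation.

Clone collapsing at 0.15 uses single-linkage connected components of the
graph with an edge wherever d < 0.15. A greedy "remove all but one" sweep
would depend on strain order; components make the partition deterministic,
with the lexicographically smallest ID as representative.

Group inference encodes genotypes as per-allele dosage vectors (0/1/2),
centres and scales them, keeps the principal components covering ≥ 90% of
variance (an explicit, configurable choice — the survey does not state a
retention rule), and runs seeded k-means for k = 1..k_max scored by
`BIC(k) = n·ln(WSS_k/n) + k·ln n`. This criterion is meaningful on
populations with continuous within-group diversity (the non-redundant
strain set it is applied to after clone collapsing); on sets of
near-duplicate clones WSS collapses toward zero and the curve degenerates,
which is why collapsing precedes clustering in the pipeline. The published
methods name both a k-means and a Ward's criterion for group selection;
k-means is implemented, Ward is a noted unimplemented alternative. Neighbor
joining is delegated to scikit-bio and serialised as newick.

## Isogenic heterogeneity

Nearly isogenic groups are built by greedy agglomeration over the clone set:
a strain joins a group only if its Bruvo distance to every member is below
0.106 (the survey states both 0.106 and 0.105; 0.106 is used) and it
differs from the group's modal genotype at fewer than two loci by VNTR and
fewer than two by LOH — the only reading of "less than two VNTR or LOH"
consistent with groups harbouring several events spread across members. The
modal genotype is the most frequent per locus (ties broken toward the
smallest allele pair) and is refreshed after each admission. Groups smaller
than three strains are dropped.

Event classification against the modal genotype, in precedence order:
**LOH** — strain homozygous (a,a) where the modal genotype is heterozygous
and contains a; **CR** (chromosome XVI only) — a different multiset of
rearrangement classes, flagged as a conflict if a shared class also shifted
size; **VNTR** — same classes, an allele size shifted by at least one repeat
unit. Heterogeneity fractions divide event counts by strain-locus cells
(group size × 15 microsatellites, × 1 chromosome VIII locus, × 1 chromosome
XVI locus), the only denominator that reproduces the published group cells
(2/75 → 2.7%, 1/6 → 16.7%). The TOTAL row is the unweighted mean of group
percentages, which reproduces six of the seven published totals; the
published chromosome XVI VNTR total (2.9) follows from neither an
unweighted (4.6) nor a strain-weighted (4.0) mean of its printed column and
is treated as an internal inconsistency of the published table, excluded
from consistency checks.

## Growth kinetics

Raw OD600 readings are linearised with the cubic calibration polynomial
(coefficients −0.0018, 0.1464, 0.7757, 0.0386, increasing on the 0–2
operating range), applied in the measured→corrected direction with the
constant term as printed. Each curve is fit with the Richards
(generalised-logistic) model `y(t) = K(1 + ν e^{−k(t−t_m)})^{−1/ν}`,
all parameters positive, by bounded least squares restarted from several
seeded initialisations (ν spanning sub- and super-logistic shapes, rate from
a crude log-slope estimate); the lowest residual sum of squares wins.
Because the published description names the model but not its
parameterisation, μmax is defined operationally as the maximum of
d(ln y)/dt of the fitted curve over the observed window, which is invariant
to reparameterisation. For this model that derivative is monotone
decreasing, so the maximum sits at the window's start; on noisy data the
shape–rate (ν, k) likelihood ridge gives single-curve μmax a sampling
scatter of a few percent, while the estimator is unbiased — recovery is
therefore assessed on the mean over replicates. Lag time is the first
linearly interpolated crossing of twice the inoculum OD (corrected scale by
default, with a raw-data switch), right-censored at the last time point;
curves starting at or above the threshold get lag 0. Degenerate
non-increasing curves are flagged with μmax 0 rather than fitted.

The variance decomposition fits `trait ~ ChrXVI * SO₂` by OLS with
sequential (type I) sums of squares — on the balanced design the ordering is
immaterial, and a dedicated test asserts that invariance. Percent variance
is each term's share of the total SS; homoscedasticity uses the
median-centred (Brown–Forsythe) Levene variant across design cells, the
robust default where the published text names only "Levene". Censored lags
are excluded with the count reported; empty design cells abort with the
cells named.

## Synthetic data

The generators are pure functions of their configuration and a mandatory
seed.

*Peak tables* emit one peak per dye per allele at the expected size plus
Gaussian sizing noise (default sd 0.5 bp, a capillary precision scale) with
optional per-peak dropout; homozygotes produce a single peak set, as on a
real trace.

*Microsatellite populations* draw founder diploid genotypes per lineage from
lineage-specific repeat-count blocks spaced 10 repeat steps apart — far
beyond the 0.15 clone cutoff — then expand clones with per-locus ±1-step
VNTR mutations (stepwise mutation model, the minimal model consistent with
observed repeat shifts) and heterozygote→homozygote LOH at configured rates
(defaults 0.02 and 0.01 per locus per clone, giving event fractions on the
scale of the published heterogeneity table). Every applied event is logged
so downstream estimates can be scored.

*Growth curves* cover the published tolerance design — six promoter
configurations × four SO₂ doses (0/25/50/75 mg/L) × strains × replicates on
a 0–96 h grid (25 points by default) with OD noise sd 0.01. The truth
model is a Richards curve anchored at the inoculum: `t_m = ln(K/od₀ − 1)/k`
makes the curve start exactly at the inoculum OD (default 0.1, the OD600
scale of 10⁶ cells/mL in a microplate), and SO₂ enters as a pure delay
(holding the curve at the inoculum floor) plus a multiplicative rate loss,
scaled per configuration so rearranged promoters are the more tolerant.
During an active delay the floored curve is not a pure Richards shape, and
the Richards fit slightly underestimates the post-lag log-slope there; the
truth table flags those curves (`floored`) and exact parameter recovery is
asserted on the unfloored ones.

What the generators do not emulate: sequence-level realism of the templates
(GC content, chromatin), selection or drift across clonal generations,
plate-position effects, and non-Gaussian peak artefacts (stutter,
pull-up). Passing tests therefore demonstrate correctness of the decision
rules and estimators under the stated error model, not robustness to every
artefact of real traces.

## Numerical choices and limitations

- Repeat-step rounding makes the Bruvo distance robust to sub-motif sizing
  jitter but maps size differences below half a motif to zero.
- k-means restarts (10) and the PCA solver are seeded; BIC ties break toward
  smaller k.
- Richards fitting bounds: K ≤ 10× the observed maximum, ν ∈ [10⁻³, 50],
  k ≤ 10 /h, t_m ≤ 10× the window; WSS/RSS floors of 10⁻¹² guard logs.
- χ² on tables with a zero margin is undefined and returned flagged instead
  of raised; Yates correction is on by default for 2×2 contrasts.
- The published population tables cannot be recomputed without the
  undeposited strain collection; they enter only as shipped constants for
  internal-arithmetic checks (`ssu1_checkup.reference`), never as fitted
  targets.
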