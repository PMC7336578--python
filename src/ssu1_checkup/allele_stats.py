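"""Population-level statistics of chromosome XVI (SSU1-promoter) alleles.

Allele frequencies are computed under the diploid assumption: each euploid
strain contributes two CEN16-linked allele copies (a single observed allele
counts twice), an aneuploid strain contributes one copy per distinct allele
(its full copy number), and strains with no amplification are excluded from
both numerator and denominator.  An alternative euploid-only mode drops
aneuploid strains entirely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Sequence, Union

import pandas as pd
from scipy import stats as sps

from .panel import CR_CLASSES, AllelePanel, Chr16Genotype, classify_configuration


@dataclass(frozen=True)
class StrainRecord:
    """One strain with its metadata and chromosome XVI genotype."""

    strain_id: str
    population: str  # starter | natural | clone
    genotype: Chr16Genotype
    environment: str = "NA"  # cellar | vineyard | NA
    matrix: str = "NA"  # sweet | white | red | NA


GroupKey = Union[None, str, Callable[[StrainRecord], str]]


def _group(records: Sequence[StrainRecord], by: GroupKey) -> Dict[str, List[StrainRecord]]:
    if not records:
        raise ValueError("no strain records")
    if by is None:
        return {"all": list(records)}
    keyfun = by if callable(by) else (lambda r: getattr(r, by))
    out: Dict[str, List[StrainRecord]] = {}
    for r in records:
        out.setdefault(str(keyfun(r)), []).append(r)
    return out


def allele_frequencies(
    records: Sequence[StrainRecord],
    by: GroupKey = None,
    *,
    include_aneuploid: bool = True,
) -> pd.DataFrame:
    """Per-group CEN16 allele frequencies (tidy frame: group, allele, freq).

    The denominator is the total number of CEN16 allele copies in the group:
    2 per euploid strain, ``copy_number`` per aneuploid strain.  Frequencies
    over observed alleles sum to 1 within each group.
    """
    rows = []
    for group, members in _group(records, by).items():
        counts: Counter = Counter()
        denom = 0
        n_no_amp = 0
        for r in members:
            g = r.genotype
            if g.zygosity == "no_amplification":
                n_no_amp += 1
                continue
            if g.zygosity == "aneuploid" and not include_aneuploid:
                continue
            for allele in g.cen16_alleles:
                counts[allele] += 1
                denom += 1
        if denom == 0:
            raise ValueError(f"group {group!r}: no amplified strains")
        for allele, c in sorted(counts.items()):
            rows.append(
                {
                    "group": group,
                    "allele": allele,
                    "count": c,
                    "denominator": denom,
                    "freq": c / denom,
                    "n_no_amplification": n_no_amp,
                }
            )
    return pd.DataFrame(rows)


def homozygosity_pct(records: Sequence[StrainRecord], by: GroupKey = None) -> pd.DataFrame:
    """Per-group percentage of strains homozygous for each allele."""
    rows = []
    for group, members in _group(records, by).items():
        n = len(members)
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        homo: Counter = Counter()
        for r in members:
            g = r.genotype
            if g.zygosity == "homozygous":
                homo[g.cen16_alleles[0]] += 1
        alleles = sorted({a for r in members for a in r.genotype.cen16_alleles})
        for allele in alleles:
            rows.append(
                {
                    "group": group,
                    "allele": allele,
                    "n_homozygous": homo.get(allele, 0),
                    "n_strains": n,
                    "pct_homozygous": 100.0 * homo.get(allele, 0) / n,
                }
            )
    return pd.DataFrame(rows)


def aggregate_by_class(
    values: Mapping[str, float], allele_class: Mapping[str, str]
) -> Dict[str, float]:
    """Sum per-allele values into chromosome-class aggregates (exact sums).

    Works on frequencies and on homozygosity percentages alike: the class
    aggregate is by definition the sum over its member alleles (a strain
    cannot be homozygous for two different member alleles at once).
    """
    out: Dict[str, float] = {}
    for allele, v in values.items():
        cls = allele_class[allele]
        out[cls] = out.get(cls, 0.0) + float(v)
    return out


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    yates: bool
    valid: bool  # False when a margin is zero (test undefined)


def chi2_compare(
    counts_a: Sequence[float], counts_b: Sequence[float], yates: bool = True
) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, optionally Yates-corrected.

    ``counts_a`` / ``counts_b`` are (carrier, non-carrier) counts in the two
    populations.  A zero row or column margin leaves the test undefined; the
    result is then flagged rather than raised.
    """
    table = [[float(counts_a[0]), float(counts_a[1])],
             [float(counts_b[0]), float(counts_b[1])]]
    if any(c < 0 for row in table for c in row):
        raise ValueError("counts must be non-negative")
    row_margins = [sum(r) for r in table]
    col_margins = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if min(row_margins) == 0 or min(col_margins) == 0:
        return Chi2Result(float("nan"), float("nan"), yates, valid=False)
    res = sps.chi2_contingency(table, correction=yates)
    return Chi2Result(float(res.statistic), float(res.pvalue), yates, valid=True)


def chi2_allele_occurrence(
    freq_a: float, copies_a: int, freq_b: float, copies_b: int, yates: bool = True
) -> Chi2Result:
    """Chi-square on allele-copy counts reconstructed from frequencies."""
    ca = round(freq_a * copies_a)
    cb = round(freq_b * copies_b)
    return chi2_compare((ca, copies_a - ca), (cb, copies_b - cb), yates=yates)


def cr_occurrence(
    records: Sequence[StrainRecord], panel: AllelePanel, by: GroupKey = None
) -> pd.DataFrame:
    """Percent of strains per group carrying >= 1 chromosomal rearrangement.

    Also reports per-class carriage so enrichment of individual rearrangement
    types (VIII-t-XVI, XV-t-XVI, inv-XVI) can be compared between groups.
    """
    rows = []
    for group, members in _group(records, by).items():
        n = len(members)
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        flags = [classify_configuration(r.genotype, panel) for r in members]
        row = {
            "group": group,
            "n_strains": n,
            "pct_with_CR": 100.0 * sum(f.has_CR for f in flags) / n,
        }
        for cls in sorted(CR_CLASSES):
            row[f"pct_{cls}"] = 100.0 * sum(f.class_presence[cls] for f in flags) / n
        rows.append(row)
    return pd.DataFrame(rows)


def genotype_label_table(
    records: Sequence[StrainRecord], panel: AllelePanel, by: GroupKey = None
) -> pd.DataFrame:
    """Occurrence (%) of each biallelic genotype label per group."""
    groups = _group(records, by)
    labels = sorted(
        {classify_configuration(r.genotype, panel).label for r in records}
    )
    rows = []
    for group, members in groups.items():
        n = len(members)
        counts = Counter(classify_configuration(r.genotype, panel).label for r in members)
        for label in labels:
            rows.append(
                {
                    "group": group,
                    "label": label,
                    "count": counts.get(label, 0),
                    "pct": 100.0 * counts.get(label, 0) / n,
                }
            )
    return pd.DataFrame(rows)
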