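"""Heterogeneity of nearly isogenic strain groups: VNTR, LOH and CR events.

Clonal wine-yeast populations are not perfectly uniform: individual clones
drift away from the group's modal genotype by tandem-repeat length shifts
(VNTR), by loss of heterozygosity (LOH), or — at the SSU1 locus only — by a
different chromosomal rearrangement altogether (CR).  This module forms
nearly isogenic groups from a clone collection, classifies each strain-locus
difference against the modal genotype, and summarises per-group event
fractions over three locus classes: the 15 microsatellites, the chromosome
VIII assay locus and the chromosome XVI assay locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .popgen import DistanceMatrix, MicrosatTable

LOCUS_KIND_MICROSAT = "microsat"
LOCUS_KIND_CHR8 = "chr8"
LOCUS_KIND_CHR16 = "chr16"

#: loci per class used in fraction denominators
LOCI_PER_KIND = {LOCUS_KIND_MICROSAT: 15, LOCUS_KIND_CHR8: 1, LOCUS_KIND_CHR16: 1}


@dataclass(frozen=True)
class EventCall:
    strain_id: str
    locus: str
    locus_kind: str
    category: str  # VNTR | LOH | CR | none
    conflict: bool = False  # size shift and class change seen together


@dataclass
class IsogenicGroup:
    group_id: int
    members: List[str]
    modal_microsat: Dict[str, Optional[Tuple[float, float]]]  # locus -> pair
    modal_chr8: Optional[Tuple] = None
    modal_chr16: Optional[Tuple] = None
    max_bruvo: float = 0.0

    @property
    def size(self) -> int:
        return len(self.members)


def _modal_pair(pairs: Sequence[Optional[Tuple]]) -> Optional[Tuple]:
    """Most frequent genotype; ties broken toward the smallest allele pair."""
    observed = [tuple(sorted(p)) for p in pairs if p is not None]
    if not observed:
        return None
    counts = Counter(observed)
    top = max(counts.values())
    return min(p for p, c in counts.items() if c == top)


def _diff_kind_microsat(g: Optional[Tuple], modal: Optional[Tuple]) -> str:
    """none / VNTR / LOH for a microsatellite locus vs the modal genotype."""
    if g is None or modal is None:
        return "none"
    g = tuple(sorted(g))
    modal = tuple(sorted(modal))
    if g == modal:
        return "none"
    if g[0] == g[1] and modal[0] != modal[1] and g[0] in modal:
        return "LOH"
    return "VNTR"


def form_groups(
    t: MicrosatTable,
    m: DistanceMatrix,
    max_bruvo: float = 0.106,
    max_diff_loci: int = 2,
    min_size: int = 3,
) -> List[IsogenicGroup]:
    """Greedy agglomeration of clones into nearly isogenic groups.

    A strain joins a group only if its Bruvo distance to every current member
    is below ``max_bruvo`` and it differs from the group's modal
    microsatellite genotype at fewer than ``max_diff_loci`` loci by VNTR and
    fewer than ``max_diff_loci`` loci by LOH.  Seeds are taken in strain
    order and the modal genotype is refreshed after each admission, so the
    procedure is deterministic.  Groups smaller than ``min_size`` are
    dropped.
    """
    locus_names = [l.name for l in t.loci]
    geno = {
        s: {
            ln: (None if np.isnan(t.alleles[i, j]).any() else tuple(t.alleles[i, j]))
            for j, ln in enumerate(locus_names)
        }
        for i, s in enumerate(t.strains)
    }
    unassigned = list(t.strains)
    groups: List[IsogenicGroup] = []
    gid = 0
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        modal = {ln: geno[seed][ln] for ln in locus_names}
        changed = True
        while changed:
            changed = False
            for s in list(unassigned):
                if any(
                    np.isnan(m.d(s, mem)) or m.d(s, mem) >= max_bruvo
                    for mem in members
                ):
                    continue
                kinds = Counter(
                    _diff_kind_microsat(geno[s][ln], modal[ln]) for ln in locus_names
                )
                if kinds["VNTR"] >= max_diff_loci or kinds["LOH"] >= max_diff_loci:
                    continue
                members.append(s)
                unassigned.remove(s)
                modal = {
                    ln: _modal_pair([geno[mem][ln] for mem in members])
                    for ln in locus_names
                }
                changed = True
        if len(members) >= min_size:
            gid += 1
            pairwise = [
                m.d(a, b) for i, a in enumerate(members) for b in members[i + 1:]
            ]
            groups.append(
                IsogenicGroup(
                    group_id=gid,
                    members=sorted(members),
                    modal_microsat=modal,
                    max_bruvo=max(pairwise) if pairwise else 0.0,
                )
            )
    return groups


def classify_event(
    strain_genotype: Optional[Tuple],
    modal_genotype: Optional[Tuple],
    locus_kind: str,
    *,
    strain_id: str = "",
    locus: str = "",
    allele_class: Optional[Mapping] = None,
) -> EventCall:
    """Classify one strain-locus difference against the modal genotype.

    Genotypes are unordered allele pairs; for the chromosome loci the alleles
    are amplicon sizes and ``allele_class`` maps each size to its
    rearrangement class.  Rules, in order of precedence:

    * LOH — the strain is homozygous (a, a) where the modal genotype is
      heterozygous and contains a;
    * CR — chromosome XVI only: the multiset of rearrangement classes differs
      from the modal one (flagged as a conflict when allele sizes within a
      shared class also shifted);
    * VNTR — same allele classes, but an allele size differs from the modal
      one by at least one repeat unit;
    * none — identical genotypes.
    """
    if locus_kind not in LOCI_PER_KIND:
        raise ValueError(f"unknown locus kind {locus_kind!r}")
    make = lambda cat, conflict=False: EventCall(
        strain_id, locus, locus_kind, cat, conflict
    )
    if strain_genotype is None or modal_genotype is None:
        return make("none")
    g = tuple(sorted(strain_genotype))
    modal = tuple(sorted(modal_genotype))
    if g == modal:
        return make("none")
    if g[0] == g[1] and modal[0] != modal[1] and g[0] in modal:
        return make("LOH")
    if locus_kind == LOCUS_KIND_CHR16:
        classes = allele_class or {}
        g_classes = sorted(classes.get(a, "?") for a in g)
        m_classes = sorted(classes.get(a, "?") for a in modal)
        if g_classes != m_classes:
            # conflict when, class change aside, a shared class also shifted size
            shared = set(g_classes) & set(m_classes)
            shifted = any(
                sorted(a for a in g if classes.get(a, "?") == cls)
                != sorted(a for a in modal if classes.get(a, "?") == cls)
                for cls in shared
            )
            return make("CR", conflict=shifted)
    return make("VNTR")


def classify_group_events(
    group: IsogenicGroup,
    microsat_genotypes: Mapping[str, Mapping[str, Optional[Tuple]]],
    chr8_genotypes: Optional[Mapping[str, Optional[Tuple]]] = None,
    chr16_genotypes: Optional[Mapping[str, Optional[Tuple]]] = None,
    chr16_allele_class: Optional[Mapping] = None,
) -> List[EventCall]:
    """Classify every member of a group at every locus against the modal."""
    events: List[EventCall] = []
    for s in group.members:
        for locus, modal in group.modal_microsat.items():
            events.append(
                classify_event(
                    microsat_genotypes[s].get(locus), modal, LOCUS_KIND_MICROSAT,
                    strain_id=s, locus=locus,
                )
            )
    if chr8_genotypes is not None:
        modal8 = _modal_pair([chr8_genotypes.get(s) for s in group.members])
        group.modal_chr8 = modal8
        for s in group.members:
            events.append(
                classify_event(
                    chr8_genotypes.get(s), modal8, LOCUS_KIND_CHR8,
                    strain_id=s, locus="chrVIII",
                )
            )
    if chr16_genotypes is not None:
        modal16 = _modal_pair([chr16_genotypes.get(s) for s in group.members])
        group.modal_chr16 = modal16
        for s in group.members:
            events.append(
                classify_event(
                    chr16_genotypes.get(s), modal16, LOCUS_KIND_CHR16,
                    strain_id=s, locus="chrXVI",
                    allele_class=chr16_allele_class,
                )
            )
    return events


def heterogeneity_fractions(
    group: IsogenicGroup, events: Sequence[EventCall]
) -> Dict[str, float]:
    """Per-category event fractions (%) for each locus class of one group.

    The denominator is the number of strain-locus cells of the class: group
    size times the locus count (15 microsatellites, 1 chromosome VIII locus,
    1 chromosome XVI locus).  E.g. 2 VNTR events among 5 strains x 15
    microsatellite loci give 100 * 2/75 = 2.7%.
    """
    n = group.size
    out: Dict[str, float] = {}
    for kind, n_loci in LOCI_PER_KIND.items():
        cells = n * n_loci
        for cat in ("VNTR", "LOH", "CR"):
            if cat == "CR" and kind != LOCUS_KIND_CHR16:
                continue
            count = sum(
                1 for e in events if e.locus_kind == kind and e.category == cat
            )
            out[f"{'microsat' if kind == 'microsat' else kind}_{cat}"] = (
                100.0 * count / cells
            )
    return out


def summarize_totals(per_group: pd.DataFrame, columns: Optional[Sequence[str]] = None):
    """TOTAL row: unweighted arithmetic mean of the per-group percentages."""
    if len(per_group) == 0:
        raise ValueError("need at least one group")
    if columns is None:
        columns = [c for c in per_group.columns if per_group[c].dtype.kind in "fi"]
    return {c: float(per_group[c].mean()) for c in columns}
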