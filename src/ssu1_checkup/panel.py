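"""Multiplex fragment-analysis panel for SSU1-promoter rearrangement genotyping.

The assay amplifies the SSU1 promoter region of chromosome XVI together with
the wild-type loci of chromosomes VIII and XV using fluorophore-labelled
primers.  Wild-type products carry a single dye; products spanning a
rearrangement junction (translocations VIII-t-XVI and XV-t-XVI, inversion
inv-XVI) are primed from two labelled primers and therefore co-migrate in two
dye channels, which is what makes them recognisable on a capillary sequencer.

Every amplicon primed by the HEX-labelled primer sits next to the chromosome
XVI centromere (CEN16) and therefore segregates with chromosome XVI; the set
of CEN16-linked alleles of a strain is its chromosome XVI genotype.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence


class PanelError(ValueError):
    """Raised when a panel description is internally inconsistent."""


class AmbiguousPeakError(ValueError):
    """Raised when one peak matches two allele definitions equally well."""

    def __init__(self, peak: "Peak", candidates: Sequence[str]):
        self.peak = peak
        self.candidates = list(candidates)
        super().__init__(
            f"peak {peak.dye.name}:{peak.size_bp} matches "
            f"{self.candidates} equally well"
        )


class DyeChannel(Enum):
    """Fluorophore channels of the assay; LIZ is the size standard only."""

    FAM = "FAM"
    HEX = "HEX"
    ATTO550 = "ATTO550"
    ATTO565 = "ATTO565"
    LIZ = "LIZ"


# Chromosome classes recognised by the assay.
WT_CLASSES = frozenset({"VIII-wt", "XV-wt", "XVI-wt"})
CR_CLASSES = frozenset({"VIII-t-XVI", "XV-t-XVI", "inv-XVI"})
CHROM_CLASSES = WT_CLASSES | CR_CLASSES


@dataclass(frozen=True)
class Peak:
    """One detected capillary-electrophoresis fragment."""

    sample_id: str
    dye: DyeChannel
    size_bp: float
    height: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError(f"size_bp must be positive, got {self.size_bp}")
        if self.height is not None and self.height < 0:
            raise ValueError("height must be non-negative")


@dataclass(frozen=True)
class AlleleDef:
    """One allele of the assay: expected size (or range) on a dye set.

    ``cen16_linked`` is true exactly for alleles amplified by the HEX-labelled
    primer, i.e. alleles physically linked to the chromosome XVI centromere.
    """

    allele_id: str
    chrom_class: str
    dye_set: frozenset
    expected_size_bp: Optional[int] = None
    size_range: Optional[tuple] = None  # (lo, hi) inclusive, wt-VIII only
    primers: tuple = ()

    def __post_init__(self) -> None:
        if self.chrom_class not in CHROM_CLASSES:
            raise PanelError(f"unknown chromosome class {self.chrom_class!r}")
        if DyeChannel.LIZ in self.dye_set:
            raise PanelError("LIZ is reserved for the size standard")
        if (self.expected_size_bp is None) == (self.size_range is None):
            raise PanelError(
                f"{self.allele_id}: exactly one of size / size_range required"
            )
        n_dyes = len(self.dye_set)
        if self.chrom_class in CR_CLASSES and n_dyes != 2:
            raise PanelError(f"{self.allele_id}: rearranged alleles need 2 dyes")
        if self.chrom_class in WT_CLASSES and n_dyes != 1:
            raise PanelError(f"{self.allele_id}: wild-type alleles need 1 dye")

    @property
    def cen16_linked(self) -> bool:
        return DyeChannel.HEX in self.dye_set

    def match_error(self, size_bp: float) -> float:
        """Distance from an observed size to this allele's expectation.

        Inside a size range the error is 0 (the wt-VIII product length varies
        with the ECM34 tandem-repeat count, so any size in range is nominal).
        """
        if self.expected_size_bp is not None:
            return abs(size_bp - self.expected_size_bp)
        lo, hi = self.size_range
        if lo <= size_bp <= hi:
            return 0.0
        return min(abs(size_bp - lo), abs(size_bp - hi))


@dataclass
class AllelePanel:
    """A validated set of allele definitions plus the sizing tolerance."""

    alleles: list
    size_tolerance_bp: float = 3.0
    primers: dict = field(default_factory=dict)  # name -> (sequence, dye)

    def __post_init__(self) -> None:
        if not self.alleles:
            raise PanelError("panel contains no alleles")
        if self.size_tolerance_bp <= 0:
            raise PanelError("size_tolerance_bp must be positive")
        ids = [a.allele_id for a in self.alleles]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate allele_id in panel")
        self._check_collisions()

    def _check_collisions(self) -> None:
        # Two alleles sharing a dye_set must stay > 2*tolerance apart,
        # otherwise observed peaks cannot be attributed unambiguously.
        by_dyeset: dict = {}
        for a in self.alleles:
            by_dyeset.setdefault(a.dye_set, []).append(a)
        for dyeset, group in by_dyeset.items():
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    if self._indistinguishable(a, b):
                        raise PanelError(
                            f"alleles {a.allele_id} and {b.allele_id} collide "
                            f"within tolerance on dyes "
                            f"{sorted(d.name for d in dyeset)}"
                        )

    def _indistinguishable(self, a: AlleleDef, b: AlleleDef) -> bool:
        gap = 2 * self.size_tolerance_bp
        if a.expected_size_bp is not None and b.expected_size_bp is not None:
            return abs(a.expected_size_bp - b.expected_size_bp) <= gap
        # range vs point or range vs range: collide if the gap between the
        # intervals is within 2*tolerance
        lo_a, hi_a = a.size_range or (a.expected_size_bp, a.expected_size_bp)
        lo_b, hi_b = b.size_range or (b.expected_size_bp, b.expected_size_bp)
        return not (lo_b - hi_a > gap or lo_a - hi_b > gap)

    def by_id(self, allele_id: str) -> AlleleDef:
        for a in self.alleles:
            if a.allele_id == allele_id:
                return a
        raise KeyError(allele_id)

    @property
    def dual_dye_alleles(self) -> list:
        return [a for a in self.alleles if len(a.dye_set) == 2]

    @property
    def single_dye_alleles(self) -> list:
        return [a for a in self.alleles if len(a.dye_set) == 1]


@dataclass(frozen=True)
class AlleleCall:
    """A decoded allele with the peaks supporting it."""

    allele_id: str
    supporting_peaks: tuple
    match_error_bp: float


@dataclass
class DecodeResult:
    """Allele calls for one sample plus the peaks no allele could explain."""

    sample_id: str
    calls: list
    unassigned: list

    @property
    def allele_ids(self) -> list:
        return [c.allele_id for c in self.calls]


@dataclass
class Chr16Genotype:
    """Chromosome XVI genotype of a strain under the diploid assumption.

    A single observed CEN16-linked allele is duplicated to a homozygous pair
    (as in routine microsatellite scoring); three or more distinct alleles
    imply an extra chromosome XVI copy (aneuploidy); no amplification at all
    flags a putative novel rearrangement.
    """

    cen16_alleles: tuple  # allele_ids, duplicated when homozygous
    copy_number: int
    zygosity: str  # homozygous | heterozygous | aneuploid | no_amplification
    other_alleles: frozenset = frozenset()  # VIII-wt / XV-wt observations


def load_panel(config: Optional[Mapping] = None) -> AllelePanel:
    """Build an :class:`AllelePanel` from a config mapping.

    With no argument the packaged default panel (the published six-primer
    multiplex: wild-type VIII/XV/XVI plus the four VIII-t-XVI repeat-length
    alleles, XV-t-XVI 496 and inv-XVI 781) is returned.
    """
    if config is None:
        config = json.loads(
            resources.files("ssu1_checkup.data").joinpath("panel.json").read_text()
        )
    try:
        tol = float(config.get("size_tolerance_bp", 3.0))
    except (TypeError, AttributeError) as exc:
        raise PanelError("panel config must be a mapping") from exc

    primers = {}
    for p in config.get("primers", []):
        dye = p.get("dye")
        primers[p["name"]] = (p["sequence"], DyeChannel(dye) if dye else None)

    alleles = []
    for entry in config.get("alleles", []):
        try:
            dyes = frozenset(DyeChannel(d) for d in entry["dyes"])
        except ValueError as exc:
            raise PanelError(f"unknown dye in {entry.get('allele_id')}") from exc
        alleles.append(
            AlleleDef(
                allele_id=entry["allele_id"],
                chrom_class=entry["chrom_class"],
                dye_set=dyes,
                expected_size_bp=entry.get("size"),
                size_range=tuple(entry["size_range"]) if "size_range" in entry else None,
                primers=tuple(entry.get("primers", ())),
            )
        )
    return AllelePanel(alleles=alleles, size_tolerance_bp=tol, primers=primers)


def _strip_liz(peaks: Iterable[Peak]) -> list:
    return [p for p in peaks if p.dye is not DyeChannel.LIZ]


def decode_peaks(peaks: Sequence[Peak], panel: AllelePanel) -> DecodeResult:
    """Attribute the peaks of one sample to panel alleles.

    Dual-dye (rearrangement-junction) alleles are matched first: they require
    co-migrating peaks — within tolerance of the expected size in BOTH dyes of
    the allele and within tolerance of each other.  Single-dye wild-type
    alleles are then called from peaks not consumed by a dual-dye call, so a
    FAM peak at 555 bp with a HEX partner is the VIII-t-XVI junction, while
    the same peak alone is a wild-type VIII product.  Each physical peak
    supports at most one call; leftovers are reported unassigned.
    """
    peaks = _strip_liz(peaks)
    sample_ids = {p.sample_id for p in peaks}
    if len(sample_ids) > 1:
        raise ValueError(f"peaks from multiple samples: {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids)) if sample_ids else ""
    tol = panel.size_tolerance_bp
    # stable processing order regardless of input order
    ordered = sorted(peaks, key=lambda p: (p.dye.name, p.size_bp))
    consumed = [False] * len(ordered)
    calls = []

    for allele in sorted(panel.dual_dye_alleles, key=lambda a: a.allele_id):
        d1, d2 = sorted(allele.dye_set, key=lambda d: d.name)
        while True:
            best = None
            for i, p1 in enumerate(ordered):
                if consumed[i] or p1.dye is not d1 or allele.match_error(p1.size_bp) > tol:
                    continue
                for j, p2 in enumerate(ordered):
                    if consumed[j] or p2.dye is not d2:
                        continue
                    if allele.match_error(p2.size_bp) > tol:
                        continue
                    if abs(p1.size_bp - p2.size_bp) > tol:
                        continue
                    err = (allele.match_error(p1.size_bp) + allele.match_error(p2.size_bp)) / 2
                    if best is None or err < best[0]:
                        best = (err, i, j)
            if best is None:
                break
            err, i, j = best
            consumed[i] = consumed[j] = True
            calls.append(
                AlleleCall(allele.allele_id, (ordered[i], ordered[j]), err)
            )

    for i, p in enumerate(ordered):
        if consumed[i]:
            continue
        candidates = []
        for allele in panel.single_dye_alleles:
            if p.dye not in allele.dye_set:
                continue
            err = allele.match_error(p.size_bp)
            if err <= tol:
                candidates.append((err, allele))
        if not candidates:
            continue
        best_err = min(err for err, _ in candidates)
        best = [a for err, a in candidates if err == best_err]
        if len(best) > 1:
            raise AmbiguousPeakError(p, [a.allele_id for a in best])
        consumed[i] = True
        calls.append(AlleleCall(best[0].allele_id, (p,), best_err))

    unassigned = [p for i, p in enumerate(ordered) if not consumed[i]]
    calls.sort(key=lambda c: c.allele_id)
    return DecodeResult(sample_id=sample_id, calls=calls, unassigned=unassigned)


def call_chr16_genotype(decoded, panel: AllelePanel) -> Chr16Genotype:
    """Merge the CEN16-linked allele calls of one sample into a genotype.

    Accepts a :class:`DecodeResult` or a plain list of :class:`AlleleCall`.
    One distinct allele is duplicated to a homozygous pair; two are a
    heterozygote; three or more mean an extra chromosome XVI copy; none at
    all is recorded as no-amplification.
    """
    calls = decoded.calls if isinstance(decoded, DecodeResult) else list(decoded)
    cen16 = []
    other = set()
    for call in calls:
        allele = panel.by_id(call.allele_id)
        if allele.cen16_linked:
            if call.allele_id not in cen16:
                cen16.append(call.allele_id)
        else:
            other.add(call.allele_id)
    cen16.sort(key=lambda a: -_allele_size(panel.by_id(a)))

    if not cen16:
        return Chr16Genotype((), 0, "no_amplification", frozenset(other))
    if len(cen16) == 1:
        return Chr16Genotype((cen16[0], cen16[0]), 2, "homozygous", frozenset(other))
    if len(cen16) == 2:
        return Chr16Genotype(tuple(cen16), 2, "heterozygous", frozenset(other))
    return Chr16Genotype(tuple(cen16), len(cen16), "aneuploid", frozenset(other))


def _allele_size(allele: AlleleDef) -> float:
    if allele.expected_size_bp is not None:
        return float(allele.expected_size_bp)
    return float(sum(allele.size_range)) / 2


@dataclass(frozen=True)
class ConfigurationFlags:
    """Summary flags of a chromosome XVI genotype."""

    has_CR: bool
    class_presence: Mapping  # chrom_class -> bool
    label: str  # e.g. "991:555", alleles sorted descending by size


def classify_configuration(g: Chr16Genotype, panel: AllelePanel) -> ConfigurationFlags:
    """Flag rearrangement carriage and build the short genotype label."""
    if g.zygosity == "no_amplification":
        return ConfigurationFlags(
            has_CR=False,
            class_presence={c: False for c in sorted(CR_CLASSES)},
            label="NA:NA",
        )
    defs = [panel.by_id(a) for a in g.cen16_alleles]
    classes = {d.chrom_class for d in defs}
    presence = {c: (c in classes) for c in sorted(CR_CLASSES)}
    sizes = sorted((_allele_size(d) for d in defs), reverse=True)
    label = ":".join(str(int(s)) for s in sizes)
    return ConfigurationFlags(
        has_CR=bool(classes & CR_CLASSES), class_presence=presence, label=label
    )


def genotype_label_counts(genotypes: Iterable[Chr16Genotype], panel: AllelePanel) -> Counter:
    """Count genotype labels (e.g. "991:555") over a collection of strains."""
    return Counter(classify_configuration(g, panel).label for g in genotypes)
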