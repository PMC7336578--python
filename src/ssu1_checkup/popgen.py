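"""Microsatellite population genetics for clonal wine-yeast collections.

Implements locus-coverage filtering, the Bruvo stepwise-mutation distance,
clone collapsing at a fixed distance cutoff, heterozygosity profiling,
k-means group inference scored by BIC, and neighbor joining.

The Bruvo distance between two alleles that are k repeat units apart is
1 - 2**(-k); for diploid genotypes the locus distance is the minimum over the
two perfect matchings of the mean per-allele-pair distance, and the genotype
distance is the mean over loci typed in both strains.  Genome-addition /
genome-loss models for mixed ploidy are out of scope: genotypes are diploid
pairs (homozygotes stored as duplicated alleles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class LocusDef:
    name: str
    motif_len: int

    def __post_init__(self) -> None:
        if self.motif_len < 1:
            raise ValueError(f"locus {self.name}: motif_len must be >= 1")


def load_loci(config=None) -> List[LocusDef]:
    """Locus definitions (name + repeat-motif length).

    The default is the 15-locus panel used for S. cerevisiae strain typing
    (C3..C11, SCAAT1..6, SCYOR267C, YKL172W, YPL009C), with trinucleotide
    motifs for the SCAAT-family loci and dinucleotide motifs otherwise.
    """
    if config is None:
        config = json.loads(
            resources.files("ssu1_checkup.data").joinpath("loci.json").read_text()
        )
    return [LocusDef(e["name"], int(e["motif_len"])) for e in config["loci"]]


class MicrosatTable:
    """Strain x locus genotype matrix; missing genotypes are NaN pairs.

    ``alleles`` has shape (n_strains, n_loci, 2) in base pairs; homozygotes
    are stored as duplicated pairs.
    """

    def __init__(self, strains: Sequence[str], loci: Sequence[LocusDef], alleles):
        self.strains = list(strains)
        self.loci = list(loci)
        self.alleles = np.asarray(alleles, dtype=float)
        if self.alleles.shape != (len(self.strains), len(self.loci), 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{len(self.strains)} strains x {len(self.loci)} loci"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.alleles <= 0):
                raise ValueError("allele sizes must be positive")

    def genotype(self, strain: str, locus: str) -> Optional[Tuple[float, float]]:
        i = self.strains.index(strain)
        j = [l.name for l in self.loci].index(locus)
        pair = self.alleles[i, j]
        if np.isnan(pair).any():
            return None
        return (float(pair[0]), float(pair[1]))

    def n_typed(self) -> np.ndarray:
        """Per-strain count of non-missing loci."""
        return (~np.isnan(self.alleles).any(axis=2)).sum(axis=1)

    def subset(self, strains: Sequence[str]) -> "MicrosatTable":
        idx = [self.strains.index(s) for s in strains]
        return MicrosatTable(list(strains), self.loci, self.alleles[idx])

    def __len__(self) -> int:
        return len(self.strains)


@dataclass
class DistanceMatrix:
    """Square dissimilarity matrix; NaN marks pairs with no shared locus."""

    ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def d(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    @property
    def missing_pairs(self) -> List[Tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


@dataclass
class CloneSet:
    """Partition of strains into clonal groups with one representative each."""

    components: List[List[str]]
    representatives: List[str]

    @property
    def clones_removed(self) -> List[str]:
        reps = set(self.representatives)
        return [s for comp in self.components for s in comp if s not in reps]


def filter_by_locus_coverage(t: MicrosatTable, min_loci: int = 12) -> MicrosatTable:
    """Keep strains typed at >= min_loci loci (default 12 of 15)."""
    if min_loci > len(t.loci):
        raise ValueError("min_loci exceeds the number of loci")
    keep = [s for s, n in zip(t.strains, t.n_typed()) if n >= min_loci]
    return t.subset(keep)


def bruvo_allele_distance(x: float, y: float, motif_len: int) -> float:
    """Per-allele Bruvo distance 1 - 2**(-k), k = rounded repeat-step count."""
    if motif_len < 1:
        raise ValueError("motif_len must be >= 1")
    k = round(abs(x - y) / motif_len)
    return 1.0 - 2.0 ** (-k)


def bruvo_locus_distance(
    a: Tuple[float, float], b: Tuple[float, float], locus: LocusDef
) -> float:
    """Diploid Bruvo distance at one locus: best perfect matching of alleles."""
    m = locus.motif_len
    d11 = bruvo_allele_distance(a[0], b[0], m)
    d22 = bruvo_allele_distance(a[1], b[1], m)
    d12 = bruvo_allele_distance(a[0], b[1], m)
    d21 = bruvo_allele_distance(a[1], b[0], m)
    return min((d11 + d22) / 2.0, (d12 + d21) / 2.0)


def bruvo_matrix(t: MicrosatTable) -> DistanceMatrix:
    """Pairwise Bruvo distances, averaged over loci typed in both strains.

    Pairs sharing no typed locus get NaN and are reported by
    ``DistanceMatrix.missing_pairs`` so callers can exclude them.
    """
    n = len(t.strains)
    if n < 2:
        raise ValueError("need at least 2 strains")
    vals = np.zeros((n, n))
    present = ~np.isnan(t.alleles).any(axis=2)  # (n, L)
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            if not shared.any():
                vals[i, j] = vals[j, i] = np.nan
                continue
            acc = 0.0
            for jj in np.nonzero(shared)[0]:
                acc += bruvo_locus_distance(
                    tuple(t.alleles[i, jj]), tuple(t.alleles[j, jj]), t.loci[jj]
                )
            vals[i, j] = vals[j, i] = acc / shared.sum()
    return DistanceMatrix(list(t.strains), vals)


def collapse_clones(m: DistanceMatrix, threshold: float = 0.15) -> CloneSet:
    """Collapse strains closer than ``threshold`` into clonal groups.

    Groups are the single-linkage connected components of the graph with an
    edge wherever d < threshold, which makes the outcome independent of
    strain order; the lexicographically smallest ID represents each group.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    n = len(m.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = m.values[i, j]
            if not np.isnan(v) and v < threshold:
                g.add_edge(m.ids[i], m.ids[j])
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    return CloneSet(components=components, representatives=[c[0] for c in components])


def heterozygosity_profile(t: MicrosatTable):
    """Per-strain heterozygous-locus count and the inferred-diploid flag.

    A strain heterozygous at >= 2 microsatellite loci is taken as diploid;
    missing loci never count.
    """
    a = t.alleles
    present = ~np.isnan(a).any(axis=2)
    het = present & (a[:, :, 0] != a[:, :, 1])
    counts = het.sum(axis=1)
    return [
        {"strain": s, "het_loci": int(c), "inferred_diploid": bool(c >= 2)}
        for s, c in zip(t.strains, counts)
    ]


def _encode_allele_counts(t: MicrosatTable) -> np.ndarray:
    """0/1/2 dosage of every observed allele at every locus (missing -> 0)."""
    cols = []
    for j, _locus in enumerate(t.loci):
        observed = np.unique(t.alleles[:, j][~np.isnan(t.alleles[:, j])])
        for allele in observed:
            dosage = (t.alleles[:, j] == allele).sum(axis=1).astype(float)
            cols.append(dosage)
    if not cols:
        return np.zeros((len(t.strains), 0))
    return np.column_stack(cols)


@dataclass
class ClusterResult:
    assignment: Dict[str, int]
    best_k: int
    bic: Dict[int, float]
    wss: Dict[int, float] = field(default_factory=dict)


def cluster_kmeans_bic(t: MicrosatTable, k_max: int, seed: int) -> ClusterResult:
    """k-means group inference with the cluster count picked by BIC.

    Genotypes are encoded as per-allele dosage vectors, centred and scaled,
    reduced to the principal components retaining >= 90% of the variance, and
    partitioned by k-means for k = 1..k_max.  BIC(k) = n*ln(WSS_k/n) +
    k*ln(n); the argmin wins.  Deterministic given the seed.
    """
    n = len(t.strains)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds {n} strains")
    x = _encode_allele_counts(t)
    variances = x.var(axis=0)
    informative = variances > 0
    if not informative.any():
        # all strains identical: a single group, flat curve
        return ClusterResult(
            assignment={s: 0 for s in t.strains}, best_k=1, bic={1: -np.inf}, wss={1: 0.0}
        )
    x = StandardScaler().fit_transform(x[:, informative])
    n_comp = min(n - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, 0.90) + 1)
    scores = scores[:, :keep]

    eps = 1e-12
    bic: Dict[int, float] = {}
    wss: Dict[int, float] = {}
    labels_by_k = {}
    for k in range(1, k_max + 1):
        if k == 1:
            labels = np.zeros(n, dtype=int)
            w = float(((scores - scores.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(scores)
            w = float(km.inertia_)
        wss[k] = w
        bic[k] = n * np.log(max(w, eps) / n) + k * np.log(n)
        labels_by_k[k] = labels
    best_k = min(bic, key=lambda k: (bic[k], k))
    return ClusterResult(
        assignment=dict(zip(t.strains, (int(l) for l in labels_by_k[best_k]))),
        best_k=best_k,
        bic=bic,
        wss=wss,
    )


def nj_tree(m: DistanceMatrix) -> str:
    """Classical neighbor joining; returns the unrooted tree as newick."""
    if len(m.ids) < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(m.values).any():
        raise ValueError(f"missing distances for pairs {m.missing_pairs}")
    tree = _skbio_nj(_SkbioDM(m.values, ids=m.ids))
    return str(tree).strip()
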