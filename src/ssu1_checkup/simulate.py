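"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators mirror the four data types the analysis consumes: tabular
capillary-electrophoresis peak exports, clonal microsatellite populations,
primer-bearing FASTA templates for the reference strains, and Richards
growth curves under an SO2 dose gradient.  All of them are pure functions of
their inputs and a seed, and each returns the ground truth needed to score
the downstream estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .insilico import Primer, Template, revcomp
from .panel import AllelePanel, Peak
from .popgen import LocusDef, MicrosatTable, load_loci

#: chromosome XVI promoter configurations compared in the tolerance assay
GROWTH_CONFIGS = (
    "XVI-wt", "VIII-t-XVI^388", "VIII-t-XVI^478", "VIII-t-XVI^555",
    "XV-t-XVI", "inv-XVI",
)
SO2_LEVELS = (0.0, 25.0, 50.0, 75.0)


@dataclass
class SimConfig:
    """Study-scale simulation settings; the seed is mandatory.

    Defaults follow the published study design where one is stated (four SO2
    doses, six replicates, five strains per promoter configuration, 96 h of
    OD readings, 194-clone scale populations) and a realistic capillary /
    plate-reader error scale where none is (0.5 bp peak sizing noise, 0.01
    OD noise).
    """

    seed: int
    n_lineages: int = 4
    clone_size: int = 10
    vntr_rate: float = 0.02  # per locus per clone, +-1 repeat step
    loh_rate: float = 0.01  # per heterozygous locus per clone
    peak_noise_sd: float = 0.5  # bp
    peak_dropout: float = 0.0
    founder_block_step: int = 10  # repeat-step spacing between lineage blocks
    founder_block_width: int = 4
    growth_time_h: Tuple[float, float] = (0.0, 96.0)
    growth_n_points: int = 25
    od_noise_sd: float = 0.01
    od_baseline: float = 0.1  # inoculum-scale OD600 floor (1e6 cells/mL)
    n_strains_per_config: int = 5
    n_replicates: int = 6

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for rate in (self.vntr_rate, self.loh_rate, self.peak_dropout):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates/probabilities must be in [0, 1]")


def gen_peak_table(
    genotypes: Sequence[Tuple[str, Sequence[str]]],
    panel: AllelePanel,
    cfg: SimConfig,
    wt_sizes: Optional[Mapping[str, float]] = None,
) -> List[Peak]:
    """Emit noisy peaks for each strain's allele set.

    ``genotypes`` is a list of (sample_id, allele_ids); duplicated allele ids
    (homozygotes) yield a single peak set, as on a real trace.  Each allele
    emits one peak per dye of its definition at the expected size plus
    Gaussian sizing noise, independently dropped with the dropout
    probability.  ``wt_sizes`` optionally pins range alleles (wild-type VIII)
    to a concrete product size.
    """
    rng = np.random.default_rng(cfg.seed)
    wt_sizes = dict(wt_sizes or {})
    peaks: List[Peak] = []
    for sample_id, allele_ids in genotypes:
        for allele_id in sorted(set(allele_ids)):
            allele = panel.by_id(allele_id)
            if allele.expected_size_bp is not None:
                size = float(allele.expected_size_bp)
            elif allele_id in wt_sizes:
                size = float(wt_sizes[allele_id])
            else:
                size = float(sum(allele.size_range)) / 2
            for dye in sorted(allele.dye_set, key=lambda d: d.name):
                if cfg.peak_dropout and rng.random() < cfg.peak_dropout:
                    continue
                noise = rng.normal(0.0, cfg.peak_noise_sd) if cfg.peak_noise_sd else 0.0
                peaks.append(Peak(sample_id, dye, size + noise))
    return peaks


@dataclass
class MicrosatTruth:
    lineage: Dict[str, int]
    events: pd.DataFrame  # strain, locus, kind in {VNTR, LOH}


def gen_microsat_population(
    cfg: SimConfig, loci: Optional[Sequence[LocusDef]] = None
) -> Tuple[MicrosatTable, MicrosatTruth]:
    """Clonal microsatellite population with a logged mutation history.

    Each lineage gets a founder diploid genotype whose allele repeat counts
    are drawn from a lineage-specific block; blocks are spaced
    ``founder_block_step`` repeat steps apart, so distinct lineages are many
    mutation steps from each other at every locus while clones within a
    lineage differ only by the applied VNTR (+-1 repeat step) and LOH
    (heterozygote -> homozygote) events.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = list(loci) if loci is not None else load_loci()
    L = len(loci)
    strains, rows = [], []
    lineage_of: Dict[str, int] = {}
    events = []
    for lin in range(cfg.n_lineages):
        lo = 20 + lin * cfg.founder_block_step
        founder = np.empty((L, 2))
        for j, locus in enumerate(loci):
            reps = rng.integers(lo, lo + cfg.founder_block_width + 1, size=2)
            founder[j] = np.sort(reps) * locus.motif_len
        for c in range(cfg.clone_size):
            sid = f"L{lin}_c{c:02d}"
            strains.append(sid)
            lineage_of[sid] = lin
            geno = founder.copy()
            for j, locus in enumerate(loci):
                if rng.random() < cfg.vntr_rate:
                    which = rng.integers(0, 2)
                    step = locus.motif_len * (1 if rng.random() < 0.5 else -1)
                    geno[j, which] += step
                    geno[j] = np.sort(geno[j])
                    events.append({"strain": sid, "locus": locus.name, "kind": "VNTR"})
                elif geno[j, 0] != geno[j, 1] and rng.random() < cfg.loh_rate:
                    keep = geno[j, rng.integers(0, 2)]
                    geno[j] = (keep, keep)
                    events.append({"strain": sid, "locus": locus.name, "kind": "LOH"})
            rows.append(geno)
    table = MicrosatTable(strains, loci, np.stack(rows))
    truth = MicrosatTruth(
        lineage=lineage_of,
        events=pd.DataFrame(events, columns=["strain", "locus", "kind"]),
    )
    return table, truth


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant_amplicon(
    rng,
    fwd: Primer,
    rev: Primer,
    size: int,
    all_primer_seqs: Sequence[str],
    flank: int = 60,
    max_tries: int = 50,
) -> str:
    """Background sequence with one planted convergent primer pair.

    Product size is the 5' end of the forward primer through the 5' end of
    the reverse primer inclusive.  Backgrounds containing a spurious primer
    site are re-drawn (20-mers in random sequence make this vanishingly
    rare, but the retry is bounded and checked).
    """
    inner = size - len(fwd.sequence) - len(rev.sequence)
    if inner < 0:
        raise ValueError(f"product size {size} shorter than the two primers")
    for _ in range(max_tries):
        seq = (
            _random_dna(rng, flank)
            + fwd.sequence
            + _random_dna(rng, inner)
            + revcomp(rev.sequence)
            + _random_dna(rng, flank)
        )
        planted = {fwd.sequence, revcomp(rev.sequence)}
        spurious = False
        for p in all_primer_seqs:
            for probe in (p, revcomp(p)):
                expected = 1 if probe in planted else 0
                if seq.count(probe) != expected:
                    spurious = True
        if not spurious:
            return seq
    raise RuntimeError("could not place primer sites without collisions")


#: amplicons of the four reference strains: template id -> (fwd, rev, size)
REFERENCE_STRAIN_PLAN = {
    "SB": [("chrVIII", "1189", "1190", 604),
           ("chrXV", "1191", "1192", 702),
           ("chrXVI", "1193", "1194", 991)],
    "GN": [("chrVIII", "1189", "1190", 667),
           ("chrXV", "1191", "1192", 702),
           ("XV-t-XVI_junction", "1191", "1194", 496)],
    "F10": [("chrVIII", "1189", "1190", 604),
            ("VIII-t-XVI_junction", "1189", "1194", 555)],
    "P5": [("inv-XVI_junction", "1196", "1194", 781)],
}


def gen_templates(panel: AllelePanel, seed: int = 0) -> Dict[str, List[Template]]:
    """Synthetic FASTA-ready templates for the reference strains.

    Returns, per reference strain (SB wild type, GN carrying XV-t-XVI, F10
    carrying VIII-t-XVI, P5 carrying inv-XVI), templates whose predicted
    amplicons are exactly that strain's published product sizes and dye
    pairs.  The sequences are synthetic stand-ins — random backgrounds with
    planted primer sites — not the deposited allele sequences.
    """
    rng = np.random.default_rng(seed)
    primer_seqs = [seq for seq, _dye in panel.primers.values()]

    def primer(name: str) -> Primer:
        seq, dye = panel.primers[name]
        return Primer(name, seq, dye)

    out: Dict[str, List[Template]] = {}
    for strain, plan in REFERENCE_STRAIN_PLAN.items():
        templates = []
        for region, fwd, rev, size in plan:
            seq = _plant_amplicon(rng, primer(fwd), primer(rev), size, primer_seqs)
            templates.append(Template(id=f"{strain}_{region}", sequence=seq))
        out[strain] = templates
    return out


@dataclass
class GrowthTruthParams:
    K: float
    nu: float
    k: float
    t_m: float
    mu_max: float
    lag_time_h: float
    lag_censored: bool


def richards_truth(
    K: float, nu: float, k: float, t_m: float, time_h: np.ndarray,
    baseline: float = 0.0,
) -> GrowthTruthParams:
    """Noiseless mu_max and lag implied by a Richards parameter set.

    With a positive ``baseline`` the curve is floored at the inoculum OD
    (cultures hold their inoculum density through the lag phase instead of
    following the Richards tail toward zero); mu_max is then the maximum
    log-slope of the floored curve on a fine grid.
    """
    from .growth import mu_max_of_fit, richards_od

    y = np.maximum(richards_od(time_h, K, nu, k, t_m), baseline)
    if baseline > 0.0:
        fine = np.linspace(float(time_h[0]), float(time_h[-1]), 2001)
        yf = np.maximum(richards_od(fine, K, nu, k, t_m), baseline)
        mu = float(np.gradient(np.log(yf), fine).max())
    else:
        mu = mu_max_of_fit((K, nu, k, t_m), (float(time_h[0]), float(time_h[-1])))
    thr = 2.0 * y[0]
    above = np.nonzero(y >= thr)[0]
    if len(above) == 0:
        return GrowthTruthParams(K, nu, k, t_m, mu, float(time_h[-1]), True)
    i = int(above[0])
    if i == 0:
        lag = 0.0
    else:
        frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
        lag = float(time_h[i - 1] + frac * (time_h[i] - time_h[i - 1]))
    return GrowthTruthParams(K, nu, k, t_m, mu, lag, False)


#: per-configuration SO2 sensitivity: (lag delay h per 25 mg/L, rate loss
#: fraction per 75 mg/L).  Rearranged promoters are the more tolerant ones.
DEFAULT_SO2_SENSITIVITY = {
    "XVI-wt": (6.0, 0.45),
    "VIII-t-XVI^388": (4.0, 0.30),
    "VIII-t-XVI^478": (1.0, 0.08),
    "VIII-t-XVI^555": (3.5, 0.28),
    "XV-t-XVI": (1.2, 0.10),
    "inv-XVI": (1.5, 0.12),
}


def gen_growth_curves(
    cfg: SimConfig,
    sensitivity: Optional[Mapping[str, Tuple[float, float]]] = None,
    zero_effects: bool = False,
) -> Tuple[List["GrowthCurve"], pd.DataFrame]:
    """Richards growth curves for the full tolerance-assay design.

    The design is all promoter configurations x SO2 doses x strains x
    replicates on a shared time grid.  SO2 enters the truth as a delay of
    t_m (longer lag) and a multiplicative loss on k (slower growth), scaled
    per configuration; ``zero_effects=True`` removes both factor effects
    (null data for calibration).  Returns the curves and a truth table with
    the noiseless mu_max and lag per curve.
    """
    from .growth import GrowthCurve, richards_od

    rng = np.random.default_rng(cfg.seed)
    sens = dict(sensitivity or DEFAULT_SO2_SENSITIVITY)
    t = np.linspace(cfg.growth_time_h[0], cfg.growth_time_h[1], cfg.growth_n_points)
    curves: List[GrowthCurve] = []
    truth_rows = []
    K_true, nu_true = 1.4, 1.0
    # anchor: with t_m = ln(K/od0 - 1)/k the curve starts exactly at the
    # inoculum OD; an SO2 delay then holds it at the inoculum floor
    anchor = np.log(K_true / cfg.od_baseline - 1.0)
    for config in GROWTH_CONFIGS:
        lag_per_dose, rate_loss = sens.get(config, (3.0, 0.2))
        for s in range(cfg.n_strains_per_config):
            strain_id = f"{config}|s{s}"
            if zero_effects:
                # flat truth: residual OD noise is the only variance source
                k_strain = 0.28
            else:
                k_strain = 0.28 * rng.uniform(0.9, 1.1)
            for so2 in SO2_LEVELS:
                if zero_effects:
                    k_true, delay = k_strain, 0.0
                else:
                    k_true = k_strain * (1.0 - rate_loss * so2 / 75.0)
                    delay = lag_per_dose * so2 / 25.0
                tm_true = anchor / k_true + delay
                tr = richards_truth(
                    K_true, nu_true, k_true, tm_true, t, baseline=cfg.od_baseline
                )
                for rep in range(cfg.n_replicates):
                    y = np.maximum(
                        richards_od(t, K_true, nu_true, k_true, tm_true),
                        cfg.od_baseline,
                    )
                    y = np.clip(y + rng.normal(0.0, cfg.od_noise_sd, size=t.shape), 1e-4, None)
                    curves.append(
                        GrowthCurve(
                            strain_id=strain_id,
                            time_h=t,
                            od_raw=y,
                            chr16_config=config,
                            so2_mg_per_l=so2,
                            replicate=rep + 1,
                        )
                    )
                    truth_rows.append(
                        {
                            "strain_id": strain_id,
                            "chr16_config": config,
                            "so2": so2,
                            "replicate": rep + 1,
                            "K": K_true, "nu": nu_true, "k": k_true, "t_m": tm_true,
                            "mu_max": tr.mu_max,
                            "lag_time_h": tr.lag_time_h,
                            "lag_censored": tr.lag_censored,
                            # floor active: the curve deviates from a pure
                            # Richards shape during the lag phase
                            "floored": bool(
                                richards_od(t[0], K_true, nu_true, k_true, tm_true)
                                < cfg.od_baseline * (1 - 1e-9)
                            ),
                        }
                    )
    return curves, pd.DataFrame(truth_rows)
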