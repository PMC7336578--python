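"""End-to-end orchestration: decode -> genotype -> popgen -> stats -> isogenic
-> growth, with every stage output written under one result directory."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import allele_stats, growth as growth_mod, io as io_mod, isogenic, popgen
from .panel import AllelePanel, call_chr16_genotype, classify_configuration, decode_peaks, load_panel

log = logging.getLogger("ssu1_checkup")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunManifest:
    """Inputs, thresholds and seed of one pipeline run.

    Thresholds default to the published analysis settings: +-3 bp sizing
    tolerance, >= 12 of 15 typed loci, 0.15 Bruvo clone cutoff, 0.106
    intra-group bound.  The manifest is echoed into the output directory for
    provenance.
    """

    out_dir: str
    peaks_path: Optional[str] = None
    genotypes_path: Optional[str] = None
    metadata_path: Optional[str] = None
    growth_path: Optional[str] = None
    seed: int = 0
    size_tolerance_bp: float = 3.0
    min_loci: int = 12
    bruvo_cutoff: float = 0.15
    isogenic_max_bruvo: float = 0.106
    isogenic_max_diff_loci: int = 2
    k_max: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.bruvo_cutoff < 1):
            raise ValueError("bruvo_cutoff must be in (0, 1)")
        if not (0 < self.isogenic_max_bruvo < 1):
            raise ValueError("isogenic_max_bruvo must be in (0, 1)")
        if self.size_tolerance_bp <= 0:
            raise ValueError("size_tolerance_bp must be positive")


def call_genotypes(peaks_by_sample, panel: AllelePanel) -> pd.DataFrame:
    """Decode peaks per sample and tabulate chromosome XVI genotypes."""
    rows = []
    for sample_id in sorted(peaks_by_sample):
        decoded = decode_peaks(peaks_by_sample[sample_id], panel)
        g = call_chr16_genotype(decoded, panel)
        flags = classify_configuration(g, panel)
        rows.append(
            {
                "sample_id": sample_id,
                "cen16_alleles": ";".join(g.cen16_alleles),
                "zygosity": g.zygosity,
                "copy_number": g.copy_number,
                "label": flags.label,
                "has_CR": flags.has_CR,
                "other_alleles": ";".join(sorted(g.other_alleles)),
                "unassigned_peaks": len(decoded.unassigned),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(manifest: RunManifest) -> Dict[str, object]:
    """Execute every stage the manifest has inputs for.

    Stage order mirrors the published analysis: fragment decoding, genotype
    calling, locus-coverage filtering, Bruvo distances, clone collapsing,
    k-means/BIC grouping, neighbor joining, allele statistics, isogenic
    heterogeneity, growth kinetics.  The first hard error aborts with a
    stage-named message; a missing optional input skips its stage with a
    warning.
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2)
    )
    results: Dict[str, object] = {}
    panel = load_panel()
    if manifest.size_tolerance_bp != panel.size_tolerance_bp:
        panel.size_tolerance_bp = manifest.size_tolerance_bp

    geno_df = None
    if manifest.peaks_path:
        try:
            peaks = io_mod.read_peak_table(manifest.peaks_path)
            geno_df = call_genotypes(peaks, panel)
            geno_df.to_csv(out / "chr16_genotypes.tsv", sep="\t", index=False)
            results["chr16_genotypes"] = geno_df
            log.info("decode: %d samples, %d without amplification",
                     len(geno_df), int((geno_df["zygosity"] == "no_amplification").sum()))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("decode", str(exc)) from exc
    else:
        log.warning("no peak table given; decode stage skipped")

    table = None
    if manifest.genotypes_path:
        try:
            loci = popgen.load_loci()
            table = io_mod.read_genotype_table(manifest.genotypes_path, loci)
            n_before = len(table)
            table = popgen.filter_by_locus_coverage(table, manifest.min_loci)
            log.info("filter: %d of %d strains kept (>= %d loci)",
                     len(table), n_before, manifest.min_loci)
            if len(table) < 2:
                raise ValueError("fewer than 2 strains after filtering")
            matrix = popgen.bruvo_matrix(table)
            io_mod.write_distance_matrix(matrix, out / "bruvo_distances.tsv")
            clones = popgen.collapse_clones(matrix, manifest.bruvo_cutoff)
            pd.DataFrame(
                [
                    {"representative": rep, "members": ";".join(comp)}
                    for rep, comp in zip(clones.representatives, clones.components)
                ]
            ).to_csv(out / "clone_sets.tsv", sep="\t", index=False)
            results["microsat_table"] = table
            results["bruvo"] = matrix
            results["clones"] = clones
            log.info("collapse: %d representatives, %d clones removed",
                     len(clones.representatives), len(clones.clones_removed))

            reps = clones.representatives
            if len(reps) >= 3:
                rep_table = table.subset(reps)
                k_max = min(manifest.k_max, len(reps))
                clus = popgen.cluster_kmeans_bic(rep_table, k_max, manifest.seed)
                pd.DataFrame(
                    [{"strain_id": s, "group": g} for s, g in clus.assignment.items()]
                ).to_csv(out / "cluster_assignment.tsv", sep="\t", index=False)
                results["clusters"] = clus
                rep_matrix = popgen.bruvo_matrix(rep_table)
                newick = popgen.nj_tree(rep_matrix)
                (out / "nj_tree.nwk").write_text(newick + "\n")
                results["nj_newick"] = newick
        except StageError:
            raise
        except Exception as exc:
            raise StageError("popgen", str(exc)) from exc
    else:
        log.warning("no genotype matrix given; popgen stages skipped")

    if geno_df is not None and manifest.metadata_path:
        try:
            meta = pd.read_csv(manifest.metadata_path, sep="\t", dtype=str)
            records = _join_records(geno_df, meta, panel)
            freq = allele_stats.allele_frequencies(records, by="population")
            freq.to_csv(out / "allele_frequencies.tsv", sep="\t", index=False)
            hom = allele_stats.homozygosity_pct(records, by="population")
            hom.to_csv(out / "homozygosity.tsv", sep="\t", index=False)
            occ = allele_stats.cr_occurrence(records, panel, by="population")
            occ.to_csv(out / "cr_occurrence.tsv", sep="\t", index=False)
            results["allele_frequencies"] = freq
            results["homozygosity"] = hom
            results["cr_occurrence"] = occ
        except StageError:
            raise
        except Exception as exc:
            raise StageError("stats", str(exc)) from exc

    if table is not None and "bruvo" in results:
        try:
            groups = isogenic.form_groups(
                table, results["bruvo"],
                max_bruvo=manifest.isogenic_max_bruvo,
                max_diff_loci=manifest.isogenic_max_diff_loci,
            )
            rows = []
            for g in groups:
                geno = {
                    s: {
                        l.name: (None if np.isnan(table.alleles[table.strains.index(s), j]).any()
                                 else tuple(table.alleles[table.strains.index(s), j]))
                        for j, l in enumerate(table.loci)
                    }
                    for s in g.members
                }
                events = isogenic.classify_group_events(g, geno)
                fr = isogenic.heterogeneity_fractions(g, events)
                fr.update({"group": g.group_id, "n_strains": g.size,
                           "max_bruvo": g.max_bruvo})
                rows.append(fr)
            per_group = pd.DataFrame(rows)
            if len(per_group):
                per_group.to_csv(out / "isogenic_heterogeneity.tsv", sep="\t", index=False)
            results["isogenic_groups"] = groups
            results["isogenic_fractions"] = per_group
            log.info("isogenic: %d groups of size >= 3", len(groups))
        except Exception as exc:
            raise StageError("isogenic", str(exc)) from exc

    if manifest.growth_path:
        try:
            curves = io_mod.read_growth_table(manifest.growth_path)
            rows = []
            for c in curves:
                p = growth_mod.fit_richards(c, already_corrected=True, seed=manifest.seed)
                rows.append(
                    {"strain_id": c.strain_id, "chr16_config": c.chr16_config,
                     "so2": c.so2_mg_per_l, "replicate": c.replicate,
                     "mu_max": p.mu_max, "lag_time_h": p.lag_time_h,
                     "lag_censored": p.lag_censored, "converged": p.converged}
                )
            fits = pd.DataFrame(rows)
            fits.to_csv(out / "growth_fits.tsv", sep="\t", index=False)
            results["growth_fits"] = fits
            n_cens = int(fits["lag_censored"].sum())
            log.info("growth: %d curves fitted, %d censored lags", len(fits), n_cens)
            anova_rows = []
            for trait in ("mu_max", "lag_time_h"):
                res = growth_mod.anova_lm1(
                    fits, trait=trait, censored_col="lag_censored"
                )
                for term, pct in res.pct_variance.items():
                    anova_rows.append(
                        {"trait": trait, "term": term, "pct_variance": pct,
                         "p_value": res.p_values.get(term, float("nan")),
                         "levene_p": res.levene_p}
                    )
            pd.DataFrame(anova_rows).to_csv(out / "growth_anova.tsv", sep="\t", index=False)
            results["growth_anova"] = pd.DataFrame(anova_rows)
        except Exception as exc:
            raise StageError("growth", str(exc)) from exc
    else:
        log.warning("no growth table given; growth stage skipped")

    return results


def _join_records(geno_df: pd.DataFrame, meta: pd.DataFrame, panel: AllelePanel):
    from .panel import Chr16Genotype

    meta = meta.set_index("strain_id")
    records = []
    for _, row in geno_df.iterrows():
        sid = row["sample_id"]
        alleles = tuple(a for a in str(row["cen16_alleles"]).split(";") if a and a != "nan")
        g = Chr16Genotype(
            cen16_alleles=alleles,
            copy_number=int(row["copy_number"]),
            zygosity=row["zygosity"],
        )
        m = meta.loc[sid] if sid in meta.index else None
        records.append(
            allele_stats.StrainRecord(
                strain_id=sid,
                population=(m["population"] if m is not None else "NA"),
                genotype=g,
                environment=(m.get("environment", "NA") if m is not None else "NA"),
                matrix=(m.get("matrix", "NA") if m is not None else "NA"),
            )
        )
    return records
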