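"""Readers and writers for the pipeline's tabular and sequence formats.

Peak tables are the tidy TSV/CSV shape of GeneMapper/GeneMarker exports
(sample_id, dye, size_bp, optional height); genotype matrices are one row
per strain with one "a/b" column per locus; templates travel as FASTA;
distance matrices as square TSV; trees as newick.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .insilico import Template
from .panel import DyeChannel, Peak
from .popgen import DistanceMatrix, LocusDef, MicrosatTable

log = logging.getLogger("ssu1_checkup")


class TableFormatError(ValueError):
    pass


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_peak_table(path) -> Dict[str, List[Peak]]:
    """Load a peak export and group peaks by sample.

    Rows in the LIZ channel (the size standard) are dropped with a logged
    count; malformed rows fail loudly with their row number.
    """
    df = _read_delimited(path)
    required = {"sample_id", "dye", "size_bp"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[str, List[Peak]] = {}
    n_liz = 0
    for idx, row in df.iterrows():
        dye_name = str(row["dye"]).strip()
        try:
            dye = DyeChannel(dye_name)
        except ValueError:
            raise TableFormatError(f"{path}: row {idx + 2}: unknown dye {dye_name!r}")
        if dye is DyeChannel.LIZ:
            n_liz += 1
            continue
        try:
            size = float(row["size_bp"])
        except (TypeError, ValueError):
            raise TableFormatError(
                f"{path}: row {idx + 2}: non-numeric size {row['size_bp']!r}"
            )
        height = None
        if "height" in df.columns and pd.notna(row.get("height")):
            height = float(row["height"])
        out.setdefault(str(row["sample_id"]), []).append(
            Peak(str(row["sample_id"]), dye, size, height)
        )
    if n_liz:
        log.info("dropped %d LIZ size-standard rows from %s", n_liz, path)
    return out


def write_peak_table(peaks: Sequence[Peak], path) -> None:
    rows = [
        {"sample_id": p.sample_id, "dye": p.dye.name, "size_bp": p.size_bp,
         "height": p.height}
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_table(path, loci: Sequence[LocusDef]) -> MicrosatTable:
    """Load a strain x locus genotype matrix.

    One column per locus named after it; cells are "a/b" for heterozygotes,
    a single size for homozygotes (duplicated on load, as in routine
    microsatellite scoring), or blank for missing.
    """
    df = _read_delimited(path)
    if "strain_id" not in df.columns:
        raise TableFormatError(f"{path}: missing strain_id column")
    locus_names = [l.name for l in loci]
    unknown = set(df.columns) - {"strain_id"} - set(locus_names)
    if unknown:
        raise TableFormatError(f"{path}: unknown locus columns {sorted(unknown)}")
    strains = df["strain_id"].astype(str).tolist()
    alleles = np.full((len(strains), len(loci), 2), np.nan)
    for j, name in enumerate(locus_names):
        if name not in df.columns:
            continue
        for i, cell in enumerate(df[name]):
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            parts = str(cell).split("/")
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise TableFormatError(
                    f"{path}: row {i + 2}, locus {name}: bad genotype {cell!r}"
                )
            if len(vals) == 1:
                vals = vals * 2
            if len(vals) != 2:
                raise TableFormatError(
                    f"{path}: row {i + 2}, locus {name}: need 1 or 2 alleles"
                )
            alleles[i, j] = sorted(vals)
    return MicrosatTable(strains, list(loci), alleles)


def write_genotype_table(t: MicrosatTable, path) -> None:
    rows = []
    for i, s in enumerate(t.strains):
        row = {"strain_id": s}
        for j, locus in enumerate(t.loci):
            pair = t.alleles[i, j]
            if np.isnan(pair).any():
                row[locus.name] = ""
            elif pair[0] == pair[1]:
                row[locus.name] = _fmt(pair[0])
            else:
                row[locus.name] = f"{_fmt(pair[0])}/{_fmt(pair[1])}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def write_distance_matrix(m: DistanceMatrix, path) -> None:
    pd.DataFrame(m.values, index=m.ids, columns=m.ids).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_templates_fasta(templates: Dict[str, List[Template]], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="synthetic template")
        for group in templates.values()
        for t in group
    ]
    SeqIO.write(records, str(path), "fasta")


def read_templates_fasta(path) -> List[Template]:
    return [
        Template(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_growth_table(curves, path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.time_h, c.od_raw):
            rows.append(
                {"strain_id": c.strain_id, "chr16_config": c.chr16_config,
                 "so2": c.so2_mg_per_l, "replicate": c.replicate,
                 "time_h": t, "od": od}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_growth_table(path) -> List:
    from .growth import GrowthCurve

    df = pd.read_csv(path, sep="\t")
    curves = []
    keys = ["strain_id", "chr16_config", "so2", "replicate"]
    for (sid, config, so2, rep), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain_id=str(sid),
                time_h=g["time_h"].to_numpy(),
                od_raw=g["od"].to_numpy(),
                chr16_config=str(config),
                so2_mg_per_l=float(so2),
                replicate=int(rep),
            )
        )
    return curves
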