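"""File readers and writers for panels, markers, phenotypes and ground truth.

Genotypes travel as VCF (one pseudo-sample per accession, homozygous calls —
the panel is inbred, so heterozygous calls are set missing under the default
policy) or as a wide TSV matrix.  Phenotypes are long-format CSV; marker
definitions, allele matrices and summary tables are TSV; ground truth and
run summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .snpldb import MISSING, SnpPanel, SnpldbMarker


class IoError(ValueError):
    pass


PHENOTYPE_COLUMNS = ["accession_id", "subpop", "group", "replicate", "block",
                     "timepoint", "trait", "value"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(panel: SnpPanel, path: str | Path) -> None:
    """Write the panel as VCF 4.2 with homozygous diploid genotypes."""
    path = Path(path)
    gt_map = {0: "0/0", 1: "1/1", MISSING: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haploqtl\n")
        for c in dict.fromkeys(panel.chrom.tolist()):
            length = int(panel.pos[panel.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.accession_ids) + "\n")
        for j in range(panel.n_snps):
            calls = "\t".join(gt_map[int(g)] for g in panel.genotypes[:, j])
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j]}\tsnp{j}\t"
                     f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path, het_policy: str = "missing") -> SnpPanel:
    """Read a VCF of inbred lines into a :class:`SnpPanel`.

    ``het_policy`` controls heterozygous calls: "missing" (default) codes
    them missing; "error" raises.  The panel is sorted by chromosome and
    position.
    """
    from cyvcf2 import VCF

    if het_policy not in ("missing", "error"):
        raise IoError(f"unknown heterozygote policy {het_policy!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for i, variant in enumerate(vcf):
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = variant.gt_types
        codes[gt == 0] = 0
        codes[gt == 3] = 1
        if (gt == 1).any():
            if het_policy == "error":
                raise IoError(
                    f"heterozygous call at record {i + 1} ({variant.CHROM}:"
                    f"{variant.POS}) in an inbred panel"
                )
            codes[gt == 1] = MISSING
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        ref.append(variant.REF)
        alt.append(variant.ALT[0] if variant.ALT else ".")
        rows.append(codes)
    if not rows:
        raise IoError(f"no variant records in {path}")
    chrom_arr = np.array(chrom)
    try:
        chrom_arr = chrom_arr.astype(np.int64)
    except ValueError:
        pass
    panel = SnpPanel(
        accession_ids=samples,
        chrom=chrom_arr,
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        genotypes=np.vstack(rows).T,
    )
    order = np.lexsort((panel.pos, panel.chrom))
    panel = panel.take_snps(order)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# TSV genotypes / metadata / phenotypes
# ---------------------------------------------------------------------------

def write_genotype_tsv(panel: SnpPanel, path: str | Path) -> None:
    df = pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.pos,
        "ref": panel.ref, "alt": panel.alt,
    })
    geno = pd.DataFrame(panel.genotypes.T, columns=panel.accession_ids)
    pd.concat([df, geno], axis=1).to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> SnpPanel:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    missing_cols = [c for c in meta_cols if c not in df.columns]
    if missing_cols:
        raise IoError(f"genotype TSV lacks columns {missing_cols}")
    samples = [c for c in df.columns if c not in meta_cols]
    panel = SnpPanel(
        accession_ids=samples,
        chrom=df["chrom"].to_numpy(),
        pos=df["pos"].to_numpy(np.int64),
        ref=df["ref"].to_numpy(),
        alt=df["alt"].to_numpy(),
        genotypes=df[samples].to_numpy(np.int8).T,
    )
    order = np.lexsort((panel.pos, panel.chrom))
    panel = panel.take_snps(order)
    panel.validate()
    return panel


def read_genotypes(path: str | Path, format: str = "vcf",
                   het_policy: str = "missing") -> SnpPanel:
    if format == "vcf":
        return read_vcf(path, het_policy=het_policy)
    if format == "tsv":
        return read_genotype_tsv(path)
    raise IoError(f"unknown genotype format {format!r}")


def write_metadata(panel: SnpPanel, path: str | Path) -> None:
    pd.DataFrame({
        "accession_id": panel.accession_ids,
        "subpop": panel.subpop if panel.subpop is not None else "",
    }).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "accession_id" not in df.columns or "subpop" not in df.columns:
        raise IoError("metadata needs accession_id and subpop columns")
    return df


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    lacking = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if lacking:
        raise IoError(f"phenotype CSV lacks columns {lacking}")
    return df


# ---------------------------------------------------------------------------
# markers and matrices
# ---------------------------------------------------------------------------

def write_marker_definitions(markers: list[SnpldbMarker], path: str | Path) -> None:
    rows = [{
        "marker_id": m.marker_id, "chrom": m.chrom, "start": m.start,
        "end": m.end, "n_snps": len(m.snp_indices), "n_alleles": m.n_alleles,
        "haplotypes": ",".join(m.haplotypes),
        "frequencies": ",".join(f"{f:.6g}" for f in m.frequencies),
    } for m in markers]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_marker_codes(markers: list[SnpldbMarker], accession_ids: list[str],
                       path: str | Path) -> None:
    df = pd.DataFrame({m.marker_id: m.codes for m in markers},
                      index=accession_ids)
    df.index.name = "accession_id"
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")
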