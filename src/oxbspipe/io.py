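"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as TSV (probe_id, chrom, pos, then one column per sample;
pos written 1-based as on array manifests, converted to the internal
0-based convention on load), sample sheets as CSV, gene models as GFF3
(1-based inclusive) and BED12, CGIs and chromatin states as BED6, gene
sets as CSV, and run manifests as JSON. All coordinate conversions are
involutions: write -> load reproduces the in-memory object.
"""
from __future__ import annotations

import datetime
import json
import os

import gffutils
import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    AlignmentError,
    BetaMatrix,
    FormatError,
    GenomeAnnotation,
    TruthMethylome,
    validate_sample_sheet,
)

META_COLS = ["chrom", "pos"]


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------

def write_beta_matrix(matrix: BetaMatrix, beta_path, detection_path, coverage_path=None) -> None:
    def dump(frame, path):
        out = matrix.probes[META_COLS].copy()
        out["pos"] = out["pos"] + 1  # manifest-style 1-based
        out = pd.concat([out, frame], axis=1)
        out.to_csv(path, sep="\t", index_label="probe_id")

    dump(matrix.beta, beta_path)
    dump(matrix.detection_p, detection_path)
    if coverage_path is not None:
        dump(matrix.coverage, coverage_path)


def _read_matrix_tsv(path) -> tuple:
    table = pd.read_csv(path, sep="\t", index_col="probe_id")
    missing = [c for c in META_COLS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    probes = table[META_COLS].copy()
    probes["pos"] = probes["pos"].astype(int) - 1
    values = table.drop(columns=META_COLS)
    return probes, values


def load_beta_matrix(beta_path, detection_path, coverage=1000, channel="BS") -> BetaMatrix:
    """Load a beta matrix with its detection p-values.

    ``coverage`` is either a path to a coverage TSV of the same shape or a
    scalar pseudo-coverage applied to every cell. Out-of-range values are
    rejected with the offending probe and sample named.
    """
    probes, beta = _read_matrix_tsv(beta_path)
    probes_d, detp = _read_matrix_tsv(detection_path)
    if not probes.index.equals(probes_d.index):
        raise AlignmentError(f"probe sets differ between {beta_path} and {detection_path}")
    if isinstance(coverage, (int, float)):
        cov = pd.DataFrame(float(coverage), index=beta.index, columns=beta.columns)
    else:
        probes_c, cov = _read_matrix_tsv(coverage)
        if not probes.index.equals(probes_c.index):
            raise AlignmentError(f"probe sets differ between {beta_path} and {coverage}")
    return BetaMatrix(beta=beta, detection_p=detp, coverage=cov, probes=probes, channel=channel)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def load_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, dtype=str))


def write_truth(truth: TruthMethylome, path) -> None:
    out = truth.probes[META_COLS].copy()
    out["pos"] = out["pos"] + 1
    for cond in truth.m.columns:
        out[f"m_{cond}"] = truth.m[cond]
        out[f"h_{cond}"] = truth.h[cond]
    out.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def write_annotation(annotation: GenomeAnnotation, out_dir) -> dict:
    """Write gene models (GFF3 + BED12), CGIs/states (BED6), gene sets (CSV).

    Returns the map of written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "gff": os.path.join(out_dir, "genes.gff3"),
        "bed12": os.path.join(out_dir, "genes.bed"),
        "cgi": os.path.join(out_dir, "cgi.bed"),
        "states": os.path.join(out_dir, "chrom_states.bed"),
        "gene_sets": os.path.join(out_dir, "gene_sets.csv"),
        "chrom_sizes": os.path.join(out_dir, "chrom.sizes"),
    }
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in annotation.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for gid, row in annotation.genes.iterrows():
            fh.write(f"{row['chrom']}\toxbspipe\tgene\t{row['start'] + 1}\t{row['end']}\t.\t"
                     f"{row['strand']}\t.\tID={gid}\n")
            for i, (s, e) in enumerate(sorted(annotation.exons.get(gid, [])), start=1):
                fh.write(f"{row['chrom']}\toxbspipe\texon\t{s + 1}\t{e}\t.\t"
                         f"{row['strand']}\t.\tID={gid}.exon{i};Parent={gid}\n")
    with open(paths["bed12"], "w") as fh:
        for gid, row in annotation.genes.iterrows():
            exons = sorted(annotation.exons.get(gid, [(row["start"], row["end"])]))
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - row["start"]) for s, e in exons) + ","
            fh.write("\t".join(map(str, [
                row["chrom"], row["start"], row["end"], gid, 0, row["strand"],
                row["start"], row["end"], 0, len(exons), sizes, starts])) + "\n")
    with open(paths["cgi"], "w") as fh:
        for i, (_, row) in enumerate(annotation.cgis.iterrows(), start=1):
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\tCGI{i}\t0\t.\n")
    with open(paths["states"], "w") as fh:
        for _, row in annotation.chrom_states.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{row['state']}\t0\t.\n")
    annotation.gene_sets.rename("gene_set").to_csv(paths["gene_sets"], index_label="gene_id")
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in annotation.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    return paths


def _read_bed(path, with_name=False):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{ln}: interval end <= start")
            row = {"chrom": chrom, "start": start, "end": end}
            if with_name:
                row["name"] = parts[3] if len(parts) > 3 else ""
            rows.append(row)
    cols = ["chrom", "start", "end"] + (["name"] if with_name else [])
    return pd.DataFrame(rows, columns=cols)


def load_annotation(gff_path, cgi_bed, states_bed, gene_sets_csv,
                    chrom_sizes_path=None) -> GenomeAnnotation:
    """Assemble a GenomeAnnotation from GFF3 + BED + CSV inputs.

    GFF3 coordinates (1-based inclusive) and BED coordinates (0-based
    half-open) are unified onto the internal 0-based half-open convention.
    Genes present in the GFF but absent from the gene-set table are
    labelled "none" with a warning.
    """
    db = gffutils.create_db(str(gff_path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes, exons = [], {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        start, end = gene.start - 1, gene.end
        tss = start if gene.strand == "+" else end
        genes.append({"gene_id": gid, "chrom": gene.seqid, "start": start,
                      "end": end, "strand": gene.strand, "tss": tss})
        exons[gid] = sorted((child.start - 1, child.end)
                            for child in db.children(gene, featuretype="exon"))
    genes_df = pd.DataFrame(genes).set_index("gene_id")

    chrom_sizes = {}
    if chrom_sizes_path is not None:
        with open(chrom_sizes_path) as fh:
            for line in fh:
                chrom, size = line.split()
                chrom_sizes[chrom] = int(size)
    else:
        for directive in db.directives:
            if directive.startswith("sequence-region"):
                _, chrom, _, end = directive.split()
                chrom_sizes[chrom] = int(end)
        if not chrom_sizes:
            chrom_sizes = dict(genes_df.groupby("chrom")["end"].max() + 100_000)

    cgis = _read_bed(cgi_bed)
    states = _read_bed(states_bed, with_name=True).rename(columns={"name": "state"})
    sets = pd.read_csv(gene_sets_csv).set_index("gene_id")["gene_set"]
    unknown = sets.index.difference(genes_df.index)
    if len(unknown):
        import warnings
        warnings.warn(f"gene_sets references unknown gene_ids (dropped): {list(unknown[:5])}")
        sets = sets.drop(unknown)
    sets = sets.reindex(genes_df.index).fillna("none")
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes_df, exons=exons,
                            cgis=cgis, chrom_states=states, gene_sets=sets)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def region_bed_score(fdr: float) -> int:
    """BED score for a region: -log10(FDR) * 100, capped at 1000."""
    if not np.isfinite(fdr) or fdr <= 0:
        return 1000
    return int(min(1000, round(-np.log10(fdr) * 100)))


def write_results(tables: dict, out_dir, manifest: dict | None = None) -> dict:
    """Write result tables as TSV (regions additionally as BED6) + manifest.

    ``tables`` maps a name to a DataFrame; names containing "regions" also
    produce a BED6 file scored by -log10 of the combined FDR. The manifest
    JSON records configuration, seeds and package versions.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, table in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        table.to_csv(path, sep="\t")
        paths[name] = path
        if "regions" in name and len(table) and {"chrom", "start", "end", "fdr"} <= set(table.columns):
            bed = os.path.join(out_dir, f"{name}.bed")
            with open(bed, "w") as fh:
                for i, (_, row) in enumerate(table.iterrows(), start=1):
                    fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}_{i}\t"
                             f"{region_bed_score(row['fdr'])}\t.\n")
            paths[f"{name}.bed"] = bed
    manifest = dict(manifest or {})
    manifest.setdefault("versions", {})
    manifest["versions"].update({
        "oxbspipe": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    })
    manifest["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    paths["manifest"] = mpath
    return paths


def write_dataset(out_dir, annotation, truth, bs, oxbs, sheet) -> dict:
    """Write a full simulated dataset (annotation, truth, matrices, sheet)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = write_annotation(annotation, out_dir)
    for channel, matrix in (("bs", bs), ("oxbs", oxbs)):
        beta = os.path.join(out_dir, f"beta_{channel}.tsv")
        detp = os.path.join(out_dir, f"detp_{channel}.tsv")
        cov = os.path.join(out_dir, f"coverage_{channel}.tsv")
        write_beta_matrix(matrix, beta, detp, cov)
        paths.update({f"beta_{channel}": beta, f"detp_{channel}": detp, f"coverage_{channel}": cov})
    sheet_path = os.path.join(out_dir, "samples.csv")
    write_sample_sheet(sheet, sheet_path)
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_truth(truth, truth_path)
    paths.update({"samples": sheet_path, "truth": truth_path})
    return paths
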