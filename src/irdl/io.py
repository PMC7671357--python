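"""Readers and writers for the formats the pipeline consumes and emits.

All coordinates are BED-style (0-based, half-open); the strand column is
mandatory.  Matrix TSVs carry feature ids in the first column and sample ids
in the header.  Writers emit deterministic column ordering; every pipeline
output starts with provenance comment lines (version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from irdl.features import OpennessInput, ProfileMatrix, openness_score
from irdl.genome import INFINITY_DISTANCE, GenomicFeature, PairRecord

INF_TOKEN = "inf"  # textual form of the cross-chromosome distance sentinel


# ---------------------------------------------------------------- annotations

def read_bed6(path, kind: str = "gene") -> list[GenomicFeature]:
    """Read BED6 (chrom, start, end, name, score ignored, strand)."""
    out: list[GenomicFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(cols)}")
            chrom, start, end, name, _score, strand = cols[:6]
            try:
                feat = GenomicFeature(name, chrom, strand, int(start), int(end), kind)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate feature id {name!r}")
            seen.add(name)
            out.append(feat)
    return out


def write_bed6(features: Iterable[GenomicFeature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


def read_gff3(path, kind_map: dict[str, str] | None = None) -> list[GenomicFeature]:
    """Thin GFF3 adapter: keeps records whose type maps to gene/lncRNA.

    GFF3 is 1-based inclusive; coordinates are converted to 0-based
    half-open.  The feature id is taken from the ``ID`` attribute.
    """
    kind_map = kind_map or {"gene": "gene", "lnc_RNA": "lncRNA", "lncRNA": "lncRNA"}
    out: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            if ftype not in kind_map:
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr_map.get("ID")
            if fid is None:
                raise ValueError(f"{path}:{lineno}: record has no ID attribute")
            out.append(
                GenomicFeature(fid, chrom, strand, int(start) - 1, int(end), kind_map[ftype])
            )
    return out


# ---------------------------------------------------------------- sequences

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=fid, description="") for fid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- matrices

def read_matrix(path, space: str) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing/ragged value in row {bad!r}")
    return ProfileMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        space=space,
    )


def write_matrix(matrix: ProfileMatrix, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------- pairs

def read_pairs(path, default_role: str = "candidate") -> list[PairRecord]:
    """Pair TSV: lncrna_id, gene_id, optional role, optional distance."""
    out: list[PairRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("lncrna_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            lnc, gene = cols[0], cols[1]
            role = cols[2] if len(cols) > 2 and cols[2] else default_role
            if role not in ("positive", "nearby_pool", "candidate"):
                raise ValueError(f"{path}:{lineno}: unknown role {role!r}")
            distance = INFINITY_DISTANCE
            if len(cols) > 3 and cols[3]:
                distance = INFINITY_DISTANCE if cols[3] == INF_TOKEN else float(cols[3])
            key = (lnc, gene)
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair {key}")
            seen.add(key)
            out.append(PairRecord(lnc, gene, role, distance))
    return out


def write_pairs(pairs: Iterable[PairRecord], path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("lncrna_id\tgene_id\trole\tdistance\n")
        for p in pairs:
            d = INF_TOKEN if np.isinf(p.distance) else repr(float(p.distance))
            fh.write(f"{p.lncrna_id}\t{p.gene_id}\t{p.role}\t{d}\n")


# ---------------------------------------------------------------- features

FEATURE_COLUMNS = ["seq_pcc", "expr_pcc", "open_pcc", "distance_feature"]


def write_feature_table(
    table: dict[tuple[str, str], tuple[float, float, float, float]],
    path,
    header_lines: list[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("lncrna_id\tgene_id\t" + "\t".join(FEATURE_COLUMNS) + "\n")
        for (lnc, gene), vec in table.items():
            fh.write(f"{lnc}\t{gene}\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def read_feature_table(path) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    return {
        (str(r.lncrna_id), str(r.gene_id)): (
            float(r.seq_pcc), float(r.expr_pcc), float(r.open_pcc), float(r.distance_feature)
        )
        for r in df.itertuples()
    }


# ---------------------------------------------------------------- openness

def read_openness_raw(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"feature_id", "sample_id", "X", "L", "Y", "L0", "delta"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: openness table needs columns {sorted(required)}")
    return df


def openness_matrix_from_raw(df: pd.DataFrame) -> ProfileMatrix:
    """Compute an openness ProfileMatrix from a raw (X, L, Y, L0, delta) table."""
    feature_ids = list(dict.fromkeys(df["feature_id"]))
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    fidx = {f: i for i, f in enumerate(feature_ids)}
    sidx = {s: i for i, s in enumerate(sample_ids)}
    values = np.full((len(feature_ids), len(sample_ids)), np.nan)
    for row in df.itertuples():
        values[fidx[row.feature_id], sidx[row.sample_id]] = openness_score(
            OpennessInput(X=row.X, L=row.L, Y=row.Y, L0=row.L0, delta=row.delta)
        )
    if np.isnan(values).any():
        raise ValueError("openness table does not cover every feature x sample cell")
    return ProfileMatrix(feature_ids, sample_ids, values, "openness")


# ---------------------------------------------------------------- misc tables

def read_sample_tissues(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[cols[0]] = cols[1]
    return out


def write_sample_tissues(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\n")
        for sid, tissue in mapping.items():
            fh.write(f"{sid}\t{tissue}\n")


def read_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def provenance_lines(cfg: dict, seed: int) -> list[str]:
    from irdl import __version__

    return [f"irdl {__version__}", f"seed {seed}", f"config {config_hash(cfg)}"]


# ---------------------------------------------------------------- datasets

def write_dataset(ds, outdir) -> dict[str, Path]:
    """Write a synthetic dataset in the exact formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_bed": outdir / "genes.bed",
        "lncrnas_bed": outdir / "lncrnas.bed",
        "sequences": outdir / "sequences.fasta",
        "gene_expr": outdir / "gene_expression.tsv",
        "lnc_expr": outdir / "lncrna_expression.tsv",
        "gene_open": outdir / "gene_openness.tsv",
        "lnc_open": outdir / "lncrna_openness.tsv",
        "openness_raw": outdir / "openness_raw.tsv",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_bed6([f for f in ds.features if f.kind == "gene"], paths["genes_bed"])
    write_bed6([f for f in ds.features if f.kind == "lncRNA"], paths["lncrnas_bed"])
    write_fasta(ds.sequences, paths["sequences"])
    write_matrix(ds.gene_expr_raw, paths["gene_expr"])
    write_matrix(ds.lnc_expr_raw, paths["lnc_expr"])
    write_matrix(ds.gene_open, paths["gene_open"])
    write_matrix(ds.lnc_open, paths["lnc_open"])
    ds.openness_raw.to_csv(paths["openness_raw"], sep="\t", index=False)
    write_pairs(ds.pairs, paths["pairs"])
    with open(paths["truth"], "w") as fh:
        fh.write("lncrna_id\tgene_id\tis_regulatory\n")
        for (lnc, gene), flag in ds.truth.items():
            fh.write(f"{lnc}\t{gene}\t{int(flag)}\n")
    return paths
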