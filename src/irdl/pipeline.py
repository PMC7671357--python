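"""End-to-end pipeline: features -> self-training -> summary -> tissues.

The pipeline reads annotations, sequences, expression and openness inputs,
computes the four per-pair features, runs the increasingly-learning loop to
grow the positive set, summarises the genomic properties of the identified
associations, and (when a sample-tissue map is supplied) assigns each
association its specific tissue.  Every output TSV starts with provenance
comment lines recording the package version, master seed and a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from irdl import io as irdl_io
from irdl.features import (
    DISTANCE_CAP,
    ProfileMatrix,
    log2_transform,
    pair_features,
)
from irdl.genome import GenomicFeature, PairRecord, genome_distance, summarize_pair_properties
from irdl.learner import FeatureTable, LearnerConfig, run_increasing_learning
from irdl.tissue import assign_specific_tissue

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and options for one end-to-end run."""

    genes_bed: str
    lncrnas_bed: str
    sequences_fasta: str
    gene_expr: str
    lnc_expr: str
    pairs: str
    out_dir: str
    master_seed: int
    # openness: either precomputed matrices or a raw count table
    gene_open: str | None = None
    lnc_open: str | None = None
    openness_raw: str | None = None
    sample_tissues: str | None = None
    learner: LearnerConfig = dataclasses.field(default_factory=LearnerConfig)
    log2_pseudocount: float = 1.0
    tss_mode: str = "strand_aware"
    distance_cap: float = DISTANCE_CAP
    pcc_cutoff: float = 0.7
    distance_cutoff: int = 100_000
    gene_high_threshold: float = 6.0
    lnc_high_threshold: float = 4.0

    def validate(self) -> None:
        required = [
            self.genes_bed, self.lncrnas_bed, self.sequences_fasta,
            self.gene_expr, self.lnc_expr, self.pairs,
        ]
        for p in required:
            if not Path(p).exists():
                raise FileNotFoundError(f"pipeline input does not exist: {p}")
        has_matrices = self.gene_open and self.lnc_open
        if not has_matrices and not self.openness_raw:
            raise ValueError("need either openness matrices or a raw openness table")

    def as_dict(self) -> dict:
        # the output location is not part of the analysis: identical inputs
        # and seed must hash identically wherever the results land
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return d


def compute_feature_table(
    pairs: list[PairRecord],
    features_by_id: dict[str, GenomicFeature],
    sequences: dict[str, str],
    gene_expr_log2: ProfileMatrix,
    lnc_expr_log2: ProfileMatrix,
    gene_open: ProfileMatrix,
    lnc_open: ProfileMatrix,
    tss_mode: str = "strand_aware",
    distance_cap: float = DISTANCE_CAP,
) -> FeatureTable:
    """Compute the 4-feature vector for every pair; fills pair distances."""
    if gene_expr_log2.sample_ids != lnc_expr_log2.sample_ids:
        raise ValueError("gene and lncRNA expression matrices have different sample order")
    if gene_open.sample_ids != lnc_open.sample_ids:
        raise ValueError("gene and lncRNA openness matrices have different sample order")
    table: FeatureTable = {}
    for pair in pairs:
        gene = features_by_id[pair.gene_id]
        lnc = features_by_id[pair.lncrna_id]
        pair.distance = genome_distance(gene, lnc, tss_mode)
        vec = pair_features(
            pair,
            sequences[pair.gene_id],
            sequences[pair.lncrna_id],
            gene_expr_log2.row(pair.gene_id),
            lnc_expr_log2.row(pair.lncrna_id),
            gene_open.row(pair.gene_id),
            lnc_open.row(pair.lncrna_id),
            distance_cap,
        )
        pair.features = vec
        table[pair.key] = vec
    return table


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the paths of the written outputs."""
    cfg.validate()
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = irdl_io.provenance_lines(cfg.as_dict(), cfg.master_seed)

    genes = irdl_io.read_bed6(cfg.genes_bed, kind="gene")
    lncs = irdl_io.read_bed6(cfg.lncrnas_bed, kind="lncRNA")
    features_by_id = {f.id: f for f in genes + lncs}
    sequences = irdl_io.read_fasta(cfg.sequences_fasta)

    gene_expr = log2_transform(
        irdl_io.read_matrix(cfg.gene_expr, "expression_raw"), cfg.log2_pseudocount
    )
    lnc_expr = log2_transform(
        irdl_io.read_matrix(cfg.lnc_expr, "expression_raw"), cfg.log2_pseudocount
    )
    if cfg.gene_open and cfg.lnc_open:
        gene_open = irdl_io.read_matrix(cfg.gene_open, "openness")
        lnc_open = irdl_io.read_matrix(cfg.lnc_open, "openness")
    else:
        full = irdl_io.openness_matrix_from_raw(irdl_io.read_openness_raw(cfg.openness_raw))
        gene_ids = [f.id for f in genes if f.id in set(full.feature_ids)]
        lnc_ids = [f.id for f in lncs if f.id in set(full.feature_ids)]
        gene_open = ProfileMatrix(
            gene_ids, full.sample_ids, np.vstack([full.row(i) for i in gene_ids]), "openness"
        )
        lnc_open = ProfileMatrix(
            lnc_ids, full.sample_ids, np.vstack([full.row(i) for i in lnc_ids]), "openness"
        )

    all_pairs = irdl_io.read_pairs(cfg.pairs)
    logger.info("computing features for %d pairs", len(all_pairs))
    table = compute_feature_table(
        all_pairs, features_by_id, sequences, gene_expr, lnc_expr,
        gene_open, lnc_open, cfg.tss_mode, cfg.distance_cap,
    )
    features_path = outdir / "features.tsv"
    irdl_io.write_feature_table(table, features_path, prov)

    positives0 = [p for p in all_pairs if p.role == "positive"]
    nearby = [p for p in all_pairs if p.role == "nearby_pool"]
    candidates = [p for p in all_pairs if p.role == "candidate"]
    identified, state = run_increasing_learning(
        positives0, nearby, candidates, table, cfg.learner, cfg.master_seed
    )

    assoc_path = outdir / "identified_associations.tsv"
    with open(assoc_path, "w") as fh:
        for line in prov:
            fh.write(f"# {line}\n")
        fh.write("lncrna_id\tgene_id\tadmission_iteration\tadmission_score\n")
        for p in identified:
            fh.write(f"{p.lncrna_id}\t{p.gene_id}\t{p.admission_iteration}\t{p.admission_score:.6f}\n")

    log_path = outdir / "iteration_log.tsv"
    with open(log_path, "w") as fh:
        for line in prov:
            fh.write(f"# {line}\n")
        fh.write("iteration\tn_positives_before\tn_added\tC\tgamma\tcv_aupr\n")
        for rec in state.iteration_log:
            fh.write(
                f"{rec.iteration}\t{rec.n_positives_before}\t{rec.n_added}\t"
                f"{rec.C:g}\t{rec.gamma:g}\t{rec.cv_aupr:.6f}\n"
            )

    summary = summarize_pair_properties(identified, cfg.pcc_cutoff, cfg.distance_cutoff) if identified else {
        "seq_pcc": 0, "expr_pcc": 0, "open_pcc": 0, "close_distance": 0, "n_pairs": 0
    }
    summary_path = outdir / "property_summary.tsv"
    with open(summary_path, "w") as fh:
        for line in prov:
            fh.write(f"# {line}\n")
        fh.write("property\tcount\n")
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")

    outputs = {
        "features": features_path,
        "associations": assoc_path,
        "iteration_log": log_path,
        "summary": summary_path,
    }

    if cfg.sample_tissues:
        tissues_map = irdl_io.read_sample_tissues(cfg.sample_tissues)
        tissue_path = outdir / "tissue_assignments.tsv"
        with open(tissue_path, "w") as fh:
            for line in prov:
                fh.write(f"# {line}\n")
            fh.write("lncrna_id\tgene_id\tassigned_tissue\tes\ttied_tissues\n")
            for p in identified:
                primary, tied, scores = assign_specific_tissue(
                    gene_expr.row(p.gene_id),
                    lnc_expr.row(p.lncrna_id),
                    gene_expr.sample_ids,
                    tissues_map,
                    cfg.gene_high_threshold,
                    cfg.lnc_high_threshold,
                )
                es = scores[primary] if primary else float("nan")
                fh.write(
                    f"{p.lncrna_id}\t{p.gene_id}\t{primary or 'none'}\t{es:.6f}\t"
                    f"{','.join(tied)}\n"
                )
        outputs["tissues"] = tissue_path

    return outputs
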