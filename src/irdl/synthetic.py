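"""Synthetic datasets with the statistical structure the method assumes.

The generator emulates a paired expression / chromatin-accessibility panel
over a modest number of cell lines (56 by default, the size of the mouse
ENCODE panel the method was designed around), with three populations of
lncRNA-gene pairs:

* seed positives (8 by default, mirroring the validated knockdown pairs)
  and planted candidate positives: head-to-head divergent geometry with a
  TSS gap in 500 bp - 10 kb, and expression and openness profiles drawn as
  correlated bivariate normals with target correlation ``planted_pcc``;
* decoy candidates: independent profiles, arbitrary distances including
  cross-chromosome pairs;
* a nearby pool used for negative sampling: close pairs with independent
  profiles.

Raw expression is ``2**z`` of the latent normal so the log2 path of the
feature extractor is exercised.  Openness is emitted twice: as per-sample
read-count tables (region reads X, region length L, background reads Y,
background length L0, pseudocount 5) and as matrices precomputed from those
very tables, so the two representations agree exactly.  Sequences are
i.i.d. uniform ACGT and unrelated within a pair — planted pairs are
detectable by co-expression and co-accessibility, not by sequence, matching
the genomic profile of the validated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from irdl.features import OpennessInput, ProfileMatrix, openness_score
from irdl.genome import GenomicFeature, PairRecord, genome_distance

REGION_LENGTH = 1_000  # bp, accessibility region per feature
BACKGROUND_LENGTH = 10_000  # bp
OPENNESS_DELTA = 5.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_seed_positives: int = 8
    n_planted_positives: int = 20
    n_decoy_candidates: int = 200
    n_nearby_pool: int = 300
    n_samples: int = 56
    planted_pcc: float = 0.9
    decoy_pcc: float = 0.0
    tss_gap_range: tuple[int, int] = (500, 10_000)
    seq_length: int = 1_000
    expr_mean: float = 6.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_seed_positives,
            self.n_planted_positives,
            self.n_decoy_candidates,
            self.n_nearby_pool,
            self.n_samples,
            self.seq_length,
        ) <= 0:
            raise ValueError("all counts and lengths must be positive")
        if not -1.0 < self.planted_pcc < 1.0 or not -1.0 < self.decoy_pcc < 1.0:
            raise ValueError("target correlations must lie in (-1, 1)")


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the planted ground truth."""

    config: SyntheticConfig
    features: list[GenomicFeature]
    sequences: dict[str, str]
    gene_expr_raw: ProfileMatrix
    lnc_expr_raw: ProfileMatrix
    gene_open: ProfileMatrix
    lnc_open: ProfileMatrix
    openness_raw: pd.DataFrame  # feature_id, sample_id, X, L, Y, L0, delta
    pairs: list[PairRecord]
    truth: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.gene_expr_raw.sample_ids)

    def feature_by_id(self, fid: str) -> GenomicFeature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)


def _correlated_pair(rng: np.random.Generator, n: int, rho: float, mean: float, sd: float):
    """Two length-n vectors with population correlation rho (Cholesky)."""
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return mean + sd * z1, mean + sd * z2


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset; byte-reproducible under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"s{i + 1:03d}" for i in range(cfg.n_samples)]

    features: list[GenomicFeature] = []
    sequences: dict[str, str] = {}
    pairs: list[PairRecord] = []
    truth: dict[tuple[str, str], bool] = {}
    gene_ids: list[str] = []
    lnc_ids: list[str] = []
    gene_expr_rows: list[np.ndarray] = []
    lnc_expr_rows: list[np.ndarray] = []
    gene_open_latent: list[np.ndarray] = []
    lnc_open_latent: list[np.ndarray] = []

    cursor = {f"chr{c}": 1_000_000 for c in range(1, 6)}
    chroms = sorted(cursor)

    def place_pair(idx: int, tag: str, gap: int, chrom: str, cross_chrom: bool, divergent: bool):
        """Lay down one lncRNA/gene pair and return the two features."""
        lnc_len = 2_000
        gene_len = 5_000
        a = cursor[chrom]
        lnc = GenomicFeature(f"lnc_{tag}{idx:03d}", chrom, "-", a - lnc_len, a, "lncRNA")
        if cross_chrom:
            other = chroms[(chroms.index(chrom) + 1) % len(chroms)]
            b = cursor[other]
            gene = GenomicFeature(f"gene_{tag}{idx:03d}", other, "+", b, b + gene_len, "gene")
            cursor[other] = b + gene_len + 50_000
        elif divergent:
            gene = GenomicFeature(f"gene_{tag}{idx:03d}", chrom, "+", a + gap, a + gap + gene_len, "gene")
        else:  # tandem neighbour, same strand as the lncRNA's gene-side convention
            gene = GenomicFeature(f"gene_{tag}{idx:03d}", chrom, "-", a + gap, a + gap + gene_len, "gene")
        cursor[chrom] = a + gap + gene_len + 100_000
        return lnc, gene

    def add_pair(lnc, gene, role, correlated: bool, is_true: bool):
        features.extend([lnc, gene])
        sequences[lnc.id] = _random_sequence(rng, cfg.seq_length)
        sequences[gene.id] = _random_sequence(rng, cfg.seq_length)
        rho_e = cfg.planted_pcc if correlated else cfg.decoy_pcc
        ge, le = _correlated_pair(rng, cfg.n_samples, rho_e, cfg.expr_mean, cfg.noise_sd)
        go, lo = _correlated_pair(rng, cfg.n_samples, rho_e, 0.0, 1.0)
        gene_ids.append(gene.id)
        lnc_ids.append(lnc.id)
        gene_expr_rows.append(np.exp2(ge))
        lnc_expr_rows.append(np.exp2(le))
        gene_open_latent.append(go)
        lnc_open_latent.append(lo)
        pair = PairRecord(
            lncrna_id=lnc.id,
            gene_id=gene.id,
            role=role,
            distance=genome_distance(gene, lnc),
        )
        pairs.append(pair)
        if role != "nearby_pool":
            truth[pair.key] = is_true

    def gap(lo=None, hi=None):
        lo = cfg.tss_gap_range[0] if lo is None else lo
        hi = cfg.tss_gap_range[1] if hi is None else hi
        return int(rng.integers(lo, hi + 1))

    for i in range(cfg.n_seed_positives):
        lnc, gene = place_pair(i, "seed", gap(), chroms[i % 5], False, True)
        add_pair(lnc, gene, "positive", correlated=True, is_true=True)
    for i in range(cfg.n_planted_positives):
        lnc, gene = place_pair(i, "plant", gap(), chroms[i % 5], False, True)
        add_pair(lnc, gene, "candidate", correlated=True, is_true=True)
    for i in range(cfg.n_decoy_candidates):
        cross = i % 5 == 4  # a fifth of decoys pair across chromosomes
        lnc, gene = place_pair(i, "decoy", gap(500, 100_000), chroms[i % 5], cross, True)
        add_pair(lnc, gene, "candidate", correlated=False, is_true=False)
    for i in range(cfg.n_nearby_pool):
        divergent = i % 2 == 0
        lnc, gene = place_pair(i, "near", gap(500, 100_000), chroms[i % 5], False, divergent)
        add_pair(lnc, gene, "nearby_pool", correlated=False, is_true=False)

    gene_expr = ProfileMatrix(gene_ids, sample_ids, np.vstack(gene_expr_rows), "expression_raw")
    lnc_expr = ProfileMatrix(lnc_ids, sample_ids, np.vstack(lnc_expr_rows), "expression_raw")

    # Openness: latent normal -> integer read counts -> exact fold-change score.
    all_ids = lnc_ids + gene_ids
    latent = np.vstack(lnc_open_latent + gene_open_latent)
    counts = np.maximum(np.rint(400.0 * np.exp2(latent)), 0.0)
    background = rng.integers(300, 701, size=len(all_ids)).astype(float)
    records = []
    open_values = np.empty_like(latent)
    for r, fid in enumerate(all_ids):
        for c, sid in enumerate(sample_ids):
            inp = OpennessInput(
                X=counts[r, c], L=REGION_LENGTH, Y=background[r],
                L0=BACKGROUND_LENGTH, delta=OPENNESS_DELTA,
            )
            open_values[r, c] = openness_score(inp)
            records.append(
                (fid, sid, counts[r, c], REGION_LENGTH, background[r], BACKGROUND_LENGTH, OPENNESS_DELTA)
            )
    openness_raw = pd.DataFrame(
        records, columns=["feature_id", "sample_id", "X", "L", "Y", "L0", "delta"]
    )
    n_lnc = len(lnc_ids)
    lnc_open = ProfileMatrix(lnc_ids, sample_ids, open_values[:n_lnc], "openness")
    gene_open = ProfileMatrix(gene_ids, sample_ids, open_values[n_lnc:], "openness")

    return SyntheticDataset(
        config=cfg,
        features=features,
        sequences=sequences,
        gene_expr_raw=gene_expr,
        lnc_expr_raw=lnc_expr,
        gene_open=gene_open,
        lnc_open=lnc_open,
        openness_raw=openness_raw,
        pairs=pairs,
        truth=truth,
    )


@dataclass
class TissuePanel:
    """Expression panel where designated pairs are tissue-restricted."""

    sample_ids: list[str]
    sample_tissues: dict[str, str]
    gene_expr: ProfileMatrix  # already on the thresholded scale
    lnc_expr: ProfileMatrix
    designated: list[tuple[str, str, str]]  # (lncrna_id, gene_id, target tissue)
    silent_pair: tuple[str, str]  # a pair lowly expressed everywhere


def generate_tissue_panel(
    cfg: SyntheticConfig, n_tissues: int = 3, n_designated: int = 4
) -> TissuePanel:
    """Panel where each designated pair is high only in one known tissue.

    Construction guarantees the specificity assignment: both members of a
    designated pair exceed their thresholds (gene > 6, lncRNA > 4) in every
    sample of the target tissue and nowhere else, so its enrichment score
    there is exactly 1.  One extra pair is below threshold in all samples
    and must receive no assignment.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(cfg.seed)
    per_tissue = max(2, cfg.n_samples // n_tissues)
    tissues = [f"tissue{t + 1}" for t in range(n_tissues)]
    sample_ids, sample_tissues = [], {}
    for t, tissue in enumerate(tissues):
        for j in range(per_tissue):
            sid = f"{tissue}_s{j + 1:02d}"
            sample_ids.append(sid)
            sample_tissues[sid] = tissue

    n_samples = len(sample_ids)
    gene_ids, lnc_ids, designated = [], [], []
    gene_rows, lnc_rows = [], []
    for i in range(n_designated):
        target = tissues[i % n_tissues]
        mask = np.array([sample_tissues[s] == target for s in sample_ids])
        g = np.where(mask, 8.0 + rng.random(n_samples), 1.0 + rng.random(n_samples))
        l = np.where(mask, 5.0 + rng.random(n_samples), 0.5 * rng.random(n_samples))
        gene_ids.append(f"gene_tp{i:02d}")
        lnc_ids.append(f"lnc_tp{i:02d}")
        gene_rows.append(g)
        lnc_rows.append(l)
        designated.append((lnc_ids[-1], gene_ids[-1], target))
    # silent pair: everything below threshold everywhere
    gene_ids.append("gene_silent")
    lnc_ids.append("lnc_silent")
    gene_rows.append(1.0 + rng.random(n_samples))
    lnc_rows.append(0.5 * rng.random(n_samples))

    return TissuePanel(
        sample_ids=sample_ids,
        sample_tissues=sample_tissues,
        gene_expr=ProfileMatrix(gene_ids, sample_ids, np.vstack(gene_rows), "expression_log2"),
        lnc_expr=ProfileMatrix(lnc_ids, sample_ids, np.vstack(lnc_rows), "expression_log2"),
        designated=designated,
        silent_pair=("lnc_silent", "gene_silent"),
    )
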