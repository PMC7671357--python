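"""Tissue/cell-specificity assignment for identified regulatory pairs.

A pair is assigned to the tissue or cell type where both members are
specifically highly expressed.  For each member the samples with expression
above a threshold (default: > 6 for genes, > 4 for lncRNAs, strict
inequality) are collected; for every tissue represented in BOTH
high-expression sets an enrichment score

    ES = (m * n) / (p * q)

is computed, where m and n are the high-expression sample counts of gene and
lncRNA inside the tissue and p and q the totals over all tissues.  The pair
is assigned the argmax-ES tissue; ties are all reported, with the
lexicographically smallest as the primary assignment.  Pairs whose members
share no high-expression tissue (or are lowly expressed everywhere) get no
assignment.

The thresholds are applied on whatever expression scale the matrices were
loaded in; callers should make sure it is the scale the thresholds were
meant for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GENE_HIGH_THRESHOLD = 6.0
LNC_HIGH_THRESHOLD = 4.0


@dataclass(frozen=True)
class TissueCounts:
    """High-expression sample counts behind one pair-by-tissue score."""

    tissue: str
    m: int  # gene high-expression samples in tissue
    n: int  # lncRNA high-expression samples in tissue
    p: int  # all gene high-expression samples
    q: int  # all lncRNA high-expression samples

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.p and 0 <= self.n <= self.q):
            raise ValueError(f"inconsistent tissue counts {self}")


def high_expression_samples(profile, sample_ids: list[str], threshold: float) -> set[str]:
    """Samples whose expression is strictly greater than ``threshold``."""
    profile = np.asarray(profile, dtype=float)
    if not np.isfinite(profile).all():
        raise ValueError("expression profile contains non-finite values")
    if profile.shape != (len(sample_ids),):
        raise ValueError(f"profile length {profile.shape} != {len(sample_ids)} samples")
    return {sid for sid, v in zip(sample_ids, profile) if v > threshold}


def enrichment_score(tc: TissueCounts) -> float:
    """ES = (m * n) / (p * q), in [0, 1]."""
    if tc.p == 0 or tc.q == 0:
        raise ValueError(
            f"enrichment score undefined for tissue {tc.tissue!r}: "
            f"no high-expression samples (p={tc.p}, q={tc.q})"
        )
    return (tc.m * tc.n) / (tc.p * tc.q)


def assign_specific_tissue(
    gene_profile,
    lnc_profile,
    sample_ids: list[str],
    sample_tissues: dict[str, str],
    gene_threshold: float = GENE_HIGH_THRESHOLD,
    lnc_threshold: float = LNC_HIGH_THRESHOLD,
) -> tuple[str | None, list[str], dict[str, float]]:
    """Assign the tissue where both pair members are specifically high.

    Returns ``(primary_tissue_or_None, all_tied_argmax_tissues, score_table)``
    where the score table maps each overlap tissue to its ES.  Returns
    ``(None, [], {})`` when the members share no high-expression tissue.
    """
    missing = [s for s in sample_ids if s not in sample_tissues]
    if missing:
        raise ValueError(f"samples missing a tissue annotation: {missing[:5]}")

    gene_high = high_expression_samples(gene_profile, sample_ids, gene_threshold)
    lnc_high = high_expression_samples(lnc_profile, sample_ids, lnc_threshold)
    p, q = len(gene_high), len(lnc_high)
    if p == 0 or q == 0:
        return None, [], {}

    gene_tissues = {sample_tissues[s] for s in gene_high}
    lnc_tissues = {sample_tissues[s] for s in lnc_high}
    overlap = gene_tissues & lnc_tissues
    if not overlap:
        return None, [], {}

    scores: dict[str, float] = {}
    for tissue in sorted(overlap):
        m = sum(1 for s in gene_high if sample_tissues[s] == tissue)
        n = sum(1 for s in lnc_high if sample_tissues[s] == tissue)
        scores[tissue] = enrichment_score(TissueCounts(tissue, m, n, p, q))

    best = max(scores.values())
    tied = sorted(t for t, es in scores.items() if es == best)
    return tied[0], tied, scores
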