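"""Domain types for annotated features and lncRNA-gene pairs.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
The transcription start site (TSS) is strand-aware by default (``start`` on
the + strand, ``end`` on the - strand); a ``raw_start`` mode that always uses
``start`` is available for callers whose annotations are already TSS-anchored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

#: Sentinel for the genome distance between features on different chromosomes.
#: Kept as a float infinity so arithmetic comparisons behave; it is converted
#: to a bounded value only when features are encoded for the classifier.
INFINITY_DISTANCE = math.inf

TssMode = Literal["strand_aware", "raw_start"]
Role = Literal["positive", "nearby_pool", "candidate"]


@dataclass(frozen=True)
class GenomicFeature:
    """An annotated gene or lncRNA locus.

    Parameters
    ----------
    id : str
        Identifier, unique within its kind in one dataset.
    chrom : str
        Chromosome name.
    strand : {"+", "-"}
    start, end : int
        0-based half-open interval; ``end > start >= 0``.
    kind : {"gene", "lncRNA"}
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end}) "
                "(need end > start >= 0)"
            )
        if self.kind not in ("gene", "lncRNA"):
            raise ValueError(f"feature {self.id!r}: kind must be 'gene' or 'lncRNA', got {self.kind!r}")

    def tss(self, mode: TssMode = "strand_aware") -> int:
        """Transcription start site under the given convention."""
        if mode == "raw_start":
            return self.start
        return self.start if self.strand == "+" else self.end


@dataclass
class PairRecord:
    """One lncRNA-gene pair with its role in learning and, once computed,
    its 4-dimensional feature vector (seq_pcc, expr_pcc, open_pcc,
    distance_feature)."""

    lncrna_id: str
    gene_id: str
    role: Role = "candidate"
    distance: float = INFINITY_DISTANCE
    features: tuple[float, float, float, float] | None = None
    # learner bookkeeping, filled when a candidate is promoted
    admission_iteration: int | None = field(default=None, compare=False)
    admission_score: float | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.lncrna_id, self.gene_id)

    def promoted(self, iteration: int, score: float) -> "PairRecord":
        """Return a copy with role ``positive`` (the only legal transition)."""
        if self.role != "candidate":
            raise ValueError(f"pair {self.key}: only candidates can become positives (role={self.role})")
        return replace(
            self, role="positive", admission_iteration=iteration, admission_score=score
        )


def genome_distance(
    gene: GenomicFeature, lncrna: GenomicFeature, tss_mode: TssMode = "strand_aware"
) -> float:
    """Signed genome distance: gene TSS minus lncRNA TSS.

    Features on different chromosomes are assigned :data:`INFINITY_DISTANCE`
    (positive infinity), reflecting that trans pairs have no meaningful
    linear separation.
    """
    if gene.chrom != lncrna.chrom:
        return INFINITY_DISTANCE
    return float(gene.tss(tss_mode) - lncrna.tss(tss_mode))


def is_divergent(
    gene: GenomicFeature,
    lncrna: GenomicFeature,
    window: int = 10_000,
    tss_mode: TssMode = "strand_aware",
) -> bool:
    """True iff the pair is head-to-head on opposite strands within ``window`` bp.

    Head-to-head means the two TSSs point away from each other: the + strand
    member's TSS lies at a coordinate >= the - strand member's TSS, so
    transcription proceeds outward from the shared intergenic region.
    Overlapping bodies still qualify as long as the strands oppose.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if gene.chrom != lncrna.chrom or gene.strand == lncrna.strand:
        return False
    d = genome_distance(gene, lncrna, tss_mode)
    if abs(d) > window:
        return False
    plus, minus = (gene, lncrna) if gene.strand == "+" else (lncrna, gene)
    return plus.tss(tss_mode) >= minus.tss(tss_mode)


def summarize_pair_properties(
    pairs: Iterable[PairRecord],
    pcc_cutoff: float = 0.7,
    distance_cutoff: int = 100_000,
) -> dict[str, int]:
    """Count pairs with high correlations and close genome distance.

    Returns counts of pairs with each of seq/expr/open PCC strictly above
    ``pcc_cutoff``, and of pairs with ``|distance| < distance_cutoff``
    (pairs on different chromosomes never count as close).
    """
    counts = {"seq_pcc": 0, "expr_pcc": 0, "open_pcc": 0, "close_distance": 0, "n_pairs": 0}
    for pair in pairs:
        if pair.features is None:
            raise ValueError(f"pair {pair.key} has no computed features")
        counts["n_pairs"] += 1
        seq, expr, open_, _ = pair.features
        if seq > pcc_cutoff:
            counts["seq_pcc"] += 1
        if expr > pcc_cutoff:
            counts["expr_pcc"] += 1
        if open_ > pcc_cutoff:
            counts["open_pcc"] += 1
        if abs(pair.distance) < distance_cutoff:
            counts["close_distance"] += 1
    return counts
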