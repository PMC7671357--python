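"""Per-pair feature computation.

Each lncRNA-gene pair is summarised by four numbers fed to the classifier:

* ``seq_pcc`` -- Pearson correlation of the two members' k-mer (k = 1..3)
  frequency vectors,
* ``expr_pcc`` -- Pearson correlation of their log2 expression profiles
  across samples,
* ``open_pcc`` -- Pearson correlation of their chromatin-accessibility
  (openness) profiles across samples,
* ``distance_feature`` -- log10-encoded absolute genome distance.

Openness is the pseudocount-stabilised fold change of reads per base pair in
a region over a background region, O = ((X + d)/L) / ((Y + d)/L0).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from irdl.genome import PairRecord

logger = logging.getLogger(__name__)

#: Distance assigned to cross-chromosome pairs at encoding time: roughly the
#: length of the largest mammalian chromosome, so "infinitely far" maps just
#: beyond any real intra-chromosomal separation.
DISTANCE_CAP = 2.5e8

KMER_ALPHABET = "ACGT"
#: All 84 k-mers in feature order: 4 one-mers, 16 two-mers, 64 three-mers,
#: lexicographic within each block.
KMER_ORDER: tuple[str, ...] = tuple(
    "".join(p) for k in (1, 2, 3) for p in itertools.product(KMER_ALPHABET, repeat=k)
)


@dataclass(frozen=True)
class OpennessInput:
    """Raw inputs of the openness score for one region in one sample."""

    X: float  # reads in region
    L: float  # region length, bp
    Y: float  # reads in background
    L0: float  # background length, bp
    delta: float = 5.0  # pseudocount

    def __post_init__(self) -> None:
        if self.L <= 0 or self.L0 <= 0:
            raise ValueError(f"region lengths must be positive (L={self.L}, L0={self.L0})")
        if self.X < 0 or self.Y < 0:
            raise ValueError(f"read counts must be non-negative (X={self.X}, Y={self.Y})")
        if self.delta < 0:
            raise ValueError(f"pseudocount must be non-negative (delta={self.delta})")


@dataclass(frozen=True)
class KmerFeature:
    """84-dimensional k-mer frequency vector for one DNA sequence."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 84:
            raise ValueError(f"k-mer feature must have 84 entries, got {len(self.values)}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class ProfileMatrix:
    """A features-by-samples matrix of expression or openness values."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    space: str = "expression_raw"  # expression_raw | expression_log2 | openness
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in profile matrix")
        self._index = {fid: i for i, fid in enumerate(self.feature_ids)}

    def row(self, feature_id: str) -> np.ndarray:
        try:
            return self.values[self._index[feature_id]]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in profile matrix") from None


def openness_score(inp: OpennessInput) -> float:
    """Fold change of reads per base pair: ((X+d)/L) / ((Y+d)/L0)."""
    if inp.Y + inp.delta == 0:
        raise ZeroDivisionError(
            f"openness undefined: background reads Y={inp.Y} with pseudocount "
            f"delta={inp.delta} gives a zero denominator"
        )
    return ((inp.X + inp.delta) / inp.L) / ((inp.Y + inp.delta) / inp.L0)


def kmer_feature(sequence: str) -> KmerFeature:
    """Concatenated k = 1, 2, 3 k-mer frequencies of a DNA sequence.

    Within each block, the frequency of a k-mer is its count among the
    sequence's valid length-k windows divided by the number of valid windows.
    Windows containing a letter outside ACGT (e.g. N) are excluded from both
    numerator and denominator; a block with no valid window is all zeros.
    """
    if not sequence:
        raise ValueError("cannot compute k-mer features of an empty sequence")
    seq = sequence.upper()
    values: list[float] = []
    for k in (1, 2, 3):
        counts = {"".join(p): 0 for p in itertools.product(KMER_ALPHABET, repeat=k)}
        n_valid = 0
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if window in counts:
                counts[window] += 1
                n_valid += 1
        if n_valid == 0:
            logger.warning("no valid %d-mer window in sequence; block left at zero", k)
            values.extend(0.0 for _ in counts)
        else:
            values.extend(counts[kmer] / n_valid for kmer in sorted(counts))
    return KmerFeature(tuple(values))


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation; NaN flags an undefined (zero-variance) case.

    Callers that need a finite feature should encode the NaN as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-d and equal length, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError(f"need at least 2 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def log2_transform(matrix: ProfileMatrix, pseudocount: float = 1.0) -> ProfileMatrix:
    """Elementwise v -> log2(v + pseudocount) on a raw expression matrix."""
    if matrix.space != "expression_raw":
        raise ValueError(f"log2_transform expects expression_raw, got {matrix.space!r}")
    bad = np.argwhere(matrix.values < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"negative expression at feature {matrix.feature_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}: {matrix.values[i, j]}"
        )
    return ProfileMatrix(
        feature_ids=list(matrix.feature_ids),
        sample_ids=list(matrix.sample_ids),
        values=np.log2(matrix.values + pseudocount),
        space="expression_log2",
    )


def encode_distance(d: float, cap: float = DISTANCE_CAP) -> float:
    """Map a signed distance (or infinity) to a bounded classifier feature.

    ``log10(|d| + 1)`` for finite d; cross-chromosome (infinite) distances
    saturate at ``log10(cap + 1)``. Monotone non-decreasing in |d|.
    """
    if math.isinf(d):
        return math.log10(cap + 1.0)
    return math.log10(min(abs(d), cap) + 1.0)


def _finite_pcc(x, y, label: str, pair_key) -> float:
    r = pearson_correlation(x, y)
    if math.isnan(r):
        logger.warning("zero-variance %s profile for pair %s; PCC encoded as 0", label, pair_key)
        return 0.0
    return r


def pair_features(
    pair: PairRecord,
    gene_seq: str,
    lnc_seq: str,
    gene_expr: np.ndarray,
    lnc_expr: np.ndarray,
    gene_open: np.ndarray,
    lnc_open: np.ndarray,
    distance_cap: float = DISTANCE_CAP,
) -> tuple[float, float, float, float]:
    """Compute the (seq_pcc, expr_pcc, open_pcc, distance_feature) vector.

    Expression rows must come from log2-transformed matrices with identical
    sample ordering; openness rows likewise.  Undefined correlations are
    encoded as 0 with a logged warning so the feature matrix stays finite.
    """
    seq_pcc = _finite_pcc(
        kmer_feature(gene_seq).as_array(), kmer_feature(lnc_seq).as_array(), "sequence", pair.key
    )
    expr_pcc = _finite_pcc(gene_expr, lnc_expr, "expression", pair.key)
    open_pcc = _finite_pcc(gene_open, lnc_open, "openness", pair.key)
    return (seq_pcc, expr_pcc, open_pcc, encode_distance(pair.distance, distance_cap))
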