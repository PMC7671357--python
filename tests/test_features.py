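import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irdl.features import (
    KMER_ORDER,
    KmerFeature,
    OpennessInput,
    ProfileMatrix,
    encode_distance,
    kmer_feature,
    log2_transform,
    openness_score,
    pair_features,
    pearson_correlation,
)
from irdl.genome import INFINITY_DISTANCE, PairRecord

dna = st.text(alphabet="ACGT", min_size=3, max_size=80)


def pearson_by_definition(x, y):
    """Independent from-definition oracle: covariance over product of sds."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


class TestOpenness:
    def test_region_equals_background_gives_one(self):
        assert openness_score(OpennessInput(X=10, L=100, Y=10, L0=100, delta=3)) == 1.0

    def test_hand_evaluated_fold_change(self):
        assert openness_score(OpennessInput(X=15, L=100, Y=5, L0=100, delta=5)) == 2.0

    def test_zero_reads_forced_to_parity_by_pseudocount(self):
        assert openness_score(OpennessInput(X=0, L=200, Y=0, L0=200, delta=5)) == 1.0

    def test_matches_formula_on_randomized_tuples(self, rng):
        for _ in range(25):
            X = float(rng.integers(0, 1000))
            Y = float(rng.integers(0, 1000))
            L = float(rng.integers(1, 10_000))
            L0 = float(rng.integers(1, 10_000))
            delta = float(rng.integers(0, 10))
            if Y + delta == 0:
                continue
            got = openness_score(OpennessInput(X, L, Y, L0, delta))
            expected = ((X + delta) / L) / ((Y + delta) / L0)
            assert got == pytest.approx(expected, abs=0, rel=1e-15)

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            openness_score(OpennessInput(X=5, L=10, Y=0, L0=10, delta=0))

    @pytest.mark.parametrize("kwargs", [
        {"X": -1, "L": 10, "Y": 0, "L0": 10},
        {"X": 1, "L": 0, "Y": 0, "L0": 10},
        {"X": 1, "L": 10, "Y": 0, "L0": 10, "delta": -1},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OpennessInput(**kwargs)

    def test_monotone_in_region_and_background_reads(self):
        base = OpennessInput(X=10, L=100, Y=10, L0=100, delta=5)
        more_region = OpennessInput(X=20, L=100, Y=10, L0=100, delta=5)
        more_background = OpennessInput(X=10, L=100, Y=20, L0=100, delta=5)
        assert openness_score(more_region) > openness_score(base)
        assert openness_score(more_background) < openness_score(base)


class TestKmerFeature:
    def test_dimension_is_84(self):
        assert len(kmer_feature("ACGTACGT").values) == 84
        assert len(KMER_ORDER) == 4 + 16 + 64

    def test_homopolymer(self):
        vec = dict(zip(KMER_ORDER, kmer_feature("AAAA").values))
        assert vec["A"] == 1.0 and vec["AA"] == 1.0 and vec["AAA"] == 1.0
        assert sum(v != 0 for v in vec.values()) == 3

    def test_acgt_hand_count(self):
        vec = dict(zip(KMER_ORDER, kmer_feature("ACGT").values))
        for b in "ACGT":
            assert vec[b] == pytest.approx(0.25)
        for d in ("AC", "CG", "GT"):
            assert vec[d] == pytest.approx(1 / 3)
        for t in ("ACG", "CGT"):
            assert vec[t] == pytest.approx(0.5)
        assert sum(vec.values()) == pytest.approx(3.0)

    @given(seq=dna)
    @settings(max_examples=60, deadline=None)
    def test_blocks_sum_to_one(self, seq):
        values = kmer_feature(seq).values
        assert sum(values[:4]) == pytest.approx(1.0)
        assert sum(values[4:20]) == pytest.approx(1.0)
        assert sum(values[20:]) == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in values)

    @given(seq=dna)
    @settings(max_examples=40, deadline=None)
    def test_reverse_complement_permutes_blocks(self, seq):
        """Complementing maps each k-mer's frequency onto its complement's."""
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))
        orig = dict(zip(KMER_ORDER, kmer_feature(seq).values))
        flipped = dict(zip(KMER_ORDER, kmer_feature(comp).values))
        for kmer in KMER_ORDER:
            ckmer = kmer.translate(str.maketrans("ACGT", "TGCA"))
            assert flipped[ckmer] == pytest.approx(orig[kmer])

    def test_ambiguous_windows_excluded(self):
        # "ANA": valid 1-mer windows are the two A's; no valid 2/3-mer window
        vec = dict(zip(KMER_ORDER, kmer_feature("ANA").values))
        assert vec["A"] == 1.0
        values = kmer_feature("ANA").values
        assert sum(values[4:]) == 0.0

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            kmer_feature("")

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(ValueError):
            KmerFeature((0.0,) * 83)


class TestPearson:
    def test_identity_and_sign_flip(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_definition(self):
        x, y = [1, 2, 3, 4], [2, 4, 6, 9]
        assert pearson_correlation(x, y) == pytest.approx(pearson_by_definition(x, y), abs=1e-12)

    def test_random_vectors_match_definition(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert pearson_correlation(x, y) == pytest.approx(
                pearson_by_definition(x, y), abs=1e-12
            )

    def test_zero_variance_flags_nan(self):
        assert math.isnan(pearson_correlation([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("x,y", [([1], [2]), ([1, 2], [1, 2, 3])])
    def test_bad_shapes_rejected(self, x, y):
        with pytest.raises(ValueError):
            pearson_correlation(x, y)

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        data=st.lists(st.floats(-100, 100), min_size=3, max_size=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_positive_affine_transform(self, a, b, data):
        from hypothesis import assume

        x = np.asarray(data)
        assume(np.ptp(x) > 1e-3)  # avoid catastrophic cancellation regimes
        y = np.linspace(-1, 1, len(x)) + 0.1 * np.sin(np.arange(len(x)))
        r1 = pearson_correlation(x, y)
        r2 = pearson_correlation(a * x + b, y)
        if not math.isnan(r1):
            assert r2 == pytest.approx(r1, abs=1e-8)


class TestLog2Transform:
    def matrix(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return ProfileMatrix(
            [f"f{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])],
            values,
            "expression_raw",
        )

    def test_values_and_shape(self):
        out = log2_transform(self.matrix([[0.0, 7.0, 3.0]]), pseudocount=1.0)
        assert out.space == "expression_log2"
        assert out.values.shape == (1, 3)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(3.0)

    def test_negative_value_names_the_cell(self):
        with pytest.raises(ValueError, match="f0.*s1"):
            log2_transform(self.matrix([[1.0, -2.0]]))

    def test_requires_raw_space(self):
        m = log2_transform(self.matrix([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            log2_transform(m)


class TestEncodeDistance:
    def test_reference_points(self):
        assert encode_distance(0.0) == 0.0
        assert encode_distance(999.0) == pytest.approx(3.0)
        assert encode_distance(INFINITY_DISTANCE) == pytest.approx(math.log10(2.5e8 + 1))

    @given(d=st.floats(-1e9, 1e9, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, d):
        assert encode_distance(d) == encode_distance(-d)
        assert 0.0 <= encode_distance(d) <= encode_distance(INFINITY_DISTANCE)

    def test_monotone_in_absolute_distance(self):
        ds = [0, 10, 1_000, 100_000, 2.5e8, INFINITY_DISTANCE]
        encoded = [encode_distance(d) for d in ds]
        assert encoded == sorted(encoded)


class TestPairFeatures:
    def test_identical_inputs_give_unit_correlations(self):
        pair = PairRecord("l", "g", "candidate", 0.0)
        profile = np.array([1.0, 2.0, 3.0, 5.0])
        vec = pair_features(pair, "ACGTACGTAA", "ACGTACGTAA", profile, profile, profile, profile)
        assert vec == pytest.approx((1.0, 1.0, 1.0, 0.0))

    def test_zero_variance_profile_encoded_as_zero(self, caplog):
        pair = PairRecord("l", "g", "candidate", 100.0)
        flat = np.ones(4)
        varying = np.array([1.0, 2.0, 3.0, 4.0])
        with caplog.at_level("WARNING"):
            vec = pair_features(pair, "ACGTAC", "ACGTAC", flat, varying, varying, varying)
        assert vec[1] == 0.0
        assert "zero-variance" in caplog.text

    def test_matches_independent_recomputation_on_synthetic_pair(self, small_dataset):
        """End-to-end oracle: recompute a planted pair's features from raw data."""
        from irdl.features import kmer_feature as kf

        ds = small_dataset
        pair = next(p for p in ds.pairs if p.role == "candidate" and ds.truth[p.key])
        gene_raw = ds.gene_expr_raw.row(pair.gene_id)
        lnc_raw = ds.lnc_expr_raw.row(pair.lncrna_id)
        expected_expr = pearson_by_definition(np.log2(gene_raw + 1), np.log2(lnc_raw + 1))
        expected_open = pearson_by_definition(
            ds.gene_open.row(pair.gene_id), ds.lnc_open.row(pair.lncrna_id)
        )
        expected_seq = pearson_by_definition(
            kf(ds.sequences[pair.gene_id]).values, kf(ds.sequences[pair.lncrna_id]).values
        )
        vec = pair_features(
            pair,
            ds.sequences[pair.gene_id],
            ds.sequences[pair.lncrna_id],
            np.log2(gene_raw + 1),
            np.log2(lnc_raw + 1),
            ds.gene_open.row(pair.gene_id),
            ds.lnc_open.row(pair.lncrna_id),
        )
        assert vec[0] == pytest.approx(expected_seq, abs=1e-10)
        assert vec[1] == pytest.approx(expected_expr, abs=1e-10)
        assert vec[2] == pytest.approx(expected_open, abs=1e-10)
        assert vec[3] == pytest.approx(math.log10(abs(pair.distance) + 1))
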