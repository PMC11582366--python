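import numpy as np
import pytest

from isoanchor.ani import (
    ANIMatrix,
    Cluster,
    SpeciesClustering,
    ani_from_sketches,
    cluster_species,
    expand_dataset,
    kmer_sketch,
    sketch_ani,
)
from isoanchor.errors import ValidationError

RNG = np.random.default_rng(42)
BASES = np.array(list("ACGT"))


def _random_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, n)])


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestSketch:
    def test_deterministic(self):
        seq = _random_seq(5000, np.random.default_rng(0))
        assert np.array_equal(kmer_sketch(seq), kmer_sketch(seq))

    def test_strand_invariant(self):
        seq = _random_seq(5000, np.random.default_rng(1))
        assert np.array_equal(kmer_sketch(seq), kmer_sketch(_revcomp(seq)))

    def test_contigs_pool_without_spanning(self):
        seq = _random_seq(2000, np.random.default_rng(2))
        split = [seq[:1000], seq[1000:]]
        pooled = kmer_sketch(split, k=21)
        whole = kmer_sketch(seq, k=21)
        # the split loses only the 20 k-mers spanning the join
        assert len(np.intersect1d(pooled, whole)) >= len(whole) - 20

    def test_n_kmers_skipped(self):
        seq = "ACGT" * 20
        with_n = seq[:30] + "N" + seq[31:]
        assert len(kmer_sketch(with_n, k=5)) <= len(kmer_sketch(seq, k=5))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            kmer_sketch("ACGT", k=21)


class TestANIEstimate:
    def test_identical_sequences_ani_100(self):
        seq = _random_seq(10000, np.random.default_rng(3))
        est = sketch_ani(seq, seq)
        assert est.ani == pytest.approx(100.0)
        assert est.jaccard == pytest.approx(1.0)
        assert not est.saturated

    def test_disjoint_sketches_saturated(self):
        a = np.array([1, 2, 3], dtype=np.uint64)
        b = np.array([4, 5, 6], dtype=np.uint64)
        est = ani_from_sketches(a, b)
        assert est.saturated and est.ani == 0.0

    def test_empty_sketch_rejected(self):
        with pytest.raises(ValidationError):
            ani_from_sketches(np.empty(0, np.uint64), np.array([1], dtype=np.uint64))


class TestANIMatrix:
    def test_symmetry_enforced(self):
        v = np.array([[100.0, 95.0], [90.0, 100.0]])
        with pytest.raises(ValidationError):
            ANIMatrix(("a", "b"), v)

    def test_diagonal_enforced(self):
        v = np.array([[99.0, 95.0], [95.0, 100.0]])
        with pytest.raises(ValidationError):
            ANIMatrix(("a", "b"), v)

    def test_from_pairs_and_tsv_roundtrip(self, tmp_path):
        m = ANIMatrix.from_pairs(["a", "b", "c"], {("a", "b"): 95.0})
        assert m.get("b", "a") == 95.0
        assert np.isnan(m.get("a", "c"))
        m.write_tsv(tmp_path / "ani.tsv")
        back = ANIMatrix.read_tsv(tmp_path / "ani.tsv")
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values, equal_nan=True)


def _priority(**scores):
    return {g: (s, 0.0) for g, s in scores.items()}


class TestClustering:
    def test_best_quality_becomes_representative(self):
        m = ANIMatrix.from_pairs(
            ["a", "b", "c", "d"],
            {("a", "b"): 95.0, ("a", "c"): 94.0, ("b", "c"): 92.0,
             ("a", "d"): 80.0, ("b", "d"): 80.0, ("c", "d"): 85.0},
        )
        clustering = cluster_species(m, _priority(a=90, b=80, c=70, d=60))
        assert clustering.representatives == ("a", "d")
        assert clustering.assignments() == {"a": "a", "b": "a", "c": "a", "d": "d"}

    def test_no_transitive_chaining(self):
        # with c as the top genome, b (ANI 92 to c) starts its own cluster
        m = ANIMatrix.from_pairs(
            ["a", "b", "c"],
            {("a", "b"): 95.0, ("a", "c"): 94.0, ("b", "c"): 92.0},
        )
        clustering = cluster_species(m, _priority(a=10, b=20, c=90))
        assert clustering.representatives == ("c", "b")

    def test_threshold_is_inclusive(self):
        m = ANIMatrix.from_pairs(["a", "b"], {("a", "b"): 93.0})
        clustering = cluster_species(m, _priority(a=2, b=1))
        assert len(clustering.clusters) == 1

    def test_missing_ani_counts_as_below_threshold(self):
        m = ANIMatrix.from_pairs(["a", "b"], {})
        clustering = cluster_species(m, _priority(a=2, b=1))
        assert len(clustering.clusters) == 2

    def test_priority_keys_must_match(self):
        m = ANIMatrix.from_pairs(["a", "b"], {})
        with pytest.raises(ValidationError):
            cluster_species(m, _priority(a=1))


class TestExpandedSet:
    def test_strictly_below_derep_threshold_kept(self):
        m = ANIMatrix.from_pairs(
            ["a", "b", "c"], {("a", "b"): 98.9, ("a", "c"): 99.0, ("b", "c"): 98.0}
        )
        clustering = cluster_species(m, _priority(a=3, b=2, c=1))
        expanded = expand_dataset(clustering, m)
        # b at 98.9 (< 99) is kept; c at exactly 99.0 is dropped
        assert expanded == ("a", "b")

    def test_representative_always_in_expanded_set(self):
        m = ANIMatrix.from_pairs(["a", "b"], {("a", "b"): 100.0})
        clustering = cluster_species(m, _priority(a=2, b=1))
        assert "a" in expand_dataset(clustering, m)


def test_cluster_representative_must_be_member():
    with pytest.raises(ValidationError):
        Cluster("a", ("b",))
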