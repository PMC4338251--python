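"""Reference merge, re-scoring, Gower dissimilarity and Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from methatlas.atlas import (
    build_atlas,
    classify_location,
    classify_locations,
    gower_dissimilarity,
    merge_hmr_sets,
    score_reference,
    ward_cluster,
)
from methatlas.genome import GeneModel
from methatlas.intervals import GenomicInterval, IntervalSet
from methatlas.segmentation import call_hmrs, hmrs_to_intervals

from conftest import make_track


def gower_brute(X):
    """Scalar double-loop oracle for the Gower dissimilarity."""
    X = np.asarray(X, float)
    rng_ = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    keep = np.isfinite(rng_) & (rng_ > 0)
    X = X[:, keep]
    rng_ = rng_[keep]
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = cnt = 0
            for c in range(X.shape[1]):
                if np.isfinite(X[i, c]) and np.isfinite(X[j, c]):
                    num += abs(X[i, c] - X[j, c]) / rng_[c]
                    cnt += 1
            D[i, j] = num / cnt if cnt else np.nan
    np.fill_diagonal(D, 0.0)
    return D


class TestMerge:
    def test_overlap_coalescing(self):
        a = IntervalSet([GenomicInterval("chr1", 100, 200)])
        b = IntervalSet([GenomicInterval("chr1", 150, 300)])
        merged = merge_hmr_sets([a, b])
        assert [(i.start, i.end) for i in merged] == [(100, 300)]

    def test_disjoint_concatenation(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 100, 110)])
        assert len(merge_hmr_sets([a, b])) == 2


class TestScoreReference:
    def test_weighted_mean_and_missing(self):
        track = make_track([10, 20, 500], [1.0, 0.0, 0.4], [10, 10, 5])
        ref = IntervalSet([GenomicInterval("chr1", 0, 100),
                           GenomicInterval("chr1", 1000, 1100)]).merge()
        m = score_reference(ref, [track])
        assert m.iloc[0, 0] == pytest.approx(0.5)
        assert np.isnan(m.iloc[1, 0])  # no covered CpGs

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(100_000, size=2000, replace=False))
        levels = rng.random(2000)
        reads = rng.integers(0, 30, size=2000)
        track = make_track(pos, levels, reads)
        ref = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 500)
             for s in range(0, 100_000, 1500)]
        ).merge()
        m = score_reference(ref, [track], min_cpg=1)
        for row, iv in enumerate(ref):
            inside = (pos >= iv.start) & (pos < iv.end) & (reads > 0)
            if reads[inside].sum() == 0:
                assert np.isnan(m.iloc[row, 0])
            else:
                expected = (levels[inside] * reads[inside]).sum() / \
                    reads[inside].sum()
                assert m.iloc[row, 0] == pytest.approx(expected, abs=1e-12)


class TestClassifyLocation:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel("g1", "chr1", "+", 10_000,
                      GenomicInterval("chr1", 10_000, 30_000)),
            GeneModel("g2", "chr2", "-", 25_000,
                      GenomicInterval("chr2", 5_000, 25_000)),
        ]

    def test_promoter_takes_priority_over_gene_body(self, genes):
        iv = GenomicInterval("chr1", 10_500, 12_000)  # TSS window + body
        assert classify_location(iv, genes) == "promoter"

    def test_deep_gene_body_is_intragenic(self, genes):
        assert classify_location(GenomicInterval("chr1", 15_000, 16_000),
                                 genes) == "intragenic"

    def test_gene_free_chromosome_is_intergenic(self, genes):
        assert classify_location(GenomicInterval("chr9", 0, 1000),
                                 genes) == "intergenic"

    def test_minus_strand_promoter_window(self, genes):
        assert classify_location(GenomicInterval("chr2", 25_500, 25_900),
                                 genes) == "promoter"

    def test_vectorized_agrees_with_scalar(self, genes):
        rng = np.random.default_rng(1)
        ivs = IntervalSet(
            [GenomicInterval(rng.choice(["chr1", "chr2"]), int(s), int(s) + 800)
             for s in rng.integers(0, 40_000, size=60)]
        )
        vec = classify_locations(ivs, genes)
        for iv, got in zip(ivs, vec):
            assert got == classify_location(iv, genes)


class TestGower:
    def test_forced_example(self):
        X = np.array([[0, 0.5, 1], [1, 0.5, 0]])
        D = gower_dissimilarity(X, ranges=np.ones(3))
        assert D[0, 1] == pytest.approx(2 / 3)

    def test_identical_rows_zero(self):
        X = np.array([[0.2, 0.4], [0.2, 0.4], [0.9, 0.1]])
        D = gower_dissimilarity(X)
        assert D[0, 1] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.random((100, 7))
        X[rng.random((100, 7)) < 0.1] = np.nan  # sprinkle missing entries
        D = gower_dissimilarity(X)
        np.testing.assert_allclose(D, gower_brute(X), atol=1e-12)

    def test_all_degenerate_columns_rejected(self):
        with pytest.raises(ValueError):
            gower_dissimilarity(np.ones((5, 3)))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(2, 12), st.integers(1, 5), st.integers(0, 10_000))
    def test_symmetry_bounds_zero_diagonal(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((n, p))
        X[0] = 0.0
        X[1] = 1.0  # guarantee non-degenerate columns
        D = gower_dissimilarity(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert np.nanmax(D) <= 1.0 + 1e-12 and np.nanmin(D) >= 0.0


class TestWard:
    def test_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.01, (10, 4)),
                       rng.normal(1, 0.01, (10, 4))])
        labels = ward_cluster(gower_dissimilarity(X), 2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_rows_gives_singletons(self):
        D = gower_dissimilarity(np.random.default_rng(1).random((6, 3)))
        assert sorted(ward_cluster(D, 6)) == [1, 2, 3, 4, 5, 6]

    def test_k_too_large_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            ward_cluster(D, 4)


@pytest.fixture(scope="module")
def atlas_inputs(small_genome, small_archetypes):
    """PMD-free tracks: the clustering scenario isolates HMR structure."""
    import dataclasses

    from methatlas.simulate import generate_methylome

    tracks = []
    for i, spec in enumerate(small_archetypes.values()):
        flat = dataclasses.replace(spec, pmd_blocks=IntervalSet())
        track, _ = generate_methylome(small_genome, flat, seed=300 + i)
        tracks.append(track)
    hmr_sets = [hmrs_to_intervals(call_hmrs(t)) for t in tracks]
    return tracks, hmr_sets


class TestBuildAtlas:
    def test_structure_and_planted_cluster_recovery(
            self, small_genome, atlas_inputs):
        tracks, hmr_sets = atlas_inputs
        ref = build_atlas(hmr_sets, tracks, small_genome.genes, k=8)
        n = len(ref.intervals)
        assert len(ref.methylation_matrix) == n
        assert set(np.unique(ref.location)) <= {
            "promoter", "intragenic", "intergenic"}
        # rows that cluster carry exactly one label
        assert ((ref.cluster_label >= 0)
                & (ref.cluster_label <= 8)).all()
        # planted-cluster recovery per category via interval identity
        truth = small_genome.cluster_regions
        for category in ("promoter", "intragenic", "intergenic"):
            planted = truth[truth["category"] == category]
            got, expect = [], []
            pl = IntervalSet([
                GenomicInterval(r.chrom, r.start, r.end, name=str(r.cluster))
                for r in planted.itertuples(index=False)]).sort()
            for iv, loc, lab in zip(ref.intervals, ref.location,
                                    ref.cluster_label):
                if loc != category or lab == 0:
                    continue
                hits = [p for p in pl if p.overlaps(iv)]
                if len(hits) == 1:
                    got.append(lab)
                    expect.append(int(hits[0].name))
            assert len(got) > 20
            assert adjusted_rand_score(expect, got) >= 0.9

    def test_sample_order_permutation_invariance(
            self, small_genome, atlas_inputs):
        tracks, hmr_sets = atlas_inputs
        ref_a = build_atlas(hmr_sets, tracks, small_genome.genes, k=4)
        perm = [3, 0, 6, 2, 5, 1, 4]
        ref_b = build_atlas([hmr_sets[i] for i in perm],
                            [tracks[i] for i in perm],
                            small_genome.genes, k=4)
        np.testing.assert_array_equal(ref_a.cluster_label, ref_b.cluster_label)

    def test_single_profile_category_collapses(self):
        # all reference rows share one profile: the category collapses to a
        # single cluster regardless of the requested k
        rng = np.random.default_rng(5)
        pos = np.arange(0, 60_000, 100)
        levels = np.full(len(pos), 0.1) + rng.normal(0, 1e-4, len(pos))
        tracks = [make_track(pos, np.clip(levels, 0, 1),
                             np.full(len(pos), 30), sample=f"s{i}")
                  for i in range(3)]
        hmrs = [IntervalSet([GenomicInterval("chr1", s, s + 500)
                             for s in range(0, 60_000, 2000)])
                for _ in range(3)]
        ref = build_atlas(hmrs, tracks, genes=[], k=4)
        labs = ref.cluster_label[ref.location == "intergenic"]
        assert (labs == 1).all()

    def test_cluster_one_is_most_hypomethylated(
            self, small_genome, atlas_inputs):
        tracks, hmr_sets = atlas_inputs
        ref = build_atlas(hmr_sets, tracks, small_genome.genes, k=8)
        X = ref.methylation_matrix.to_numpy(float)
        for category in ("promoter", "intragenic", "intergenic"):
            sel = (ref.location == category) & (ref.cluster_label > 0)
            labs = ref.cluster_label[sel]
            means = [np.nanmean(X[sel][labs == lab])
                     for lab in sorted(np.unique(labs))]
            assert means == sorted(means)
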