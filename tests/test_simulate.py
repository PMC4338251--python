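"""Synthetic-data generator contracts: determinism, densities, noise model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from methatlas.genome import GenomeConfig, generate_genome
from methatlas.simulate import (
    ArchetypeSpec,
    CohortSpec,
    LinkSpec,
    default_archetypes,
    default_cluster_profiles,
    generate_expression,
    generate_methylome,
    generate_paired_cohort,
    male_like_archetype,
    sample_reference_matrix,
)


class TestGenerateGenome:
    def test_determinism_byte_identical(self):
        g1 = generate_genome(GenomeConfig(), seed=1)
        g2 = generate_genome(GenomeConfig(), seed=1)
        for chrom in g1.cpg_positions:
            np.testing.assert_array_equal(g1.cpg_positions[chrom],
                                          g2.cpg_positions[chrom])
        assert g1.genes == g2.genes
        assert g1.cgis == g2.cgis
        pd.testing.assert_frame_equal(g1.cluster_regions, g2.cluster_regions)

    def test_zero_genes_degenerate_case(self):
        cfg = GenomeConfig(n_genes=0)
        g = generate_genome(cfg, seed=2)
        assert g.genes == []
        assert all(len(p) > 0 for p in g.cpg_positions.values())

    def test_short_chromosome_rejected(self):
        cfg = GenomeConfig(chromosomes=[("chr1", 5000), ("chrX", 100_000)])
        with pytest.raises(ValueError, match="shorter"):
            generate_genome(cfg, seed=0)

    def test_missing_x_chromosome_rejected(self):
        cfg = GenomeConfig(chromosomes=[("chr1", 500_000)])
        with pytest.raises(ValueError, match="X-like"):
            generate_genome(cfg, seed=0)

    def test_cpg_densities_within_20pct_of_targets(self, small_genome):
        cfg = small_genome.config
        # CGI density
        ratios = []
        for iv in small_genome.cgis:
            pos = small_genome.cpg_positions[iv.chrom]
            n = ((pos >= iv.start) & (pos < iv.end)).sum()
            ratios.append(n / iv.width / cfg.cgi_density)
        assert abs(np.mean(ratios) - 1) < 0.2
        # background density measured on a desert region with no overlays
        chrom, length = cfg.chromosomes[0]
        lo = int(length * 0.9)
        pos = small_genome.cpg_positions[chrom]
        n_bg = ((pos >= lo) & (pos < length)).sum()
        assert abs(n_bg / (length - lo) / cfg.background_density - 1) < 0.2

    def test_promoters_contain_at_least_five_cpgs(self, small_genome):
        for g in small_genome.genes:
            p = g.promoter(1000)
            pos = small_genome.cpg_positions[g.chrom]
            assert ((pos >= p.start) & (pos < p.end)).sum() >= 5

    def test_positions_strictly_increasing(self, small_genome):
        for pos in small_genome.cpg_positions.values():
            assert (np.diff(pos) > 0).all()


class TestGenerateMethylome:
    def test_noiseless_limit_exact(self, small_genome):
        spec = ArchetypeSpec(name="normal", background_level=0.8,
                             hmr_level=0.05, mean_depth=math.inf,
                             dispersion=0.0,
                             cluster_profiles=dict(
                                 default_cluster_profiles()["NB"]))
        track, truth = generate_methylome(small_genome, spec, seed=1)
        for iv in truth["hmr"]:
            pos, lv, _ = track.chrom_arrays(iv.chrom)
            inside = (pos >= iv.start) & (pos < iv.end)
            assert (lv[inside] == 0.05).all()

    def test_depth_concentrates_near_mean(self, small_genome):
        spec = default_archetypes(small_genome, seed=0)["NB"]
        track, _ = generate_methylome(small_genome, spec, seed=4)
        assert len(track) > 10_000
        assert abs(track.df["reads"].mean() / 18.8 - 1) < 0.05

    def test_levels_in_unit_interval_counts_nonnegative(self, nb_methylome):
        track, _ = nb_methylome
        lv = track.df["level"].to_numpy()
        assert np.nanmin(lv) >= 0 and np.nanmax(lv) <= 1
        assert (track.df["reads"] >= 0).all()

    def test_determinism(self, small_genome, small_archetypes):
        t1, _ = generate_methylome(small_genome, small_archetypes["NB"], seed=9)
        t2, _ = generate_methylome(small_genome, small_archetypes["NB"], seed=9)
        assert t1 == t2

    def test_truth_intervals_sorted_disjoint(self, nb_methylome):
        _, truth = nb_methylome
        for key in ("hmr", "pmd"):
            s = truth[key]
            assert s.merged
            for a, b in zip(s, list(s)[1:]):
                if a.chrom == b.chrom:
                    assert a.end < b.start

    def test_pmd_fraction_targets(self, small_genome, small_archetypes):
        genome_bp = sum(small_genome.chrom_lengths.values())
        nb = small_archetypes["NB"].pmd_blocks
        frac_nb = nb.total_bp() / genome_bp if len(nb) else 0.0
        frac_cl = small_archetypes["MCF7"].pmd_blocks.total_bp() / genome_bp
        assert frac_nb < 0.01
        assert 0.25 <= frac_cl <= 0.35

    def test_male_archetype_x_promoters_low(self, small_genome):
        spec = male_like_archetype(small_genome, mean_depth=math.inf,
                                   dispersion=0.0)
        track, _ = generate_methylome(small_genome, spec, seed=2)
        for g in small_genome.x_genes[1:5]:
            pos, lv, _ = track.chrom_arrays(g.chrom)
            w = (pos >= g.tss - 500) & (pos < g.tss + 500)
            assert lv[w].mean() < 0.2


class TestGenerateExpression:
    def _promoter_meth(self, genome, cols, seed, tumor_cols=()):
        profiles = default_cluster_profiles()
        rng = np.random.default_rng(seed)
        rows = [r for r in genome.cluster_regions.itertuples(index=False)
                if r.category == "promoter" and r.gene_id]
        pm = {}
        for r in rows:
            vals = []
            for c in cols:
                ref = "MCF7" if c in tumor_cols else "NB"
                vals.append(np.clip(
                    profiles.loc[("promoter", r.cluster), ref]
                    + rng.normal(0, 0.05), 0, 1))
            pm[r.gene_id] = vals
        return pd.DataFrame.from_dict(pm, orient="index", columns=cols)

    def test_zero_slope_uncorrelated(self, small_genome):
        cols = [f"s{i}" for i in range(2)]
        pm = self._promoter_meth(small_genome, cols, seed=1)
        table, _ = generate_expression(
            small_genome, pm, LinkSpec(slope=0.0), seed=2)
        logc = np.log2(table.cpm + 0.5)
        r = spearmanr(pm[cols[0]], logc[cols[0]]).statistic
        assert abs(r) < 3 / np.sqrt(len(pm))  # null bound at this gene count

    def test_strong_negative_link(self, small_genome):
        cols = ["n", "t"]
        pm = self._promoter_meth(small_genome, cols, seed=3,
                                 tumor_cols={"t"})
        link = LinkSpec(linked_clusters=frozenset({3, 6}), slope=4.0,
                        nb_dispersion=0.02)
        table, linked = generate_expression(small_genome, pm, link, seed=4)
        lg = [g for g in pm.index if g in linked]
        dm = pm.loc[lg, "t"] - pm.loc[lg, "n"]
        lfc = (np.log2(table.cpm.loc[lg, "t"] + 0.5)
               - np.log2(table.cpm.loc[lg, "n"] + 0.5))
        assert spearmanr(dm, lfc).statistic < -0.5

    def test_determinism(self, small_genome):
        pm = self._promoter_meth(small_genome, ["a", "b"], seed=5)
        t1, _ = generate_expression(small_genome, pm, LinkSpec(), seed=6)
        t2, _ = generate_expression(small_genome, pm, LinkSpec(), seed=6)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_counts_nonnegative(self, small_genome):
        pm = self._promoter_meth(small_genome, ["a"], seed=7)
        t, _ = generate_expression(small_genome, pm, LinkSpec(), seed=8)
        assert (t.counts.to_numpy() >= 0).all()


class TestGeneratePairedCohort:
    def test_exact_affected_count(self, small_genome):
        cohort, truth = generate_paired_cohort(
            small_genome, CohortSpec(n_patients=78,
                                     xci_loss_fraction=36 / 78, seed=1))
        assert len(truth["affected_patients"]) == 36
        assert len(cohort.patients) == 78

    def test_null_cohort_centered_at_zero(self, small_genome):
        cohort, truth = generate_paired_cohort(
            small_genome, CohortSpec(n_patients=30, xci_loss_fraction=0.0,
                                     seed=2))
        assert truth["affected_patients"] == []
        x = [g for g in cohort.x_genes if g != cohort.xist_gene_id]
        delta = (cohort.promoter_meth_tumor.loc[x]
                 - cohort.promoter_meth_normal.loc[x]).mean(axis=0)
        assert abs(delta.mean()) < 0.02

    def test_affected_delta_matches_spec(self, small_genome):
        spec = CohortSpec(n_patients=60, xci_loss_fraction=0.5,
                          x_promoter_delta=-0.25, seed=3)
        cohort, truth = generate_paired_cohort(small_genome, spec)
        x = [g for g in cohort.x_genes if g != cohort.xist_gene_id]
        delta = (cohort.promoter_meth_tumor.loc[x]
                 - cohort.promoter_meth_normal.loc[x]).mean(axis=0)
        aff = delta[truth["affected_patients"]]
        assert aff.mean() == pytest.approx(-0.25, abs=0.04)

    def test_invalid_fraction_rejected(self, small_genome):
        with pytest.raises(ValueError):
            generate_paired_cohort(
                small_genome, CohortSpec(xci_loss_fraction=1.5))

    def test_levels_within_unit_interval(self, small_genome):
        cohort, _ = generate_paired_cohort(small_genome, CohortSpec(seed=4))
        for df in (cohort.promoter_meth_normal, cohort.promoter_meth_tumor):
            assert df.to_numpy().min() >= 0 and df.to_numpy().max() <= 1


class TestReferenceMatrixSampler:
    def test_shape_and_labels(self):
        m, cats, clus = sample_reference_matrix(n_regions=240, seed=1)
        assert m.shape == (240, 7)
        assert set(cats) == {"promoter", "intragenic", "intergenic"}
        assert set(clus) <= set(range(1, 9))
        assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 1)).all()

    def test_rows_track_their_profiles(self):
        m, cats, clus = sample_reference_matrix(n_regions=480, seed=2)
        profiles = default_cluster_profiles()
        for cat, cl in [("promoter", 1), ("intergenic", 4)]:
            rows = (cats == cat) & (clus == cl)
            got = m[rows].mean(axis=0).to_numpy()
            want = profiles.loc[(cat, cl)].to_numpy(float)
            assert np.abs(got - want).max() < 0.1
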