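"""Summaries and HMR/PMD segmentation, including planted-truth recovery."""

import math

import numpy as np
import pytest

from methatlas.intervals import GenomicInterval, IntervalSet
from methatlas.segmentation import (
    call_hmrs,
    call_pmds,
    genome_fraction,
    hmrs_to_intervals,
    level_categories,
    pmds_to_intervals,
    weighted_mean_level,
    window_summary,
)

from conftest import make_track


class TestWeightedMean:
    @pytest.mark.parametrize(
        "levels,reads,expected",
        [
            ([1.0, 0.0], [10, 10], 0.5),
            ([0.6], [5], 0.6),
            ([1.0, 0.0], [30, 10], 0.75),
            ([0.9, 0.1], [0, 5], 0.1),  # zero-coverage CpG excluded
        ],
    )
    def test_known_values(self, levels, reads, expected):
        assert weighted_mean_level(levels, reads) == pytest.approx(expected)

    def test_all_zero_reads_is_undefined(self):
        assert math.isnan(weighted_mean_level([0.5, 0.5], [0, 0]))


class TestLevelCategories:
    def test_one_cpg_per_band(self):
        track = make_track([10, 20, 30], [0.1, 0.5, 0.9], [5, 5, 5])
        c = level_categories(track)
        assert (c.low, c.intermediate, c.high) == (1, 1, 1)
        assert c.total == 3

    def test_boundaries_are_inclusive_intermediate(self):
        track = make_track([10, 20], [0.2, 0.8], [5, 5])
        c = level_categories(track)
        assert (c.low, c.intermediate, c.high) == (0, 2, 0)

    def test_region_restriction(self):
        track = make_track([10, 110, 210], [0.1, 0.1, 0.1], [5, 5, 5])
        inside = IntervalSet([GenomicInterval("chr1", 100, 120)])
        assert level_categories(track, regions=inside).total == 1
        empty = IntervalSet([GenomicInterval("chr1", 5000, 5010)])
        assert level_categories(track, regions=empty).total == 0


class TestWindowSummary:
    def test_tiling_count_and_constant_track(self):
        pos = np.arange(0, 1_000_000, 2000)
        track = make_track(pos, np.full(len(pos), 0.8), np.full(len(pos), 10))
        ws = window_summary(track, {"chr1": 1_000_000}, 10_000)
        assert len(ws) == 100
        assert np.allclose(ws["mean_level"], 0.8)
        # windows tile without overlap
        assert (ws["start"].to_numpy()[1:] == ws["end"].to_numpy()[:-1]).all()

    def test_cpg_density_units(self):
        pos = np.arange(0, 10_000, 200)  # 50 CpGs in one 10 kb window
        track = make_track(pos, np.full(50, 0.5), np.full(50, 5))
        ws = window_summary(track, {"chr1": 10_000}, 10_000)
        assert ws["cpg_density"].iloc[0] == pytest.approx(0.5)

    def test_uncovered_window_flagged_undefined(self):
        track = make_track([100], [0.5], [5])
        ws = window_summary(track, {"chr1": 20_000}, 10_000)
        assert math.isnan(ws["mean_level"].iloc[1])


def _noiseless_track(block_specs, spacing=100, background=0.9, depth=30,
                     n_total=400):
    """Background CpGs every `spacing` bp with optional low blocks."""
    pos = np.arange(n_total) * spacing
    levels = np.full(n_total, background)
    for a, b, lv in block_specs:
        levels[a:b] = lv
    return make_track(pos, levels, np.full(n_total, depth))


class TestCallHmrs:
    def test_single_noiseless_block_recovered_exactly(self):
        track = _noiseless_track([(100, 120, 0.05)])
        hmrs = call_hmrs(track)
        assert len(hmrs) == 1
        h = hmrs[0]
        assert h.n_cpg == 20
        assert h.interval.start == 100 * 100
        assert h.interval.end == 119 * 100 + 2
        assert h.mean_level == pytest.approx(0.05)

    def test_blocks_never_merged_across_cpg_desert(self):
        # two low blocks separated by a 2,000 bp gap with no CpGs
        pos = np.concatenate([np.arange(0, 2000, 100),
                              np.arange(4000, 6000, 100)])
        levels = np.full(len(pos), 0.05)
        # add flanking background so the low state is not the whole genome
        bg_pos = np.concatenate([np.arange(10_000, 40_000, 100)])
        pos = np.concatenate([pos, bg_pos])
        levels = np.concatenate([levels, np.full(len(bg_pos), 0.9)])
        track = make_track(pos, levels, np.full(len(pos), 30))
        hmrs = call_hmrs(track)
        assert len(hmrs) == 2
        assert all(h.interval.end <= 6002 for h in hmrs)

    def test_uniform_methylated_track_yields_nothing(self):
        track = _noiseless_track([])
        assert call_hmrs(track) == []

    def test_tiny_track_warns_and_returns_empty(self, caplog):
        track = make_track([10, 20], [0.1, 0.1], [5, 5])
        with caplog.at_level("WARNING"):
            assert call_hmrs(track, min_cpg=4) == []

    def test_monotonicity_lowering_block_keeps_call(self):
        base = _noiseless_track([(100, 120, 0.15)])
        lower = _noiseless_track([(100, 120, 0.02)])
        called_base = {(h.interval.start, h.interval.end)
                       for h in call_hmrs(base)}
        called_lower = {(h.interval.start, h.interval.end)
                        for h in call_hmrs(lower)}
        assert called_base <= called_lower or called_base == called_lower

    def test_no_internal_gap_exceeds_limit_and_calls_disjoint(
            self, panel_tracks):
        track, _truth = panel_tracks["BT126"]
        hmrs = call_hmrs(track)
        assert hmrs, "expected HMR calls on the simulated sample"
        prev_end = {}
        for h in hmrs:
            chrom = h.interval.chrom
            pos, _, rd = track.chrom_arrays(chrom)
            inside = pos[(pos >= h.interval.start) & (pos < h.interval.end)]
            assert (np.diff(inside) <= 1000).all()
            if chrom in prev_end:
                assert h.interval.start >= prev_end[chrom]
            prev_end[chrom] = h.interval.end

    def test_determinism(self, nb_methylome):
        track, _ = nb_methylome
        a = call_hmrs(track)
        b = call_hmrs(track)
        assert a == b

    def test_planted_recovery_on_simulated_track(self, nb_methylome):
        track, truth = nb_methylome
        called = hmrs_to_intervals(call_hmrs(track)).merge()
        recovered = 0
        for iv in truth["hmr"]:
            ok = False
            for j in called.overlapping_range(iv.chrom, iv.start, iv.end):
                starts, ends = called._build_index()[iv.chrom]
                inter = min(iv.end, ends[j]) - max(iv.start, starts[j])
                w = ends[j] - starts[j]
                if inter / iv.width >= 0.8 and inter / w >= 0.8:
                    ok = True
            recovered += ok
        assert recovered / len(truth["hmr"]) >= 0.9


class TestCallPmds:
    def test_noiseless_block_boundaries_within_two_bins(self):
        # 2 Mb partially methylated block inside a 6 Mb chromosome
        pos = np.arange(0, 6_000_000, 200)
        levels = np.full(len(pos), 0.8)
        block = (pos >= 2_000_000) & (pos < 4_000_000)
        levels[block] = 0.45
        track = make_track(pos, levels, np.full(len(pos), 30))
        pmds = call_pmds(track)
        assert len(pmds) == 1
        p = pmds[0]
        assert abs(p.interval.start - 2_000_000) <= 2000
        assert abs(p.interval.end - 4_000_000) <= 2000
        assert 0.15 < p.mean_level < 0.75

    def test_uniform_methylated_track_yields_no_pmds(self):
        pos = np.arange(0, 2_000_000, 200)
        track = make_track(pos, np.full(len(pos), 0.85),
                           np.full(len(pos), 20))
        assert call_pmds(track) == []

    def test_planted_fractions_by_archetype(self, small_genome, panel_tracks):
        lengths = small_genome.chrom_lengths
        frac = {}
        for sample in ("NB", "MCF7"):
            track, _ = panel_tracks[sample]
            pmds = call_pmds(track, min_domain=50_000)
            s = pmds_to_intervals(pmds).merge()
            frac[sample] = genome_fraction(s, lengths) if len(s) else 0.0
        assert frac["NB"] < 0.01
        assert 0.25 <= frac["MCF7"] <= 0.35


class TestGenomeFraction:
    def test_simple_fraction(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 1_000_000)]).merge()
        assert genome_fraction(s, {"chr1": 10_000_000}) == pytest.approx(0.1)

    def test_empty_set_is_zero(self):
        assert genome_fraction(IntervalSet().merge(), {"chr1": 100}) == 0.0

    def test_unmerged_set_refused(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            genome_fraction(s, {"chr1": 100})

    def test_complement_partition_sums_to_one(self):
        s = IntervalSet([GenomicInterval("chr1", 100, 400),
                         GenomicInterval("chr1", 600, 900)]).merge()
        comp = IntervalSet(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 400, 600),
             GenomicInterval("chr1", 900, 1000)]
        ).merge()
        total = genome_fraction(s, {"chr1": 1000}) + genome_fraction(
            comp, {"chr1": 1000})
        assert total == pytest.approx(1.0)
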