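"""Methylome summarization and segmentation into HMRs and PMDs.

HMRs (hypomethylated regions) are kilobase-scale low-methylation segments
called per CpG; segmentation never joins CpGs more than ``max_cpg_gap``
(default 1 kb) apart.  PMDs (partially methylated domains) are megabase-scale
blocks of intermediate (~40-60%) methylation called on 1 kb bin summaries with
a 20 kb gap limit and a minimum domain size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hmm import segment_betabinom, segment_gaussian
from .intervals import GenomicInterval, IntervalSet
from .io import MethylomeTrack

__all__ = [
    "HMR",
    "PMD",
    "LevelCategoryCounts",
    "weighted_mean_level",
    "level_categories",
    "window_summary",
    "call_hmrs",
    "call_pmds",
    "genome_fraction",
    "hmrs_to_intervals",
    "pmds_to_intervals",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HMR:
    interval: GenomicInterval
    n_cpg: int
    mean_level: float
    sample_id: str


@dataclass(frozen=True)
class PMD:
    interval: GenomicInterval
    mean_level: float
    n_bins: int
    sample_id: str


@dataclass(frozen=True)
class LevelCategoryCounts:
    """CpG counts in the three canonical methylation bands.

    low: level < 0.2; intermediate: 0.2 <= level <= 0.8 (both boundaries
    inclusive); high: level > 0.8.
    """

    low: int
    intermediate: int
    high: int

    @property
    def total(self) -> int:
        return self.low + self.intermediate + self.high


def weighted_mean_level(
    levels: Sequence[float], reads: Sequence[int]
) -> float:
    """Coverage-weighted mean methylation, sum(level*reads)/sum(reads).

    Zero-coverage CpGs contribute nothing; if no CpG has coverage the level
    is undefined and ``nan`` is returned.
    """
    levels = np.asarray(levels, dtype=float)
    reads = np.asarray(reads, dtype=float)
    ok = reads > 0
    total = reads[ok].sum()
    if total == 0:
        return math.nan
    return float((levels[ok] * reads[ok]).sum() / total)


def level_categories(
    track: MethylomeTrack,
    regions: Optional[IntervalSet] = None,
    low: float = 0.2,
    high: float = 0.8,
) -> LevelCategoryCounts:
    """Classify assessable CpGs as lowly/intermediately/highly methylated.

    When ``regions`` is given, only CpGs inside it are counted (e.g. restrict
    to CpG islands).
    """
    sub = track.assessable()
    if regions is not None:
        merged = regions if regions.merged else regions.merge()
        mask = np.zeros(len(sub), dtype=bool)
        chrom_vals = sub["chrom"].to_numpy()
        pos_vals = sub["pos"].to_numpy(np.int64)
        for chrom in dict.fromkeys(chrom_vals):
            sel = chrom_vals == chrom
            mask[sel] = merged.contains_positions(chrom, pos_vals[sel])
        sub = sub[mask]
    lv = sub["level"].to_numpy(float)
    n_low = int((lv < low).sum())
    n_high = int((lv > high).sum())
    return LevelCategoryCounts(n_low, len(lv) - n_low - n_high, n_high)


def window_summary(
    track: MethylomeTrack,
    chrom_lengths: dict[str, int],
    window_size: int,
):
    """Tile each chromosome into fixed windows and summarize methylation.

    Returns a DataFrame with one row per window: coverage-weighted mean level
    (nan when the window has no assessable CpG), CpG count, and CpG density
    per 100 bp.  Windows never overlap; the last window of a chromosome is
    truncated at the chromosome end.
    """
    import pandas as pd

    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        pos, lv, rd = track.chrom_arrays(chrom)
        n_win = (length + window_size - 1) // window_size
        idx = pos // window_size
        wsum = np.bincount(
            idx, weights=np.where(rd > 0, lv * rd, 0.0), minlength=n_win
        )
        wread = np.bincount(idx, weights=np.where(rd > 0, rd, 0), minlength=n_win)
        ncpg = np.bincount(idx, minlength=n_win)
        for w in range(n_win):
            start = w * window_size
            end = min(start + window_size, length)
            mean = wsum[w] / wread[w] if wread[w] > 0 else math.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "mean_level": mean,
                    "n_cpg": int(ncpg[w]),
                    "cpg_density": ncpg[w] / ((end - start) / 100.0),
                }
            )
    return pd.DataFrame(rows)


def _split_fragments(positions: np.ndarray, max_gap: int) -> list[slice]:
    """Slices delimiting runs of CpGs with no internal gap > max_gap."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
    bounds = np.concatenate([[0], breaks, [len(positions)]])
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def call_hmrs(
    track: MethylomeTrack,
    max_cpg_gap: int = 1000,
    min_cpg: int = 4,
    conc: float = 15.0,
    stay_prob: float = 0.99,
    min_separation: float = 0.2,
    posterior_cut: float = 0.5,
) -> list[HMR]:
    """Call hypomethylated regions with a two-state beta-binomial chain.

    Each chromosome is fragmented at CpG gaps larger than ``max_cpg_gap``
    before decoding, so no emitted HMR ever spans such a gap.  Low-state runs
    with at least ``min_cpg`` CpGs become HMRs.  If EM collapses the two state
    means closer than ``min_separation`` the track is treated as homogeneous
    and nothing is called.
    """
    out: list[HMR] = []
    all_frags: list[tuple[np.ndarray, np.ndarray]] = []
    frag_meta: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    n_total = 0
    lv_all: list[np.ndarray] = []
    for chrom in track.chroms:
        pos, lv, rd = track.chrom_arrays(chrom)
        ok = rd > 0
        pos, lv, rd = pos[ok], lv[ok], rd[ok]
        n_total += len(pos)
        lv_all.append(lv)
        meth = np.rint(lv * rd)
        for sl in _split_fragments(pos, max_cpg_gap):
            all_frags.append((meth[sl], rd[sl].astype(float)))
            frag_meta.append((chrom, pos[sl], lv[sl], rd[sl]))
    if n_total < min_cpg:
        log.warning("track %s has < %d assessable CpGs", track.sample_id, min_cpg)
        return []
    levels = np.concatenate(lv_all)
    low_obs = levels[levels < 0.5]
    high_obs = levels[levels >= 0.5]
    init = (
        float(low_obs.mean()) if len(low_obs) else 0.1,
        float(high_obs.mean()) if len(high_obs) else 0.9,
    )
    post_low, fit = segment_betabinom(
        all_frags, init_means=init, conc=conc, stay_prob=stay_prob
    )
    if fit.mean_high - fit.mean_low < min_separation:
        return []
    background = weighted_mean_level(
        levels, np.concatenate([m[3] for m in frag_meta]) if frag_meta else []
    )
    for (chrom, pos, lv, rd), p_low in zip(frag_meta, post_low):
        state = p_low > posterior_cut
        for sl in _bool_runs(state):
            n_cpg = sl.stop - sl.start
            if n_cpg < min_cpg:
                continue
            mean = weighted_mean_level(lv[sl], rd[sl])
            if not math.isnan(background) and mean >= background:
                continue
            iv = GenomicInterval(chrom, int(pos[sl.start]), int(pos[sl.stop - 1]) + 2)
            out.append(HMR(iv, n_cpg, mean, track.sample_id))
    return out


def _bool_runs(mask: np.ndarray) -> list[slice]:
    if len(mask) == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def call_pmds(
    track: MethylomeTrack,
    bin_size: int = 1000,
    max_cpg_gap: int = 20000,
    min_domain: int = 100_000,
    min_cpg_per_bin: int = 3,
    stay_prob: float = 0.998,
    min_separation: float = 0.1,
    level_band: tuple[float, float] = (0.15, 0.75),
) -> list[PMD]:
    """Call partially methylated domains on binned mean levels.

    The track is summarized into ``bin_size`` bins (coverage-weighted mean;
    bins with fewer than ``min_cpg_per_bin`` CpGs are masked), fragmented at
    CpG gaps above ``max_cpg_gap``, and segmented with a two-state Gaussian
    chain.  Low-state runs longer than ``min_domain`` whose mean level falls
    strictly inside ``level_band`` (between HMR-like and fully methylated)
    are emitted.
    """
    frags: list[np.ndarray] = []
    meta: list[tuple[str, np.ndarray, np.ndarray]] = []  # chrom, bin starts, means
    for chrom in track.chroms:
        pos, lv, rd = track.chrom_arrays(chrom)
        ok = rd > 0
        pos, lv, rd = pos[ok], lv[ok], rd[ok]
        if len(pos) == 0:
            continue
        for sl in _split_fragments(pos, max_cpg_gap):
            p, l, r = pos[sl], lv[sl], rd[sl]
            b0 = int(p[0] // bin_size)
            idx = p // bin_size - b0
            nb = int(idx[-1]) + 1
            wsum = np.bincount(idx, weights=l * r, minlength=nb)
            wread = np.bincount(idx, weights=r.astype(float), minlength=nb)
            ncpg = np.bincount(idx, minlength=nb)
            keep = ncpg >= min_cpg_per_bin
            if keep.sum() < 2:
                continue
            means = wsum[keep] / wread[keep]
            starts = (np.flatnonzero(keep) + b0) * bin_size
            frags.append(means)
            meta.append((chrom, starts.astype(np.int64), means))
    if not frags:
        return []
    allm = np.concatenate(frags)
    mid = allm[(allm >= 0.2) & (allm < 0.7)]
    hi = allm[allm >= 0.7]
    if len(hi) == 0:
        hi = allm
    init = (float(mid.mean()) if len(mid) else 0.45, float(hi.mean()))
    post_low, fit = segment_gaussian(frags, init_means=init, stay_prob=stay_prob)
    if fit.mean_high - fit.mean_low < min_separation:
        return []
    out: list[PMD] = []
    for (chrom, starts, means), p_low in zip(meta, post_low):
        state = p_low > 0.5
        for sl in _bool_runs(state):
            start = int(starts[sl.start])
            end = int(starts[sl.stop - 1]) + bin_size
            if end - start < min_domain:
                continue
            mean = float(means[sl].mean())
            if not (level_band[0] < mean < level_band[1]):
                continue
            out.append(
                PMD(GenomicInterval(chrom, start, end), mean, sl.stop - sl.start,
                    track.sample_id)
            )
    return out


def genome_fraction(regions: IntervalSet, chrom_lengths: dict[str, int]) -> float:
    """Fraction of the genome covered by a merged interval set."""
    if not regions.merged:
        raise ValueError(
            "genome_fraction requires a merged IntervalSet (double-count hazard)"
        )
    genome_bp = sum(chrom_lengths.values())
    if genome_bp == 0:
        raise ValueError("empty genome")
    return regions.total_bp() / genome_bp


def hmrs_to_intervals(hmrs: list[HMR]) -> IntervalSet:
    """HMR calls as an interval set (mean level in the score slot)."""
    return IntervalSet(
        [
            GenomicInterval(
                h.interval.chrom, h.interval.start, h.interval.end,
                name=f"hmr_{i}", score=round(h.mean_level, 6),
            )
            for i, h in enumerate(hmrs)
        ]
    )


def pmds_to_intervals(pmds: list[PMD]) -> IntervalSet:
    return IntervalSet(
        [
            GenomicInterval(
                p.interval.chrom, p.interval.start, p.interval.end,
                name=f"pmd_{i}", score=round(p.mean_level, 6),
            )
            for i, p in enumerate(pmds)
        ]
    )
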