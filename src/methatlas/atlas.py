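"""Reference-HMR atlas: merge, per-sample re-scoring, location classes and
Gower + Ward clustering.

Per-sample HMR calls are merged into a single reference set of maximal
disjoint intervals; each reference region is re-scored in every sample
(coverage-weighted mean methylation) to form a regions x samples matrix.
Regions are classified as promoter / intragenic / intergenic and clustered
within each class with Ward linkage on pairwise Gower dissimilarities, the
range-normalized mean absolute difference over the samples assessable in
both rows (missing entries are excluded pairwise).  Cluster ids within a
category are renumbered by ascending mean methylation, so cluster 1 is the
most hypomethylated group of its category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genome import GeneModel
from .intervals import GenomicInterval, IntervalSet
from .io import MethylomeTrack

__all__ = [
    "ReferenceHMRSet",
    "merge_hmr_sets",
    "score_reference",
    "classify_location",
    "classify_locations",
    "gower_dissimilarity",
    "ward_cluster",
    "build_atlas",
]

log = logging.getLogger(__name__)

CATEGORIES = ("promoter", "intragenic", "intergenic")


@dataclass
class ReferenceHMRSet:
    """The clustered atlas: intervals, methylation matrix and labels."""

    intervals: IntervalSet
    methylation_matrix: pd.DataFrame  # rows align with intervals
    location: np.ndarray  # per-row category
    cluster_label: np.ndarray  # per-row int, 0 = unclustered (dropped row)

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if not (len(self.methylation_matrix) == len(self.location)
                == len(self.cluster_label) == n):
            raise ValueError("atlas row counts disagree")

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "location": self.location,
                "cluster": self.cluster_label,
            }
        )
        return pd.concat(
            [rows, self.methylation_matrix.reset_index(drop=True)], axis=1
        )


def merge_hmr_sets(per_sample_hmrs: list[IntervalSet]) -> IntervalSet:
    """Union of all samples' HMRs as maximal disjoint intervals."""
    ivs: list[GenomicInterval] = []
    for s in per_sample_hmrs:
        ivs.extend(s)
    return IntervalSet(ivs).merge()


def score_reference(
    reference: IntervalSet,
    tracks: list[MethylomeTrack],
    min_cpg: int = 1,
) -> pd.DataFrame:
    """Coverage-weighted mean level of every reference region in every track.

    Entries with fewer than ``min_cpg`` assessable CpGs are missing (NaN).
    """
    ref = reference if reference.merged else reference.merge()
    n = len(ref)
    out = {}
    chroms = [iv.chrom for iv in ref]
    starts = np.array([iv.start for iv in ref], dtype=np.int64)
    ends = np.array([iv.end for iv in ref], dtype=np.int64)
    for track in tracks:
        col = np.full(n, np.nan)
        for chrom in dict.fromkeys(chroms):
            rows = [i for i, c in enumerate(chroms) if c == chrom]
            pos, lv, rd = track.chrom_arrays(chrom)
            ok = rd > 0
            pos, lv, rd = pos[ok], lv[ok], rd[ok]
            if len(pos) == 0:
                continue
            cw = np.concatenate([[0.0], np.cumsum(lv * rd)])
            cr = np.concatenate([[0.0], np.cumsum(rd.astype(float))])
            cn = np.arange(len(pos) + 1, dtype=float)
            a = np.searchsorted(pos, starts[rows])
            b = np.searchsorted(pos, ends[rows])
            reads_sum = cr[b] - cr[a]
            cpgs = cn[b] - cn[a]
            with np.errstate(invalid="ignore"):
                means = (cw[b] - cw[a]) / reads_sum
            means[(cpgs < min_cpg) | (reads_sum == 0)] = np.nan
            col[rows] = means
        out[track.sample_id] = col
    return pd.DataFrame(out)


def classify_location(
    interval: GenomicInterval,
    genes: list[GeneModel],
    promoter_halfwidth: int = 1000,
) -> str:
    """promoter > intragenic > intergenic, by overlap priority.

    A region overlapping any TSS +/- halfwidth window is a promoter region
    even if it also lies in a gene body; otherwise any gene-span overlap
    makes it intragenic; otherwise it is intergenic.
    """
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        p0 = max(0, g.tss - promoter_halfwidth)
        p1 = g.tss + promoter_halfwidth
        if interval.start < p1 and p0 < interval.end:
            return "promoter"
    for g in genes:
        if g.chrom == interval.chrom and interval.overlaps(g.span):
            return "intragenic"
    return "intergenic"


def classify_locations(
    intervals: IntervalSet,
    genes: list[GeneModel],
    promoter_halfwidth: int = 1000,
) -> np.ndarray:
    promoters = IntervalSet(
        [g.promoter(promoter_halfwidth) for g in genes]
    ).merge()
    spans = IntervalSet([g.span for g in genes]).merge()
    in_prom = promoters.overlap_any(intervals)
    in_gene = spans.overlap_any(intervals)
    return np.where(in_prom, "promoter",
                    np.where(in_gene, "intragenic", "intergenic"))


def gower_dissimilarity(
    matrix, ranges: np.ndarray | None = None, min_range: float = 0.0
) -> np.ndarray:
    """All-pairs Gower dissimilarities between matrix rows.

    d(i, j) is the mean over columns assessable in both rows of
    ``|x_ic - x_jc| / range_c``.  Degenerate columns (zero or undefined
    range) are dropped with a warning; a pair sharing no assessable column
    gets NaN.  The result is symmetric with a zero diagonal and entries in
    [0, 1].
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if ranges is None:
        with np.errstate(all="ignore"):
            ranges = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    ranges = np.asarray(ranges, dtype=float)
    keep = np.isfinite(ranges) & (ranges > max(min_range, 0.0))
    if not keep.any():
        raise ValueError("all columns are degenerate (zero range)")
    if not keep.all():
        log.warning("dropping %d degenerate column(s) from Gower",
                    int((~keep).sum()))
    X = X[:, keep]
    ranges = ranges[keep]
    n = X.shape[0]
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for c in range(X.shape[1]):
        col = X[:, c]
        valid = np.isfinite(col)
        d = np.abs(col[:, None] - col[None, :]) / ranges[c]
        pair_ok = valid[:, None] & valid[None, :]
        num += np.where(pair_ok, d, 0.0)
        cnt += pair_ok
    with np.errstate(invalid="ignore"):
        D = num / cnt
    D[cnt == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D


def ward_cluster(D: np.ndarray, k: int) -> np.ndarray:
    """Cut a Ward-linkage tree built on a precomputed dissimilarity matrix.

    Uses the Lance-Williams recurrence (scipy linkage) on the condensed
    matrix; deterministic for a given matrix.  Labels are 1..k.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.isnan(D).any():
        raise ValueError("dissimilarity matrix must be complete (no NaN)")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(squareform(D, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def build_atlas(
    per_sample_hmrs: list[IntervalSet],
    tracks: list[MethylomeTrack],
    genes: list[GeneModel],
    k: int = 8,
    min_cpg: int = 1,
    max_missing_frac: float = 0.5,
    promoter_halfwidth: int = 1000,
    subsample_cap: int = 50_000,
    seed: int = 0,
) -> ReferenceHMRSet:
    """merge -> score -> classify -> per-category Gower + Ward.

    Rows missing in more than ``max_missing_frac`` of the samples are
    excluded from clustering (label 0) and reported.  Categories larger than
    ``subsample_cap`` are clustered on a seeded subsample and the remaining
    rows assigned to the nearest cluster medoid (all-pairs dissimilarity at
    full scale is not desk-sized).  Within each category, cluster numbers are
    ordered by ascending mean methylation across samples.
    """
    reference = merge_hmr_sets(per_sample_hmrs)
    matrix = score_reference(reference, tracks, min_cpg=min_cpg)
    location = classify_locations(reference, genes, promoter_halfwidth)
    labels = np.zeros(len(reference), dtype=int)

    X = matrix.to_numpy(float)
    usable = np.isfinite(X).sum(axis=1) >= X.shape[1] * (1 - max_missing_frac)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning("%d reference region(s) missing in more than half the "
                    "samples; excluded from clustering", n_dropped)

    rng = np.random.default_rng(seed)
    for category in CATEGORIES:
        rows = np.flatnonzero((location == category) & usable)
        if len(rows) == 0:
            continue
        k_eff = min(k, len(rows))
        if k_eff < k:
            log.warning("category %s has %d rows < k=%d; using k=%d",
                        category, len(rows), k, k_eff)
        if len(rows) <= subsample_cap:
            try:
                # a range floor at measurement-noise scale makes a category
                # whose rows all share one profile collapse to one cluster
                D = gower_dissimilarity(X[rows], min_range=0.02)
            except ValueError:
                log.warning("category %s has one shared profile; "
                            "single cluster emitted", category)
                labels[rows] = 1
                continue
            _fill_incomparable(D)
            labels[rows] = _ordered_labels(ward_cluster(D, k_eff), X[rows])
        else:
            sub = np.sort(rng.choice(rows, size=subsample_cap, replace=False))
            Dsub = gower_dissimilarity(X[sub])
            _fill_incomparable(Dsub)
            sub_labels = ward_cluster(Dsub, k_eff)
            medoids = _cluster_medoids(Dsub, sub_labels)
            rest = np.setdiff1d(rows, sub)
            rest_labels = _assign_to_medoids(X[rest], X[sub[medoids]],
                                             sub_labels[medoids])
            tmp = np.zeros(len(X), dtype=int)
            tmp[sub] = sub_labels
            tmp[rest] = rest_labels
            labels[rows] = _ordered_labels(tmp[rows], X[rows])
    return ReferenceHMRSet(reference, matrix, location, labels)


def _fill_incomparable(D: np.ndarray) -> None:
    """Pairs with no shared assessable sample get the maximum dissimilarity."""
    if np.isnan(D).any():
        D[np.isnan(D)] = np.nanmax(D[np.isfinite(D)]) if np.isfinite(D).any() else 1.0


def _ordered_labels(raw: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Renumber clusters by ascending mean methylation."""
    means = {}
    for lab in np.unique(raw):
        means[lab] = float(np.nanmean(X[raw == lab]))
    order = sorted(means, key=lambda lab: means[lab])
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([remap[lab] for lab in raw])


def _cluster_medoids(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    medoids = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        within = D[np.ix_(idx, idx)].sum(axis=1)
        medoids.append(idx[int(np.argmin(within))])
    return np.array(medoids)


def _assign_to_medoids(X: np.ndarray, M: np.ndarray, medoid_labels: np.ndarray
                       ) -> np.ndarray:
    with np.errstate(all="ignore"):
        ranges = np.nanmax(np.vstack([X, M]), axis=0) - np.nanmin(
            np.vstack([X, M]), axis=0
        )
    ranges[~np.isfinite(ranges) | (ranges <= 0)] = 1.0
    out = np.empty(len(X), dtype=int)
    for i, row in enumerate(X):
        diffs = np.abs(row[None, :] - M) / ranges[None, :]
        valid = np.isfinite(diffs)
        with np.errstate(invalid="ignore"):
            d = np.where(valid, diffs, 0).sum(axis=1) / valid.sum(axis=1)
        out[i] = medoid_labels[int(np.nanargmin(d))]
    return out
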