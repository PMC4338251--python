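"""Regulatory potential of HMRs and chromatin-state association tests.

An HMR's regulatory potential is the number of distinct regulatory feature
*tracks* (FANTOM5 TSS/enhancers, CGI, TFBS, DNase, MNase, HpaII, PolII — 8 by
default) it overlaps by at least one base: fewer than four is "Low", four or
more "High".  Continuous signals (histone marks) are summarized per HMR and
the top 20% of scores flagged as "high level".  Cluster-by-state association
uses Fisher's exact test with Benjamini-Hochberg adjustment, plus a pooled
two-proportion z-test for comparing state proportions between cell types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "RegulatoryScore",
    "EnrichmentResult",
    "count_overlaps",
    "regulatory_potential",
    "top_quantile_flags",
    "state_enrichment",
    "state_proportion_difference",
]


@dataclass(frozen=True)
class RegulatoryScore:
    hmr_id: str
    overlap_count: int
    potential: str  # "Low" | "High"


@dataclass
class EnrichmentResult:
    cluster_id: object
    state_name: str
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    adjusted_p: float = math.nan
    testable: bool = True


def count_overlaps(hmr: GenomicInterval,
                   feature_sets: dict[str, IntervalSet]) -> int:
    """Number of distinct feature sets overlapping the region (set-level:
    five elements of one track still count once)."""
    n = 0
    for fs in feature_sets.values():
        merged = fs if fs.merged else fs.merge()
        if merged.overlaps_interval(hmr):
            n += 1
    return n


def regulatory_potential(count: int, threshold: int = 4) -> str:
    """'High' when the region intersects ``threshold`` or more feature sets."""
    if count < 0:
        raise ValueError("negative overlap count")
    return "High" if count >= threshold else "Low"


def score_hmrs(hmrs: IntervalSet, feature_sets: dict[str, IntervalSet],
               threshold: int = 4) -> list[RegulatoryScore]:
    merged = {k: (v if v.merged else v.merge()) for k, v in feature_sets.items()}
    out = []
    for i, iv in enumerate(hmrs):
        c = count_overlaps(iv, merged)
        out.append(RegulatoryScore(iv.name or f"hmr_{i}", c,
                                   regulatory_potential(c, threshold)))
    return out


def top_quantile_flags(scores, q: float = 0.20) -> np.ndarray:
    """Flag scores at or above the (1-q) quantile (ties at the cut included)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 5:
        raise ValueError("need at least 5 scores")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    cut = np.quantile(scores, 1 - q)
    return scores >= cut


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table ((a, b), (c, d))."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def state_enrichment(cluster_membership, state_overlap: dict[str, np.ndarray],
                     adjust: str = "fdr_bh") -> list[EnrichmentResult]:
    """Per (cluster, state) 2x2 Fisher exact tests with multi-test adjustment.

    ``cluster_membership`` is a per-HMR label; ``state_overlap`` maps state
    name to a per-HMR boolean flag.  Each table is in-cluster vs not x
    overlapping vs not.  Tables with an empty margin are flagged untestable
    and excluded from the adjustment.
    """
    labels = np.asarray(cluster_membership)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    results: list[EnrichmentResult] = []
    for cluster in uniq:
        inc = labels == cluster
        for state, flags in state_overlap.items():
            flags = np.asarray(flags, dtype=bool)
            a = int((inc & flags).sum())
            b = int((inc & ~flags).sum())
            c = int((~inc & flags).sum())
            d = int((~inc & ~flags).sum())
            table = ((a, b), (c, d))
            testable = min(a + b, c + d, a + c, b + d) > 0
            if testable:
                odds, p = stats.fisher_exact([[a, b], [c, d]],
                                             alternative="two-sided")
            else:
                odds, p = math.nan, math.nan
            results.append(EnrichmentResult(cluster, state, table, float(odds)
                                            if testable else math.nan,
                                            float(p) if testable else math.nan,
                                            testable=testable))
    testable_idx = [i for i, r in enumerate(results) if r.testable]
    if testable_idx:
        raw = [results[i].p_value for i in testable_idx]
        adj = multipletests(raw, method=adjust)[1]
        for i, p_adj in zip(testable_idx, adj):
            results[i].adjusted_p = float(p_adj)
    return results


def state_proportion_difference(count_a: int, total_a: int,
                                count_b: int, total_b: int
                                ) -> tuple[float, float]:
    """Two-proportion z-test with pooled variance; returns (z, two-sided p).

    Undefined (NaN) when the pooled proportion is 0 or 1 — there is no
    variance to test against.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    p_a, p_b = count_a / total_a, count_b / total_b
    pooled = (count_a + count_b) / (total_a + total_b)
    if pooled in (0.0, 1.0):
        return math.nan, math.nan
    se = math.sqrt(pooled * (1 - pooled) * (1 / total_a + 1 / total_b))
    z = (p_a - p_b) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, float(p)
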