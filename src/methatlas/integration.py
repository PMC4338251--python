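"""Differential methylation, effect sizes, and methylation-expression
integration.

Differential methylation is the plain per-site/per-region difference of
levels (sample minus reference), a value in [-1, 1] where positive means
hypermethylation in the sample.  Cohen's d quantifies tumor-normal
methylation differences in pooled-SD units with the conventional
0.2/0.5/0.8 magnitude bins.  The internal differential-expression test is
plumbing only — a Welch test on log2(CPM + 0.5) with BH FDR — and external
DE labels are accepted verbatim when supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel
from .intervals import IntervalSet
from .io import MethylomeTrack
from .segmentation import weighted_mean_level

__all__ = [
    "ExpressionTable",
    "EffectSize",
    "differential_methylation",
    "promoter_methylation",
    "promoter_methylation_matrix",
    "cohens_d",
    "simple_de_test",
    "stratify_dm_by_expression",
    "compare_feature_methylation",
]


@dataclass
class ExpressionTable:
    """Gene x sample counts with optional DE labels."""

    counts: pd.DataFrame
    de_label: Optional[pd.Series] = None  # per gene: under / over / no_de
    fdr: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def cpm(self) -> pd.DataFrame:
        """Counts per million; each column sums to 1e6."""
        totals = self.counts.sum(axis=0)
        return self.counts / totals * 1e6


@dataclass(frozen=True)
class EffectSize:
    d: float
    n_a: int
    n_b: int

    @property
    def magnitude(self) -> str:
        a = abs(self.d)
        if math.isnan(a):
            return "undefined"
        if a < 0.2:
            return "negligible"
        if a < 0.5:
            return "small"
        if a < 0.8:
            return "medium"
        return "large"


def differential_methylation(a: pd.Series | MethylomeTrack,
                             b: pd.Series | MethylomeTrack) -> pd.DataFrame:
    """Per shared site/region difference ``a - b`` in [-1, 1].

    Positive deltas mean hypermethylation in ``a`` relative to the reference
    ``b``.  Sites missing (NaN / zero coverage) on either side are excluded;
    the count of exclusions is attached as ``df.attrs['n_excluded']``.
    """
    sa = _as_level_series(a)
    sb = _as_level_series(b)
    joined = pd.concat([sa.rename("a"), sb.rename("b")], axis=1, join="inner")
    if len(joined) == 0:
        raise ValueError("no shared sites between the two inputs")
    ok = joined.notna().all(axis=1)
    out = pd.DataFrame({"delta": joined.loc[ok, "a"] - joined.loc[ok, "b"]})
    out.attrs["n_excluded"] = int((~ok).sum())
    return out


def _as_level_series(x) -> pd.Series:
    if isinstance(x, MethylomeTrack):
        df = x.df
        idx = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
        return pd.Series(df["level"].to_numpy(), index=idx)
    return pd.Series(x)


def promoter_methylation(track: MethylomeTrack, gene: GeneModel,
                         halfwidth: int = 1000, min_cpg: int = 1) -> float:
    """Coverage-weighted mean level over [tss - halfwidth, tss + halfwidth).

    NaN when fewer than ``min_cpg`` assessable CpGs fall in the window.
    """
    pos, lv, rd = track.chrom_arrays(gene.chrom)
    lo = max(0, gene.tss - halfwidth)
    a, b = np.searchsorted(pos, [lo, gene.tss + halfwidth])
    lv, rd = lv[a:b], rd[a:b]
    if (rd > 0).sum() < min_cpg:
        return math.nan
    return weighted_mean_level(lv, rd)


def promoter_methylation_matrix(tracks: Sequence[MethylomeTrack],
                                genes: Sequence[GeneModel],
                                halfwidth: int = 1000,
                                min_cpg: int = 1) -> pd.DataFrame:
    return pd.DataFrame(
        {t.sample_id: [promoter_methylation(t, g, halfwidth, min_cpg)
                       for g in genes] for t in tracks},
        index=[g.id for g in genes],
    )


def cohens_d(group_a, group_b) -> EffectSize:
    """Standardized mean difference (mean_b - mean_a) / pooled SD.

    Pooled variance weights each group's variance by (n - 1).  Undefined
    (NaN) when the pooled variance is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    var_p = (((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
             / (len(a) + len(b) - 2))
    if var_p == 0:
        d = 0.0 if b.mean() == a.mean() else math.nan
    else:
        d = (b.mean() - a.mean()) / math.sqrt(var_p)
    return EffectSize(float(d), len(a), len(b))


def simple_de_test(table: ExpressionTable, groups: dict[str, str],
                   alpha: float = 0.05, student: bool = False
                   ) -> ExpressionTable:
    """Two-group DE on log2(CPM + 0.5): Welch t (or pooled Student), BH FDR.

    ``groups`` maps sample id to 'a' (reference) or 'b' (treatment); 'over'
    means higher in 'b'.  Genes with degenerate variance in both groups are
    labelled no_de.  Returns a new table with labels and FDR attached.
    """
    cols_a = [s for s in table.counts.columns if groups.get(s) == "a"]
    cols_b = [s for s in table.counts.columns if groups.get(s) == "b"]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per group")
    logcpm = np.log2(table.cpm + 0.5)
    xa = logcpm[cols_a].to_numpy()
    xb = logcpm[cols_b].to_numpy()
    with np.errstate(all="ignore"):
        t, p = stats.ttest_ind(xb, xa, axis=1, equal_var=student)
    p = np.asarray(p)
    degenerate = ~np.isfinite(p)
    p_for_adj = np.where(degenerate, 1.0, p)
    fdr = multipletests(p_for_adj, method="fdr_bh")[1]
    diff = xb.mean(axis=1) - xa.mean(axis=1)
    label = np.where(
        degenerate | (fdr > alpha), "no_de",
        np.where(diff > 0, "over", "under"),
    )
    return ExpressionTable(
        counts=table.counts,
        de_label=pd.Series(label, index=table.counts.index),
        fdr=pd.Series(fdr, index=table.counts.index),
    )


@dataclass
class StratifiedDM:
    """Promoter differential-methylation distributions split by DE status."""

    strata: dict[str, np.ndarray]
    medians: dict[str, float]
    under_vs_over_p: float

    @property
    def median_gap(self) -> float:
        """median delta(under) - median delta(over); positive recovers the
        negative methylation-expression coupling."""
        return self.medians.get("under", math.nan) - self.medians.get(
            "over", math.nan)


def stratify_dm_by_expression(promoter_dm: pd.Series, de_label: pd.Series
                              ) -> StratifiedDM:
    """Split per-gene promoter deltas by DE label; rank-test under vs over."""
    joined = pd.concat([promoter_dm.rename("delta"),
                        de_label.rename("label")], axis=1, join="inner")
    strata = {}
    medians = {}
    for lab in ("under", "over", "no_de"):
        vals = joined.loc[joined["label"] == lab, "delta"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        strata[lab] = vals
        medians[lab] = float(np.median(vals)) if len(vals) else math.nan
    if len(strata["under"]) and len(strata["over"]):
        p = float(stats.mannwhitneyu(strata["under"], strata["over"],
                                     alternative="two-sided").pvalue)
    else:
        p = math.nan
    return StratifiedDM(strata, medians, p)


def compare_feature_methylation(track: MethylomeTrack, features: IntervalSet,
                                partition_by: IntervalSet,
                                student: bool = False) -> dict:
    """Compare per-feature mean methylation between features overlapping and
    not overlapping a partitioning set (e.g. fragile sites with vs without
    PMDs).  Welch t-test by default; ``student`` switches to pooled variance.
    """
    part = partition_by if partition_by.merged else partition_by.merge()
    in_levels, out_levels = [], []
    for iv in features:
        pos, lv, rd = track.chrom_arrays(iv.chrom)
        a, b = np.searchsorted(pos, [iv.start, iv.end])
        m = weighted_mean_level(lv[a:b], rd[a:b])
        if math.isnan(m):
            continue
        (in_levels if part.overlaps_interval(iv) else out_levels).append(m)
    result = {
        "overlapping": np.array(in_levels),
        "non_overlapping": np.array(out_levels),
        "testable": len(in_levels) >= 2 and len(out_levels) >= 2,
        "t": math.nan,
        "p": math.nan,
    }
    if result["testable"]:
        t, p = stats.ttest_ind(in_levels, out_levels, equal_var=student)
        result["t"], result["p"] = float(t), float(p)
    return result
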