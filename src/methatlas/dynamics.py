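"""HMR width expansion/contraction between a reference (normal) sample and
another methylome.

Each normal-breast HMR is matched against the other sample's HMRs; the
matched width is the summed width of every overlapping HMR (a split HMR has
not contracted in covered bases, so widths add rather than taking the
largest).  The log2 width ratio is binned into the conventional categories:
|log2 FC| < 0.19 unchanged, 0.19-1 small (+/-), 1-3 large (++/--), >= 3
extreme (+++/---, i.e. more than eight times the reference width).  Boundary
values fall into the higher-|change| bin.  HMRs with no overlap at all are
"lost".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .intervals import GenomicInterval, IntervalSet

__all__ = ["WidthChange", "match_widths", "classify_width_change", "annotate_cgi"]

DEFAULT_BINS = (0.19, 1.0, 3.0)


@dataclass
class WidthChange:
    nb_hmr: GenomicInterval
    matched_width: int
    log2_fc: float  # -inf when lost
    category: Optional[str] = None  # unchanged, +, ++, +++, -, --, ---, lost
    has_cgi: Optional[bool] = None


def match_widths(nb_hmrs: IntervalSet, other_hmrs: IntervalSet
                 ) -> list[WidthChange]:
    """Sum, per reference HMR, the widths of all overlapping other-sample HMRs."""
    other = other_hmrs if other_hmrs.merged else other_hmrs.merge()
    index = other._build_index()
    out = []
    for iv in nb_hmrs:
        idx = other.overlapping_range(iv.chrom, iv.start, iv.end)
        if len(idx):
            starts, ends = index[iv.chrom]
            matched = int((ends[list(idx)] - starts[list(idx)]).sum())
        else:
            matched = 0
        log2_fc = math.log2(matched / iv.width) if matched > 0 else -math.inf
        out.append(WidthChange(iv, matched, log2_fc))
    return out


def classify_width_change(log2_fc: float,
                          bins: tuple[float, float, float] = DEFAULT_BINS) -> str:
    """Bin a log2 width ratio; -inf means the reference HMR was lost."""
    if math.isinf(log2_fc) and log2_fc < 0:
        return "lost"
    if math.isnan(log2_fc):
        raise ValueError("log2_fc must be finite or -inf (lost)")
    mag = abs(log2_fc)
    small, large, extreme = bins
    if mag < small:
        return "unchanged"
    sign = "+" if log2_fc > 0 else "-"
    if mag < large:
        return sign
    if mag < extreme:
        return sign * 2
    return sign * 3


def annotate_cgi(changes: list[WidthChange], cgis: IntervalSet,
                 bins: tuple[float, float, float] = DEFAULT_BINS
                 ) -> list[WidthChange]:
    """Set category and CGI-intersection flag on each width change (in place)."""
    merged = cgis if cgis.merged else cgis.merge()
    for wc in changes:
        wc.category = classify_width_change(wc.log2_fc, bins)
        wc.has_cgi = merged.overlaps_interval(wc.nb_hmr)
    return changes
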