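"""Detection of X-chromosome-inactivation (XCI) dysregulation in paired
tumor-normal cohorts.

In an XCI-intact female methylome, X-linked promoters sit near 50%
methylation (one allele silenced).  Loss of XCI shows up as tumor-vs-normal
hypomethylation of X promoters, hypermethylation/silencing of XIST, and
over-expression of a subset of X-linked genes.  Patients are split into the
dysregulated vs normal populations with a two-component Gaussian mixture on
per-patient mean X-promoter deltas (with a minimum-separation floor so a
null cohort yields no calls); escapee-like genes are those both
significantly hypomethylated and significantly over-expressed in the
dysregulated group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedCohort",
    "XCICall",
    "EscapeeLikeGene",
    "x_promoter_deltas",
    "classify_xci_status",
    "xist_group_test",
    "call_escapee_like",
    "male_pattern_similarity",
]


@dataclass
class PairedCohort:
    """Per-patient paired promoter methylation and expression."""

    patients: list[str]
    promoter_meth_normal: pd.DataFrame  # genes x patients
    promoter_meth_tumor: pd.DataFrame
    expr_normal: pd.DataFrame
    expr_tumor: pd.DataFrame
    x_genes: list[str]
    xist_gene_id: str

    def __post_init__(self) -> None:
        for df in (self.promoter_meth_normal, self.promoter_meth_tumor,
                   self.expr_normal, self.expr_tumor):
            if list(df.columns) != list(self.patients):
                raise ValueError("every patient needs both tissue columns in "
                                 "every matrix")
        for df in (self.promoter_meth_normal, self.promoter_meth_tumor):
            vals = df.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if ((finite < 0) | (finite > 1)).any():
                raise ValueError("methylation levels must lie in [0, 1]")


@dataclass(frozen=True)
class XCICall:
    patient: str
    mean_x_delta: float
    status: str  # xci_dysregulated | xci_normal


@dataclass(frozen=True)
class EscapeeLikeGene:
    gene: str
    group_delta_meth: float  # dysregulated - normal group tumor methylation
    meth_p: float
    group_logfc_expr: float
    expression_p: float
    called: bool


def x_promoter_deltas(cohort: PairedCohort, min_promoters: int = 5
                      ) -> tuple[pd.Series, list[str]]:
    """Per patient, the mean over assessable X promoters of tumor - normal.

    XIST's own promoter is excluded (it moves opposite to the rest).
    Patients with fewer than ``min_promoters`` assessable X promoters are
    excluded and reported in the second return value.
    """
    genes = [g for g in cohort.x_genes if g != cohort.xist_gene_id]
    delta = (cohort.promoter_meth_tumor.loc[genes]
             - cohort.promoter_meth_normal.loc[genes])
    n_ok = delta.notna().sum(axis=0)
    means = delta.mean(axis=0, skipna=True)
    excluded = [p for p in cohort.patients if n_ok[p] < min_promoters]
    return means.drop(excluded), excluded


def classify_xci_status(deltas: pd.Series, separation_floor: float = 0.1,
                        threshold: Optional[float] = None) -> list[XCICall]:
    """Split patients into two populations on their mean X-promoter delta.

    Default: a one-dimensional two-component Gaussian mixture; the
    lower-mean (hypomethylated) component is the dysregulated one.  When the
    component means are closer than ``separation_floor`` the cohort is
    treated as a single population and every patient is called normal.
    ``threshold`` switches to a simple cut (delta below threshold =
    dysregulated).
    """
    if len(deltas) < 4 and threshold is None:
        raise ValueError("mixture classification needs at least 4 patients")
    x = deltas.to_numpy(float)
    if threshold is not None:
        dys = x < threshold
    else:
        mu, post_low = _two_component_em(x)
        if abs(mu[1] - mu[0]) < separation_floor:
            dys = np.zeros(len(x), dtype=bool)
        else:
            dys = post_low >= 0.5
    return [
        XCICall(p, float(d), "xci_dysregulated" if is_d else "xci_normal")
        for p, d, is_d in zip(deltas.index, x, dys)
    ]


def _two_component_em(x: np.ndarray, max_iter: int = 500, tol: float = 1e-10
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D two-component Gaussian mixture.

    Quantile-based initialization makes the fit invariant to sample order
    and equivariant under a common location shift.  Returns the sorted
    component means (low first) and the posterior probability of the
    low-mean component per point.
    """
    mu = np.quantile(x, [0.25, 0.75]).astype(float)
    if mu[0] == mu[1]:
        mu = mu + np.array([-1e-6, 1e-6])
    var = np.full(2, max(x.var() / 4, 1e-8))
    w = np.array([0.5, 0.5])
    post = None
    for _ in range(max_iter):
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        nk = p.sum(axis=0)
        new_mu = (p * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        new_var = np.maximum(
            (p * (x[:, None] - new_mu[None, :]) ** 2).sum(axis=0)
            / np.maximum(nk, 1e-12), 1e-8)
        new_w = nk / len(x)
        done = np.abs(new_mu - mu).max() < tol
        mu, var, w, post = new_mu, new_var, new_w, p
        if done:
            break
    order = np.argsort(mu)
    return mu[order], post[:, order[0]]


def _groups(calls: list[XCICall]) -> tuple[list[str], list[str]]:
    dys = [c.patient for c in calls if c.status == "xci_dysregulated"]
    norm = [c.patient for c in calls if c.status == "xci_normal"]
    return dys, norm


def xist_group_test(cohort: PairedCohort, calls: list[XCICall],
                    student: bool = False) -> tuple[float, float]:
    """t-test of tumor XIST expression, dysregulated vs normal group.

    Returns (t, two-sided p); t < 0 when the dysregulated group has the
    lower XIST expression.
    """
    dys, norm = _groups(calls)
    if len(dys) < 2 or len(norm) < 2:
        return math.nan, math.nan
    xist = cohort.expr_tumor.loc[cohort.xist_gene_id]
    a, b = xist[dys].to_numpy(float), xist[norm].to_numpy(float)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=student)
    return float(t), float(p)


def call_escapee_like(cohort: PairedCohort, calls: list[XCICall],
                      alpha: float = 0.01, student: bool = False
                      ) -> list[EscapeeLikeGene]:
    """Per X gene, test the dysregulated group for promoter hypomethylation
    AND expression elevation (both two-sided p < alpha, with the required
    directions).  Genes with degenerate variance are skipped.
    """
    dys, norm = _groups(calls)
    if len(dys) < 2 or len(norm) < 2:
        raise ValueError("both groups need at least 2 patients")
    out: list[EscapeeLikeGene] = []
    genes = [g for g in cohort.x_genes if g != cohort.xist_gene_id]
    for g in genes:
        m_d = cohort.promoter_meth_tumor.loc[g, dys].to_numpy(float)
        m_n = cohort.promoter_meth_tumor.loc[g, norm].to_numpy(float)
        e_d = cohort.expr_tumor.loc[g, dys].to_numpy(float)
        e_n = cohort.expr_tumor.loc[g, norm].to_numpy(float)
        if (np.ptp(m_d) == 0 and np.ptp(m_n) == 0) or (
                np.ptp(e_d) == 0 and np.ptp(e_n) == 0):
            continue
        _, p_m = stats.ttest_ind(m_d, m_n, equal_var=student)
        _, p_e = stats.ttest_ind(np.log2(e_d + 1), np.log2(e_n + 1),
                                 equal_var=student)
        dm = float(m_d.mean() - m_n.mean())
        lfc = float(np.log2(e_d.mean() + 1) - np.log2(e_n.mean() + 1))
        called = bool(dm < 0 and p_m < alpha and lfc > 0 and p_e < alpha)
        out.append(EscapeeLikeGene(g, dm, float(p_m), lfc, float(p_e), called))
    return out


def male_pattern_similarity(female: pd.Series, reference: pd.Series,
                            low: float = 0.25, mid: tuple[float, float] = (0.35, 0.65),
                            diag_tol: float = 0.15) -> dict:
    """Compare female X-promoter methylation against a male-like reference.

    The XCI signature is the off-diagonal cloud: female promoters near 50%
    (one methylated allele) while the single-X reference is hypomethylated.
    Returns the off-diagonal fraction, the on-diagonal fraction, and n.
    """
    joined = pd.concat([female.rename("f"), reference.rename("r")],
                       axis=1, join="inner").dropna()
    if len(joined) < 20:
        raise ValueError("need at least 20 shared X promoters")
    f = joined["f"].to_numpy(float)
    r = joined["r"].to_numpy(float)
    off = (f >= mid[0]) & (f <= mid[1]) & (r < low)
    diag = np.abs(f - r) <= diag_tol
    return {
        "n": len(joined),
        "off_diagonal_fraction": float(off.mean()),
        "diagonal_fraction": float(diag.mean()),
    }
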