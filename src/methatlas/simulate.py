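"""Synthetic methylome, expression and paired-cohort generators.

The generators emulate a seven-sample breast methylome panel: one normal
tissue (NB), a benign tumor (BT089), two invasive carcinomas (BT126, BT198),
a normal mammary epithelial line (HMEC) and two cancer lines (MCF7, HCC1954).
The genome is mostly methylated (~0.8) with hypomethylated regions (HMRs) at
CpG-dense promoters and planted regulatory regions, megabase
partially-methylated blocks (~0.45) in tumor-like archetypes, 24 planted HMR
cluster archetypes (8 per genomic category) whose per-sample methylation
follows a fixed profile table, beta-binomially noised read counts at ~18.8x
mean depth (the panel's average sequencing depth), and expression counts with
methylation-linked repression for designated clusters.  The paired cohort
emulates 78 tumor-normal pairs of which a planted subpopulation shows
X-promoter hypomethylation, XIST promoter hypermethylation with reduced XIST
expression, and over-expression of a subset of X-linked genes.

All generators are deterministic for a fixed seed and return planted-truth
objects alongside the data so downstream callers can be scored against
ground truth.  Truth is returned as separate objects (sidecar files when
written to disk), never embedded in the data formats themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation
from .intervals import GenomicInterval, IntervalSet
from .io import MethylomeTrack

__all__ = [
    "SAMPLES",
    "ArchetypeSpec",
    "CohortSpec",
    "LinkSpec",
    "default_cluster_profiles",
    "default_archetypes",
    "generate_methylome",
    "generate_expression",
    "generate_paired_cohort",
    "sample_reference_matrix",
]

SAMPLES = ["NB", "BT089", "BT126", "BT198", "HMEC", "MCF7", "HCC1954"]

_LOW = 0.08
_HIGH = 0.85

# Which samples are methylated (high) in each cluster.  Patterns are distinct
# within a category; cluster 1 is the universally hypomethylated one and the
# promoter cluster 8 (A-8-like) carries the allelic 0.5 X-inactivation level
# in XCI-intact samples.
_HIGH_SETS = {
    1: set(),
    2: {"MCF7"},
    3: {"MCF7", "HCC1954"},
    4: {"BT126", "BT198", "MCF7", "HCC1954"},
    5: {"NB", "BT089"},
    6: {"NB", "BT089", "BT126", "BT198"},
    7: {"NB", "BT089", "BT126", "BT198", "HMEC"},
    8: {"HMEC", "MCF7", "HCC1954"},
}

_XCI_LOST = {"MCF7", "HCC1954"}


def default_cluster_profiles() -> pd.DataFrame:
    """24-cluster x 7-sample target-methylation table.

    Index is ``(category, cluster)``; values are the target level of a
    cluster's regions in each sample.  Promoter cluster 8 is the X-linked
    archetype: allelically methylated (0.5) where X inactivation is intact,
    hypomethylated where it is lost.
    """
    rows = []
    index = []
    for category in ["promoter", "intragenic", "intergenic"]:
        for cluster in range(1, 9):
            if category == "promoter" and cluster == 8:
                row = {
                    s: (_LOW if s in _XCI_LOST else 0.5) for s in SAMPLES
                }
            else:
                hi = _HIGH_SETS[cluster]
                row = {s: (_HIGH if s in hi else _LOW) for s in SAMPLES}
            rows.append(row)
            index.append((category, cluster))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["category", "cluster"])
    )


@dataclass
class ArchetypeSpec:
    """Per-sample generative parameters.

    ``dispersion`` is the beta-binomial overdispersion rho in [0, 1): the
    per-CpG methylated fraction is drawn from Beta with mean equal to the
    regional target and concentration ``(1 - rho) / rho``; rho = 0 collapses
    to a plain binomial.  ``mean_depth`` may be ``inf`` together with
    ``dispersion = 0`` for the exact noiseless limit.
    """

    name: str  # one of normal / benign / invasive / cell_line / male_like
    background_level: float = 0.8
    hmr_level: float = 0.05
    pmd_level: float = 0.45
    pmd_blocks: IntervalSet = field(default_factory=IntervalSet)
    cluster_profiles: dict = field(default_factory=dict)  # (category, cluster) -> level
    mean_depth: float = 18.8
    dispersion: float = 0.05
    xist_promoter_level: float = 0.5
    sample_id: str = ""

    def __post_init__(self) -> None:
        for v in (self.background_level, self.hmr_level, self.pmd_level):
            if not 0 <= v <= 1:
                raise ValueError(f"level outside [0,1]: {v}")
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must be in [0, 1)")
        if not self.sample_id:
            self.sample_id = self.name


_KINDS = {
    "NB": "normal",
    "BT089": "benign",
    "BT126": "invasive",
    "BT198": "invasive",
    "HMEC": "cell_line",
    "MCF7": "cell_line",
    "HCC1954": "cell_line",
}

# Planted PMD genome-fraction targets: <1% in the normal and benign samples,
# intermediate in the invasive carcinomas, 25-35% (configured 30%) in the
# cultured lines.
_PMD_FRACTIONS = {
    "NB": 0.0,
    "BT089": 0.005,
    "BT126": 0.07,
    "BT198": 0.16,
    "HMEC": 0.30,
    "MCF7": 0.30,
    "HCC1954": 0.30,
}


def _pick_pmd_blocks(genome: GenomeAnnotation, target_fraction: float,
                     rng: np.random.Generator) -> IntervalSet:
    blocks = list(genome.pmd_candidate_blocks)
    if target_fraction <= 0 or not blocks:
        return IntervalSet(assume_merged=True)
    genome_bp = sum(genome.chrom_lengths.values())
    order = rng.permutation(len(blocks))
    chosen: list[GenomicInterval] = []
    covered = 0
    for i in order:
        chosen.append(blocks[int(i)])
        covered += blocks[int(i)].width
        if covered >= target_fraction * genome_bp:
            break
    return IntervalSet(chosen).merge()


def default_archetypes(genome: GenomeAnnotation, seed: int = 0,
                       mean_depth: float = 18.8,
                       dispersion: float = 0.05) -> dict[str, ArchetypeSpec]:
    """The seven-sample panel with its planted profile table."""
    profiles = default_cluster_profiles()
    rng = np.random.default_rng(seed)
    out: dict[str, ArchetypeSpec] = {}
    for sample in SAMPLES:
        out[sample] = ArchetypeSpec(
            name=_KINDS[sample],
            sample_id=sample,
            pmd_blocks=_pick_pmd_blocks(genome, _PMD_FRACTIONS[sample], rng),
            cluster_profiles=dict(profiles[sample]),
            mean_depth=mean_depth,
            dispersion=dispersion,
            xist_promoter_level=0.9 if sample in _XCI_LOST else 0.5,
        )
    return out


def male_like_archetype(genome: GenomeAnnotation, **kw) -> ArchetypeSpec:
    """A male-reference-like methylome: X promoters unmethylated (single
    active X), XIST promoter methylated/silent."""
    profiles = default_cluster_profiles()
    prof = dict(profiles["NB"])
    prof[("promoter", 8)] = _LOW
    return ArchetypeSpec(
        name="male_like", sample_id="male_ref", cluster_profiles=prof,
        xist_promoter_level=_HIGH, **kw,
    )


def _target_levels(genome: GenomeAnnotation, archetype: ArchetypeSpec
                   ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-CpG piecewise-constant target level and the per-region table."""
    levels = {
        chrom: np.full(len(pos), archetype.background_level)
        for chrom, pos in genome.cpg_positions.items()
    }
    pmd = archetype.pmd_blocks
    if len(pmd):
        for chrom, pos in genome.cpg_positions.items():
            mask = pmd.contains_positions(chrom, pos)
            levels[chrom][mask] = archetype.pmd_level
    rows = []
    for row in genome.cluster_regions.itertuples(index=False):
        key = (row.category, row.cluster)
        target = archetype.cluster_profiles.get(key, archetype.hmr_level)
        # map the generic profile low onto this archetype's HMR level
        if target <= _LOW:
            target = archetype.hmr_level
        if row.gene_id == genome.xist_gene_id and row.category == "promoter":
            target = archetype.xist_promoter_level
        pos = genome.cpg_positions[row.chrom]
        a, b = np.searchsorted(pos, [row.start, row.end])
        levels[row.chrom][a:b] = target
        rows.append(
            {"chrom": row.chrom, "start": row.start, "end": row.end,
             "category": row.category, "cluster": row.cluster,
             "gene_id": row.gene_id, "target_level": target}
        )
    return levels, pd.DataFrame(rows)


def generate_methylome(genome: GenomeAnnotation, archetype: ArchetypeSpec,
                       seed: int = 0) -> tuple[MethylomeTrack, dict]:
    """Draw a noised per-CpG track from an archetype's target level function.

    Returns ``(track, truth)`` where truth holds the planted HMR and PMD
    interval sets (sorted, disjoint) and the per-region target-level table.
    """
    rng = np.random.default_rng(seed)
    levels, region_table = _target_levels(genome, archetype)
    noiseless = archetype.dispersion == 0 and math.isinf(archetype.mean_depth)

    frames = []
    for chrom, pos in genome.cpg_positions.items():
        target = levels[chrom]
        n = len(pos)
        if noiseless:
            reads = np.full(n, 1000, dtype=np.int64)
            obs = target.copy()
        else:
            reads = rng.poisson(archetype.mean_depth, size=n).astype(np.int64)
            if archetype.dispersion > 0:
                conc = (1 - archetype.dispersion) / archetype.dispersion
                a = np.clip(target, 1e-3, 1 - 1e-3) * conc
                b = conc - a
                p = rng.beta(a, b)
            else:
                p = target
            meth = rng.binomial(np.maximum(reads, 0), p)
            with np.errstate(invalid="ignore"):
                obs = np.where(reads > 0, meth / np.maximum(reads, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "strand": "+", "context": "CpG",
                 "level": obs, "reads": reads}
            )
        )
    track = MethylomeTrack(archetype.sample_id, pd.concat(frames, ignore_index=True))

    hmr_truth = IntervalSet(
        [GenomicInterval(r.chrom, r.start, r.end)
         for r in region_table.itertuples(index=False) if r.target_level < 0.2]
    ).merge()
    truth = {
        "hmr": hmr_truth,
        "pmd": archetype.pmd_blocks if archetype.pmd_blocks.merged
        else archetype.pmd_blocks.merge(),
        "regions": region_table,
    }
    return track, truth


@dataclass
class LinkSpec:
    """Methylation->expression link for designated promoter clusters.

    For genes whose promoter belongs to a linked cluster, expected
    log2-expression is ``log2(base) + slope * (0.5 - promoter methylation)``;
    a positive slope therefore represses methylated promoters.  Unlinked
    genes ignore methylation entirely.
    """

    linked_clusters: frozenset = frozenset({3, 6, 8})
    slope: float = 4.0
    base_mean: float = 100.0
    nb_dispersion: float = 0.1


def generate_expression(genome: GenomeAnnotation, promoter_meth: pd.DataFrame,
                        link: LinkSpec, seed: int = 0):
    """Negative-binomial expression counts tied to promoter methylation.

    ``promoter_meth`` is genes x samples.  Returns an
    :class:`~methatlas.integration.ExpressionTable` plus the set of linked
    gene ids (truth).
    """
    from .integration import ExpressionTable

    rng = np.random.default_rng(seed)
    gene_cluster = {
        r.gene_id: r.cluster
        for r in genome.cluster_regions.itertuples(index=False)
        if r.category == "promoter" and r.gene_id is not None
    }
    genes = list(promoter_meth.index)
    samples = list(promoter_meth.columns)
    base = link.base_mean * rng.lognormal(0.0, 0.6, size=len(genes))
    linked = np.array(
        [gene_cluster.get(g) in link.linked_clusters for g in genes]
    )
    meth = promoter_meth.to_numpy(float)
    log2mu = np.log2(base)[:, None] + np.where(
        linked[:, None], link.slope * (0.5 - np.nan_to_num(meth, nan=0.5)), 0.0
    )
    mu = np.power(2.0, log2mu)
    if link.nb_dispersion > 0:
        r = 1.0 / link.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    table = ExpressionTable(
        counts=pd.DataFrame(counts, index=genes, columns=samples)
    )
    return table, {g for g, is_l in zip(genes, linked) if is_l}


@dataclass
class CohortSpec:
    """Planted paired tumor-normal cohort with an XCI-loss subpopulation."""

    n_patients: int = 78
    xci_loss_fraction: float = 36 / 78
    x_promoter_delta: float = -0.3
    affected_gene_fraction: float = 0.4
    expression_effect: float = 2.0  # log2 fold-change of affected X genes
    patient_delta_sd: float = 0.05
    gene_noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.xci_loss_fraction <= 1:
            raise ValueError("xci_loss_fraction must be in [0, 1]")
        if not 0 <= self.affected_gene_fraction <= 1:
            raise ValueError("affected_gene_fraction must be in [0, 1]")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


def generate_paired_cohort(genome: GenomeAnnotation, spec: CohortSpec):
    """Simulate per-patient normal/tumor promoter methylation and expression.

    Exactly ``round(n_patients * xci_loss_fraction)`` patients carry the
    X-promoter hypomethylation shift, XIST promoter hypermethylation with
    reduced XIST expression, and over-expression of the affected X-gene
    subset.  Returns ``(PairedCohort, truth)`` with truth naming the affected
    patients and genes.
    """
    from .xci import PairedCohort

    spec.validate()
    x_genes = [g.id for g in genome.x_genes]
    if len(x_genes) < 20:
        raise ValueError("genome must carry at least 20 X-linked genes")
    rng = np.random.default_rng(spec.seed)
    patients = [f"P{i:03d}" for i in range(spec.n_patients)]
    n_affected = round(spec.n_patients * spec.xci_loss_fraction)
    affected_patients = sorted(
        rng.choice(patients, size=n_affected, replace=False).tolist()
    )
    xist = genome.xist_gene_id
    x_nonxist = [g for g in x_genes if g != xist]
    n_aff_genes = round(spec.affected_gene_fraction * len(x_nonxist))
    affected_genes = sorted(
        rng.choice(x_nonxist, size=n_aff_genes, replace=False).tolist()
    )

    auto_genes = [g.id for g in genome.genes if not g.is_x_linked]
    all_genes = x_genes + auto_genes
    n_g, n_p = len(all_genes), spec.n_patients
    is_x = np.array([g in set(x_genes) for g in all_genes])
    is_xist = np.array([g == xist for g in all_genes])

    base = np.where(is_x, 0.5, 0.12)[:, None] + rng.normal(0, 0.02, (n_g, n_p))
    normal = np.clip(base, 0.01, 0.99)
    tumor = normal + rng.normal(0, spec.gene_noise_sd, (n_g, n_p))
    aff_mask = np.array([p in set(affected_patients) for p in patients])
    shifts = rng.normal(spec.x_promoter_delta, spec.patient_delta_sd,
                        size=aff_mask.sum())
    tumor[np.ix_(is_x & ~is_xist, aff_mask)] += shifts[None, :]
    # XIST moves the other way: hypermethylated where XCI is lost
    tumor[np.ix_(is_xist, aff_mask)] += -spec.x_promoter_delta
    tumor = np.clip(tumor, 0.0, 1.0)

    expr_base = rng.lognormal(3.0, 0.5, size=n_g)
    noise = lambda: rng.lognormal(0.0, 0.25, (n_g, n_p))  # noqa: E731
    expr_normal = expr_base[:, None] * noise()
    expr_tumor = expr_base[:, None] * noise()
    aff_gene_mask = np.array([g in set(affected_genes) for g in all_genes])
    expr_tumor[np.ix_(aff_gene_mask, aff_mask)] *= 2.0 ** spec.expression_effect
    expr_tumor[np.ix_(is_xist, aff_mask)] *= 2.0 ** (-spec.expression_effect)

    cohort = PairedCohort(
        patients=patients,
        promoter_meth_normal=pd.DataFrame(normal, index=all_genes, columns=patients),
        promoter_meth_tumor=pd.DataFrame(tumor, index=all_genes, columns=patients),
        expr_normal=pd.DataFrame(expr_normal, index=all_genes, columns=patients),
        expr_tumor=pd.DataFrame(expr_tumor, index=all_genes, columns=patients),
        x_genes=x_genes,
        xist_gene_id=xist,
    )
    truth = {"affected_patients": affected_patients,
             "affected_genes": affected_genes}
    return cohort, truth


def sample_reference_matrix(n_regions: int = 2400, n_samples: int = 7,
                            mean_cpg: float = 15.0, mean_depth: float = 18.8,
                            dispersion: float = 0.05, seed: int = 0):
    """Draw a reference-HMR methylation matrix straight from the 24 planted
    cluster profiles (region-level measurement noise only).

    Returns ``(matrix, categories, clusters)``: a regions x samples DataFrame
    plus the planted category/cluster label per row.  Used for clustering
    calibration without re-running segmentation.
    """
    rng = np.random.default_rng(seed)
    profiles = default_cluster_profiles()
    keys = list(profiles.index)
    reps = int(np.ceil(n_regions / len(keys)))
    assign = (keys * reps)[:n_regions]
    conc = (1 - dispersion) / dispersion if dispersion > 0 else None
    rows = np.empty((n_regions, len(SAMPLES)))
    for i, key in enumerate(assign):
        targets = profiles.loc[key].to_numpy(float)
        n_cpg = max(3, rng.poisson(mean_cpg))
        reads = np.maximum(rng.poisson(mean_depth, size=(n_cpg, len(SAMPLES))), 1)
        t = np.clip(np.broadcast_to(targets, (n_cpg, len(SAMPLES))), 1e-3, 1 - 1e-3)
        p = rng.beta(t * conc, (1 - t) * conc) if conc is not None else t
        meth = rng.binomial(reads, p)
        rows[i] = meth.sum(axis=0) / reads.sum(axis=0)
    matrix = pd.DataFrame(rows, columns=SAMPLES)
    categories = np.array([k[0] for k in assign])
    clusters = np.array([k[1] for k in assign])
    return matrix, categories, clusters
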