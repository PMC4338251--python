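"""Synthetic genome annotation generator.

Produces a small genome with the structural features the analysis pipeline
assumes: CpG positions with CpG-island peaks at promoters, gene models (one
X-like chromosome carrying X-linked genes plus a designated XIST stand-in),
planted cluster regions for the reference-HMR atlas (8 promoter, 8
intragenic, 8 intergenic archetype clusters), regulatory feature tracks,
chromatin-state segments for two cell-type archetypes, candidate blocks for
partially-methylated domains in CpG-poor gene deserts, and fragile-site-like
blocks.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .intervals import GenomicInterval, IntervalSet

__all__ = ["GeneModel", "GenomeConfig", "GenomeAnnotation", "generate_genome",
           "FEATURE_NAMES"]

FEATURE_NAMES = [
    "fantom5_tss",
    "fantom5_enhancer",
    "cgi",
    "encode_tfbs",
    "dnase_hs",
    "mnase_hs",
    "hpaii_hs",
    "polii",
]


@dataclass(frozen=True)
class GeneModel:
    id: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval
    is_x_linked: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        expect = self.span.start if self.strand == "+" else self.span.end
        if self.tss != expect:
            raise ValueError("TSS must sit on the strand-consistent span boundary")

    def promoter(self, halfwidth: int = 1000) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, max(0, self.tss - halfwidth), self.tss + halfwidth
        )


@dataclass
class GenomeConfig:
    """Layout of the synthetic genome.

    Each chromosome is split into a gene region (first ``gene_region_frac``)
    and a CpG-poor desert holding candidate PMD blocks.  Densities are CpGs
    per bp (0.01 = 1 per 100 bp).
    """

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 3_000_000), ("chr2", 3_000_000),
                                 ("chrX", 2_400_000)]
    )
    x_chrom: str = "chrX"
    n_genes: int = 150
    background_density: float = 0.005
    cgi_density: float = 0.10
    region_density: float = 0.03  # planted non-promoter HMR regions
    cgi_halfwidth: int = 400
    promoter_halfwidth: int = 1000
    gene_span: tuple[int, int] = (5_000, 20_000)
    gene_region_frac: float = 0.55
    pmd_block_size: int = 250_000
    n_fragile_blocks: int = 6
    clusters_per_category: int = 8
    intergenic_regions_per_chrom: int = 30
    region_width: tuple[int, int] = (800, 2_000)

    def validate(self) -> None:
        min_len = 10 * 2 * self.promoter_halfwidth
        for name, length in self.chromosomes:
            if length < min_len:
                raise ValueError(
                    f"chromosome {name} shorter than 10x promoter width "
                    f"({length} < {min_len})"
                )
        if self.x_chrom not in [c for c, _ in self.chromosomes]:
            raise ValueError(f"genome must include the X-like chromosome "
                             f"{self.x_chrom!r}")
        if not 0 < self.gene_region_frac < 1:
            raise ValueError("gene_region_frac must be in (0, 1)")


@dataclass
class GenomeAnnotation:
    """A generated genome: coordinates, genes, planted structure, features."""

    chromosomes: list[tuple[str, int]]
    cpg_positions: dict[str, np.ndarray]
    cgis: IntervalSet
    genes: list[GeneModel]
    feature_sets: dict[str, IntervalSet]
    state_segments: dict[str, dict[str, IntervalSet]]
    fragile_blocks: IntervalSet
    pmd_candidate_blocks: IntervalSet
    cluster_regions: "object"  # DataFrame: chrom,start,end,category,cluster,gene_id
    x_chrom: str
    xist_gene_id: str
    config: GenomeConfig

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def x_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_x_linked]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)


def _sample_positions(rng, start: int, end: int, density: float) -> np.ndarray:
    n = int(round((end - start) * density))
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    pos = np.unique(rng.integers(start, end, size=n))
    return pos.astype(np.int64)


def generate_genome(config: Optional[GenomeConfig] = None, seed: int = 0
                    ) -> GenomeAnnotation:
    """Generate a deterministic synthetic genome annotation."""
    import pandas as pd

    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    genes: list[GeneModel] = []
    cgi_list: list[GenomicInterval] = []
    pmd_blocks: list[GenomicInterval] = []
    fragile: list[GenomicInterval] = []
    cluster_rows: list[dict] = []
    dense_regions: dict[str, list[tuple[int, int, float]]] = {
        c: [] for c, _ in config.chromosomes
    }

    chrom_names = [c for c, _ in config.chromosomes]
    n_chrom = len(chrom_names)
    # apportion genes over chromosomes proportionally to length
    lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    gene_counts = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    gene_counts[: config.n_genes - gene_counts.sum()] += 1

    k = config.clusters_per_category
    promoter_cluster_cycle = _cluster_assignment_cycle(k)

    gi = 0
    for (chrom, length), n_genes_c in zip(config.chromosomes, gene_counts):
        gene_region_end = int(length * config.gene_region_frac)
        span_lo, span_hi = config.gene_span
        # lay genes left to right with random spacing, no overlap
        slot = gene_region_end / max(n_genes_c, 1)
        is_x = chrom == config.x_chrom
        for j in range(n_genes_c):
            span_len = int(rng.integers(span_lo, span_hi))
            lo = int(j * slot) + 2 * config.promoter_halfwidth
            hi = int((j + 1) * slot) - span_len - 100
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else start + span_len
            gene = GeneModel(
                id=f"{chrom}_g{gi}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                span=GenomicInterval(chrom, start, start + span_len),
                is_x_linked=is_x,
            )
            genes.append(gene)
            gi += 1
            cgi = GenomicInterval(
                chrom, max(0, tss - config.cgi_halfwidth), tss + config.cgi_halfwidth
            )
            cgi_list.append(cgi)
            dense_regions[chrom].append((cgi.start, cgi.end, config.cgi_density))
            # CGI-shore-like elevated density across the whole promoter, so
            # promoter HMRs are CpG-supported out to their edges
            dense_regions[chrom].append(
                (max(0, tss - config.promoter_halfwidth),
                 tss + config.promoter_halfwidth, config.region_density)
            )
            # every promoter is a planted promoter-category cluster region
            cluster_rows.append(
                {
                    "chrom": chrom,
                    "start": max(0, tss - config.promoter_halfwidth),
                    "end": tss + config.promoter_halfwidth,
                    # X-linked promoters form the dedicated X-archetype
                    # cluster (k); autosomal promoters cycle over 1..k-1
                    "category": "promoter",
                    "cluster": k if is_x else next(promoter_cluster_cycle),
                    "gene_id": gene.id,
                }
            )
            # one intragenic cluster region per sufficiently long gene,
            # well away from the promoter
            # keep intragenic regions > 1 kb clear of either strand's TSS
            body_lo = start + span_len // 2
            body_hi = start + span_len - 1500
            if body_hi - body_lo > config.region_width[1]:
                w = int(rng.integers(*config.region_width))
                s = int(rng.integers(body_lo, body_hi - w))
                cluster_rows.append(
                    {
                        "chrom": chrom,
                        "start": s,
                        "end": s + w,
                        "category": "intragenic",
                        "cluster": int(rng.integers(1, k + 1)),
                        "gene_id": gene.id,
                    }
                )
                dense_regions[chrom].append((s, s + w, config.region_density))

        # intergenic cluster regions between the gene region and elsewhere
        inter_zone = (
            gene_region_end + 2 * config.promoter_halfwidth,
            int(length * (config.gene_region_frac + 0.05)),
        )
        slot_w = (inter_zone[1] - inter_zone[0]) / max(
            config.intergenic_regions_per_chrom, 1)
        if slot_w < config.region_width[1] + 100:
            raise ValueError("intergenic zone too small for the requested "
                             "region count; enlarge chromosomes")
        for j in range(config.intergenic_regions_per_chrom):
            # one region per slot keeps planted intergenic regions disjoint
            w = int(rng.integers(*config.region_width))
            lo = int(inter_zone[0] + j * slot_w)
            s = int(rng.integers(lo, lo + int(slot_w) - w))
            cluster_rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": s + w,
                    "category": "intergenic",
                    "cluster": int(rng.integers(1, k + 1)),
                    "gene_id": None,
                }
            )
            dense_regions[chrom].append((s, s + w, config.region_density))

        # candidate PMD blocks tile the desert
        desert_start = int(length * (config.gene_region_frac + 0.08))
        b = desert_start
        while b + config.pmd_block_size <= length:
            pmd_blocks.append(GenomicInterval(chrom, b, b + config.pmd_block_size))
            b += config.pmd_block_size

    # fragile-site-like blocks: half placed on PMD candidates, half in gene
    # regions
    n_half = config.n_fragile_blocks // 2
    pick = rng.choice(len(pmd_blocks), size=min(n_half, len(pmd_blocks)),
                      replace=False)
    for i in sorted(pick):
        blk = pmd_blocks[int(i)]
        fragile.append(GenomicInterval(blk.chrom, blk.start, blk.end))
    for i in range(config.n_fragile_blocks - len(fragile)):
        chrom, length = config.chromosomes[i % n_chrom]
        start = int(rng.integers(0, int(length * 0.4)))
        fragile.append(GenomicInterval(chrom, start, start + 200_000))

    # CpG positions: background Poisson-like process + dense peaks
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom, length in config.chromosomes:
        parts = [_sample_positions(rng, 0, length, config.background_density)]
        for s, e, dens in dense_regions[chrom]:
            parts.append(_sample_positions(rng, s, min(e, length),
                                           max(dens - config.background_density, 0)))
        cpg_positions[chrom] = np.unique(np.concatenate(parts))

    cluster_regions = pd.DataFrame(cluster_rows)

    feature_sets = _make_feature_sets(rng, genes, cgi_list, cluster_regions, config)
    state_segments = _make_state_segments(rng, genes, cluster_regions, pmd_blocks,
                                          config)

    # pick the XIST stand-in: first X-linked gene
    x_genes = [g for g in genes if g.is_x_linked]
    if not x_genes:
        xist_id = ""
    else:
        xist_id = x_genes[0].id

    return GenomeAnnotation(
        chromosomes=config.chromosomes,
        cpg_positions=cpg_positions,
        cgis=IntervalSet(cgi_list).merge(),
        genes=genes,
        feature_sets=feature_sets,
        state_segments=state_segments,
        fragile_blocks=IntervalSet(fragile).merge(),
        pmd_candidate_blocks=IntervalSet(pmd_blocks).merge(),
        cluster_regions=cluster_regions,
        x_chrom=config.x_chrom,
        xist_gene_id=xist_id,
        config=config,
    )


def _cluster_assignment_cycle(k: int):
    """Autosomal promoter cluster ids 1..k-1, cluster 1 over-represented (the
    universally hypomethylated housekeeping-like cluster is the largest)."""
    order = [1, 1, 1] + list(range(2, k))
    i = 0
    while True:
        yield order[i % len(order)]
        i += 1


def _make_feature_sets(rng, genes, cgi_list, cluster_regions, config):
    """Eight regulatory feature tracks.

    Promoter regions accumulate many features (TSS, CGI, TFBS, DNase, PolII)
    so promoter-archetype HMRs score 'High' regulatory potential; intergenic
    regions get enhancer-leaning subsets.
    """
    promoters = [g.promoter(200) for g in genes]
    sets: dict[str, list[GenomicInterval]] = {name: [] for name in FEATURE_NAMES}
    sets["fantom5_tss"] = promoters
    sets["cgi"] = list(cgi_list)
    for g in genes:
        p = g.promoter(500)
        for name, prob in [("encode_tfbs", 0.9), ("dnase_hs", 0.9),
                           ("polii", 0.8), ("mnase_hs", 0.6), ("hpaii_hs", 0.6)]:
            if rng.random() < prob:
                sets[name].append(p)
    for row in cluster_regions.itertuples(index=False):
        if row.category == "intergenic":
            iv = GenomicInterval(row.chrom, row.start, row.end)
            for name, prob in [("fantom5_enhancer", 0.8), ("dnase_hs", 0.5),
                               ("encode_tfbs", 0.4), ("hpaii_hs", 0.3)]:
                if rng.random() < prob:
                    sets[name].append(iv)
        elif row.category == "intragenic":
            iv = GenomicInterval(row.chrom, row.start, row.end)
            for name, prob in [("fantom5_enhancer", 0.5), ("mnase_hs", 0.4)]:
                if rng.random() < prob:
                    sets[name].append(iv)
    return {name: IntervalSet(ivs).merge() for name, ivs in sets.items()}


def _make_state_segments(rng, genes, cluster_regions, pmd_blocks, config):
    """Chromatin-state segments for two cell-type archetypes."""
    out: dict[str, dict[str, IntervalSet]] = {}
    for cell, enh_prob in [("hmec_like", 0.7), ("mcf7_like", 0.4)]:
        promoter = [g.promoter(800) for g in genes]
        enhancer = []
        hetero = [GenomicInterval(b.chrom, b.start, b.end) for b in pmd_blocks]
        for row in cluster_regions.itertuples(index=False):
            if row.category != "promoter" and rng.random() < enh_prob:
                enhancer.append(GenomicInterval(row.chrom, row.start, row.end))
        out[cell] = {
            "promoter": IntervalSet(promoter).merge(),
            "enhancer": IntervalSet(enhancer).merge(),
            "heterochromatin": IntervalSet(hetero).merge(),
        }
    return out
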