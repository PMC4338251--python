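"""End-to-end pipeline orchestration behind a single YAML config.

Stages run in dependency order: simulate -> segmentation -> atlas ->
(dynamics, regulatory, integration, xci).  Every stage writes its outputs
under the configured output directory plus a manifest entry (parameter hash,
input file hashes, package version, derived seed).  A completed stage whose
parameters and inputs are unchanged is skipped on rerun unless ``force``.
All randomness flows from the single global seed through per-stage derived
seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import build_atlas
from .dynamics import annotate_cgi, match_widths
from .genome import GenomeConfig, generate_genome
from .integration import promoter_methylation_matrix, simple_de_test, \
    stratify_dm_by_expression
from .intervals import GenomicInterval, IntervalSet
from .io import read_bed, read_methylome, write_bed, write_matrix, \
    write_methylome
from .regulatory import score_hmrs, state_enrichment
from .segmentation import call_hmrs, call_pmds, genome_fraction, \
    hmrs_to_intervals, pmds_to_intervals
from .simulate import CohortSpec, LinkSpec, default_archetypes, \
    generate_expression, generate_methylome, generate_paired_cohort
from .xci import call_escapee_like, classify_xci_status, x_promoter_deltas, \
    xist_group_test

__all__ = ["load_config", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

STAGES = ["simulate", "segmentation", "atlas", "dynamics", "regulatory",
          "integration", "xci"]


class PipelineError(RuntimeError):
    pass


DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "methatlas_out",
    "samples": ["NB", "BT089", "BT126", "BT198", "HMEC", "MCF7", "HCC1954"],
    "stages": {s: True for s in STAGES},
    "genome": {},
    "segmentation": {},
    "atlas": {"k": 8},
    "integration": {"slope": 4.0, "linked_clusters": [3, 6, 8]},
    "cohort": {},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1_000_003 + STAGES.index(stage) + 1) % (2**31)


def _hash_params(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def fresh(self, stage: str, params_hash: str, inputs: list[Path]) -> bool:
        entry = self.data.get(stage)
        if entry is None or entry["params"] != params_hash:
            return False
        for f, h in entry["inputs"].items():
            p = Path(f)
            if not p.exists() or _hash_file(p) != h:
                return False
        return all(Path(o).exists() for o in entry["outputs"])

    def record(self, stage: str, params_hash: str, inputs: list[Path],
               outputs: list[Path], seed: int) -> None:
        self.data[stage] = {
            "params": params_hash,
            "inputs": {str(f): _hash_file(f) for f in inputs},
            "outputs": [str(o) for o in outputs],
            "seed": seed,
            "version": __version__,
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _build_genome(cfg: dict):
    gconf = GenomeConfig()
    g = dict(cfg.get("genome") or {})
    if "chromosomes" in g:
        gconf.chromosomes = [(str(c), int(l)) for c, l in g.pop("chromosomes")]
    for key, val in g.items():
        if not hasattr(gconf, key):
            raise PipelineError(f"unknown genome option {key!r}")
        setattr(gconf, key, val)
    return generate_genome(gconf, seed=_stage_seed(cfg["seed"], "simulate"))


def run_pipeline(config, force: bool = False) -> dict:
    """Run all enabled stages; returns a report dict (per-stage status)."""
    cfg = load_config(config) if not isinstance(config, dict) else {
        **json.loads(json.dumps(DEFAULT_CONFIG)), **config}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    report: dict[str, str] = {}
    samples = cfg["samples"]

    # The genome annotation is deterministic from config+seed and cheap, so
    # it is rebuilt in memory rather than serialized between stages.
    genome = _build_genome(cfg)

    track_paths = {s: outdir / "tracks" / f"{s}.meth.tsv" for s in samples}
    hmr_paths = {s: outdir / "hmr" / f"{s}.hmr.bed" for s in samples}
    pmd_paths = {s: outdir / "pmd" / f"{s}.pmd.bed" for s in samples}
    atlas_path = outdir / "atlas" / "reference_hmrs.tsv"

    def enabled(stage):
        return cfg["stages"].get(stage, True)

    def run_stage(stage, params, inputs, outputs, fn):
        if not enabled(stage):
            report[stage] = "disabled"
            return
        missing = [str(p) for p in inputs if not Path(p).exists()]
        if missing:
            raise PipelineError(
                f"stage {stage!r}: missing upstream output(s) {missing}; "
                f"run the producing stage first")
        ph = _hash_params(params)
        if not force and manifest.fresh(stage, ph, inputs):
            report[stage] = "skipped (up to date)"
            return
        for o in outputs:
            Path(o).parent.mkdir(parents=True, exist_ok=True)
        fn()
        manifest.record(stage, ph, inputs, outputs, _stage_seed(cfg["seed"],
                                                                stage))
        report[stage] = "ran"

    # -- simulate -------------------------------------------------------
    def do_simulate():
        seed = _stage_seed(cfg["seed"], "simulate")
        arch = default_archetypes(genome, seed=seed)
        for i, s in enumerate(samples):
            track, truth = generate_methylome(genome, arch[s], seed=seed + i + 1)
            write_methylome(track, track_paths[s])
            write_bed(truth["hmr"], outdir / "truth" / f"{s}.hmr.bed")
            write_bed(truth["pmd"], outdir / "truth" / f"{s}.pmd.bed")
        write_bed(genome.cgis, outdir / "truth" / "cgi.bed")

    sim_outputs = list(track_paths.values()) + [
        outdir / "truth" / f"{s}.{kind}.bed"
        for s in samples for kind in ("hmr", "pmd")] + [
        outdir / "truth" / "cgi.bed"]
    run_stage("simulate", {"cfg": cfg["genome"], "samples": samples,
                           "seed": cfg["seed"]}, [], sim_outputs, do_simulate)

    # -- segmentation ---------------------------------------------------
    def do_segmentation():
        params = cfg.get("segmentation") or {}
        rows = []
        for s in samples:
            track = read_methylome(track_paths[s], sample_id=s)
            hmrs = call_hmrs(track, **{k: v for k, v in params.items()
                                       if k in ("max_cpg_gap", "min_cpg")})
            pmds = call_pmds(track, **{k: v for k, v in params.items()
                                       if k in ("bin_size", "max_cpg_gap",
                                                "min_domain")})
            write_bed(hmrs_to_intervals(hmrs), hmr_paths[s])
            write_bed(pmds_to_intervals(pmds), pmd_paths[s])
            pmd_set = pmds_to_intervals(pmds).merge()
            rows.append({
                "sample": s, "n_hmr": len(hmrs), "n_pmd": len(pmds),
                "pmd_fraction": genome_fraction(pmd_set, genome.chrom_lengths),
            })
        pd.DataFrame(rows).to_csv(outdir / "segmentation_summary.tsv",
                                  sep="\t", index=False)

    run_stage("segmentation", cfg.get("segmentation") or {},
              list(track_paths.values()),
              list(hmr_paths.values()) + list(pmd_paths.values())
              + [outdir / "segmentation_summary.tsv"], do_segmentation)

    # -- atlas ----------------------------------------------------------
    def do_atlas():
        tracks = [read_methylome(track_paths[s], sample_id=s) for s in samples]
        hmr_sets = [read_bed(hmr_paths[s]) for s in samples]
        ref = build_atlas(hmr_sets, tracks, genome.genes,
                          k=int(cfg["atlas"].get("k", 8)),
                          seed=_stage_seed(cfg["seed"], "atlas"))
        ref.to_frame().to_csv(atlas_path, sep="\t", index=False)

    run_stage("atlas", cfg["atlas"],
              list(track_paths.values()) + list(hmr_paths.values()),
              [atlas_path], do_atlas)

    # -- dynamics -------------------------------------------------------
    def do_dynamics():
        nb = samples[0]
        nb_hmrs = read_bed(hmr_paths[nb])
        for s in samples[1:]:
            changes = annotate_cgi(
                match_widths(nb_hmrs, read_bed(hmr_paths[s])), genome.cgis)
            pd.DataFrame([{
                "chrom": c.nb_hmr.chrom, "start": c.nb_hmr.start,
                "end": c.nb_hmr.end, "matched_width": c.matched_width,
                "log2_fc": c.log2_fc, "category": c.category,
                "has_cgi": c.has_cgi,
            } for c in changes]).to_csv(
                outdir / "dynamics" / f"{nb}_vs_{s}.tsv", sep="\t",
                index=False)

    run_stage("dynamics", {}, list(hmr_paths.values()),
              [outdir / "dynamics" / f"{samples[0]}_vs_{s}.tsv"
               for s in samples[1:]], do_dynamics)

    # -- regulatory -----------------------------------------------------
    def do_regulatory():
        atlas_df = pd.read_csv(atlas_path, sep="\t")
        hmrs = IntervalSet([
            GenomicInterval(r.chrom, r.start, r.end, name=f"ref_{i}")
            for i, r in enumerate(atlas_df.itertuples(index=False))])
        scores = score_hmrs(hmrs, genome.feature_sets)
        atlas_df["overlap_count"] = [s.overlap_count for s in scores]
        atlas_df["potential"] = [s.potential for s in scores]
        atlas_df.to_csv(outdir / "regulatory" / "potential.tsv", sep="\t",
                        index=False)
        rows = []
        for cell, states in genome.state_segments.items():
            flags = {name: ivs.overlap_any(hmrs)
                     for name, ivs in states.items()}
            labels = (atlas_df["location"].astype(str) + "-"
                      + atlas_df["cluster"].astype(str))
            for r in state_enrichment(labels.to_numpy(), flags):
                rows.append({"cell": cell, "cluster": r.cluster_id,
                             "state": r.state_name, "odds_ratio": r.odds_ratio,
                             "p": r.p_value, "p_adj": r.adjusted_p,
                             "testable": r.testable})
        pd.DataFrame(rows).to_csv(outdir / "regulatory" / "enrichment.tsv",
                                  sep="\t", index=False)

    run_stage("regulatory", {}, [atlas_path],
              [outdir / "regulatory" / "potential.tsv",
               outdir / "regulatory" / "enrichment.tsv"], do_regulatory)

    # -- integration ----------------------------------------------------
    def do_integration():
        seed = _stage_seed(cfg["seed"], "integration")
        tracks = [read_methylome(track_paths[s], sample_id=s) for s in samples]
        pm = promoter_methylation_matrix(tracks, genome.genes)
        link = LinkSpec(
            linked_clusters=frozenset(cfg["integration"]["linked_clusters"]),
            slope=float(cfg["integration"]["slope"]))
        table, _linked = generate_expression(genome, pm, link, seed=seed)
        normals = [s for s in samples if s in ("NB", "HMEC")]
        tumors = [s for s in samples if s in ("MCF7", "HCC1954")]
        if len(normals) < 2 or len(tumors) < 2:
            half = len(samples) // 2
            normals, tumors = samples[:half], samples[half:]
        groups = {s: "a" for s in normals} | {s: "b" for s in tumors}
        de = simple_de_test(table, groups)
        dm = pm[tumors].mean(axis=1) - pm[normals].mean(axis=1)
        strat = stratify_dm_by_expression(dm, de.de_label)
        write_matrix(pm, outdir / "integration" / "promoter_methylation.tsv")
        out = pd.DataFrame({"delta": dm, "de_label": de.de_label,
                            "fdr": de.fdr})
        out.to_csv(outdir / "integration" / "dm_vs_expression.tsv", sep="\t")
        summary = pd.DataFrame([{
            "median_delta_under": strat.medians["under"],
            "median_delta_over": strat.medians["over"],
            "median_gap": strat.median_gap,
            "under_vs_over_p": strat.under_vs_over_p,
        }])
        summary.to_csv(outdir / "integration" / "stratification.tsv",
                       sep="\t", index=False)

    run_stage("integration", cfg["integration"], list(track_paths.values()),
              [outdir / "integration" / "promoter_methylation.tsv",
               outdir / "integration" / "dm_vs_expression.tsv",
               outdir / "integration" / "stratification.tsv"], do_integration)

    # -- xci ------------------------------------------------------------
    def do_xci():
        seed = _stage_seed(cfg["seed"], "xci")
        spec = CohortSpec(**(cfg.get("cohort") or {}), seed=seed)
        cohort, truth = generate_paired_cohort(genome, spec)
        deltas, excluded = x_promoter_deltas(cohort)
        calls = classify_xci_status(deltas)
        t, p = xist_group_test(cohort, calls)
        escapees = call_escapee_like(cohort, calls)
        pd.DataFrame([{
            "patient": c.patient, "mean_x_delta": c.mean_x_delta,
            "status": c.status} for c in calls]).to_csv(
            outdir / "xci" / "calls.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "gene": e.gene, "delta_meth": e.group_delta_meth,
            "meth_p": e.meth_p, "log2fc_expr": e.group_logfc_expr,
            "expr_p": e.expression_p, "called": e.called}
            for e in escapees]).to_csv(
            outdir / "xci" / "escapee_like.tsv", sep="\t", index=False)
        json_path = outdir / "xci" / "summary.json"
        json_path.write_text(json.dumps({
            "n_dysregulated": sum(c.status == "xci_dysregulated"
                                  for c in calls),
            "n_excluded_patients": len(excluded),
            "xist_t": t, "xist_p": p,
            "n_escapee_like": sum(e.called for e in escapees),
        }, indent=2))

    run_stage("xci", cfg.get("cohort") or {}, [],
              [outdir / "xci" / "calls.tsv",
               outdir / "xci" / "escapee_like.tsv",
               outdir / "xci" / "summary.json"], do_xci)

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
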