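"""End-to-end orchestration: config, stage wiring, report bundle, manifest.

A run is a pure function of its input files and thresholds: the manifest
records every threshold, the seed, a SHA-256 checksum of every input and
per-stage record counts, so reruns are byte-comparable.  Stage order follows
the analysis: archaic-call filtering -> allele profiles -> ancestral
inference -> five-category classification -> frequencies -> LD ->
association scoring -> annotation binning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from oxvar import annotation, association_scoring, popgen_stats
from oxvar.ancestral_inference import ancestral_calls_frame, infer_panel_ancestral
from oxvar.archaic_filter import (archaic_calls_from_frame, concordance_filter,
                                  filter_by_mq, flag_outlier_genomes)
from oxvar.io_formats import read_genotypes_vcf, read_newick
from oxvar.ld_analysis import detect_blocks, ld_matrix, ld_pairs_frame
from oxvar.pattern_classifier import classify_panel
from oxvar.site_profiles import AH, panel_from_frame


@dataclass
class RunConfig:
    """Input paths and thresholds for one pipeline run."""

    panel: str
    tree: str
    outdir: str
    archaic_calls: str | None = None
    haplotypes: str | None = None
    associations: str | None = None
    scores: str | None = None
    selection: str | None = None
    genotypes: str | None = None
    mq_threshold: float = 25.0
    min_genomes: int = 2
    r2_threshold: float = 0.8
    alpha: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mq_threshold < 0 or self.min_genomes < 1:
            raise ValueError("invalid archaic-filter thresholds")
        if not 0 <= self.r2_threshold <= 1 or not 0 < self.alpha <= 1:
            raise ValueError("invalid r2/alpha thresholds")
        for name in ("panel", "tree", "archaic_calls", "haplotypes",
                     "associations", "scores", "selection", "genotypes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw.get("inputs", {})
        thresholds = raw.get("thresholds", {})
        known = {"mq_threshold", "min_genomes", "r2_threshold", "alpha"}
        return cls(
            panel=inputs["panel"], tree=inputs["tree"],
            outdir=raw.get("outdir", "oxvar_out"),
            archaic_calls=inputs.get("archaic_calls"),
            haplotypes=inputs.get("haplotypes"),
            associations=inputs.get("associations"),
            scores=inputs.get("scores"),
            selection=inputs.get("selection"),
            genotypes=inputs.get("genotypes"),
            seed=int(raw.get("seed", 0)),
            extra={k: v for k, v in thresholds.items() if k not in known},
            **{k: v for k, v in thresholds.items() if k in known},
        )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {"mq": config.mq_threshold, "min_genomes": config.min_genomes,
                       "r2": config.r2_threshold, "alpha": config.alpha,
                       **config.extra},
        "inputs": {}, "stages": {},
    }
    for name in ("panel", "tree", "archaic_calls", "haplotypes", "associations",
                 "scores", "selection", "genotypes"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    panel = panel_from_frame(pd.read_csv(config.panel, sep="\t"))
    manifest["stages"]["panel"] = {"sites_in": len(panel)}
    tree = read_newick(config.tree)

    if config.archaic_calls:
        calls = archaic_calls_from_frame(pd.read_csv(config.archaic_calls, sep="\t"))
        n_raw = len(calls.genomes)
        calls = filter_by_mq(calls, config.mq_threshold)
        excluded, rates = flag_outlier_genomes(calls)
        calls = calls.drop_genomes(excluded)
        ah_sets = concordance_filter(calls, config.min_genomes)
        from dataclasses import replace
        rebuilt = []
        for prof in panel:
            ah = ah_sets.get(prof.site_id)
            alleles = {t: s for t, s in prof.alleles.items() if t != AH}
            missing = set(prof.missing) - {AH}
            if ah:
                alleles[AH] = ah
            else:
                missing.add(AH)
            rebuilt.append(replace(prof, alleles=alleles, missing=frozenset(missing)))
        panel = rebuilt
        manifest["stages"]["archaic_filter"] = {
            "genomes_in": n_raw, "genomes_excluded": excluded,
            "discordance_rates": rates, "sites_with_ah": len(ah_sets),
        }

    ancestral = infer_panel_ancestral(tree, panel)
    ancestral_calls_frame(ancestral).to_csv(outdir / "ancestral.tsv", sep="\t", index=False)
    manifest["stages"]["ancestral"] = {
        "resolved": sum(c.resolved for c in ancestral.values()),
        "unresolved": sum(not c.resolved for c in ancestral.values()),
    }

    result = classify_panel(panel, ancestral)
    result.frame().to_csv(outdir / "classification.tsv", sep="\t", index=False)
    result.allele_counts().to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    result.site_counts().to_csv(outdir / "site_counts.tsv", sep="\t", index=False)
    manifest["stages"]["classification"] = {
        "sites": len(result.sites),
        "site_counts": {f"{g}:{p}": int(c) for g, p, c in
                        result.site_counts().itertuples(index=False)},
    }

    if config.genotypes:
        vcf = read_genotypes_vcf(config.genotypes)
        summaries = []
        for sid in vcf.genotypes.sites:
            call = ancestral.get(sid)
            anc = call.allele if call is not None else None
            s = popgen_stats.site_frequency_summary(vcf.genotypes, sid, anc)
            summaries.append({
                "site_id": sid, "major_allele": s.major_allele, "maf": s.maf,
                "derived_allele": s.derived_allele or ".", "derived_freq": s.derived_freq,
                "top_population": s.top_population, "top_population_maf": s.top_population_maf,
            })
        pd.DataFrame(summaries).to_csv(outdir / "frequency_summary.tsv",
                                       sep="\t", index=False)
        manifest["stages"]["frequencies"] = {"sites": len(summaries)}

    if config.haplotypes:
        vcf = read_genotypes_vcf(config.haplotypes)
        if vcf.haplotypes is None:
            raise ValueError("haplotype input has no phased samples")
        ld = ld_matrix(vcf.haplotypes)
        ld_pairs_frame(ld).to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
        blocks = detect_blocks(ld, config.r2_threshold)
        pd.DataFrame(
            [{"block": i + 1, "site_id": sid} for i, b in enumerate(blocks) for sid in b]
        ).to_csv(outdir / "ld_blocks.tsv", sep="\t", index=False)
        manifest["stages"]["ld"] = {"sites": vcf.haplotypes.n_sites,
                                    "n_blocks": len(blocks),
                                    "blocks": [list(b) for b in blocks]}

    if config.associations:
        records = pd.read_csv(config.associations, sep="\t")
        per_snp = association_scoring.per_snp_percentages(records)
        per_snp.to_csv(outdir / "association_per_snp.tsv", sep="\t", index=False)
        means = association_scoring.gene_level_means(per_snp)
        means.to_csv(outdir / "association_gene_means.tsv", sep="\t", index=False)
        tests = association_scoring.all_gene_comparisons(records)
        tests.to_csv(outdir / "association_tests.tsv", sep="\t", index=False)
        manifest["stages"]["association"] = {"snps": len(per_snp), "tests": len(tests)}

    if config.scores:
        scores = pd.read_csv(config.scores, sep="\t")
        binned = annotation.bin_score_table(scores)
        binned.to_csv(outdir / "pathogenicity_bins.tsv", sep="\t", index=False)
        manifest["stages"]["annotation"] = {"scored_sites": len(binned)}

    if config.selection:
        sel = pd.read_csv(config.selection, sep="\t")
        sig = annotation.filter_selection_results(sel, config.alpha)
        sig.to_csv(outdir / "selection_significant.tsv", sep="\t", index=False)
        manifest["stages"]["selection"] = {"records_in": len(sel), "significant": len(sig)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_demo_data(outdir, seed: int = 0) -> dict[str, str]:
    """Write a complete synthetic input bundle exercising every stage.

    Returns the paths written, including a ready-to-run ``config.yaml``.
    """
    from oxvar.archaic_filter import archaic_calls_frame
    from oxvar.datasets import SPECIES_TREE_NEWICK
    from oxvar.io_formats import write_phased_vcf
    from oxvar.site_profiles import panel_to_frame
    from oxvar.synthetic_data import (BlockSpec, PanelConfig, simulate_archaic_calls,
                                      simulate_association_table, simulate_haplotypes,
                                      simulate_site_panel)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    panel, truth = simulate_site_panel(PanelConfig(seed=seed))
    paths["panel"] = str(outdir / "panel.tsv")
    panel_to_frame(panel).to_csv(paths["panel"], sep="\t", index=False)
    pd.DataFrame(
        [{"site_id": sid, "true_class": cls, "true_ancestral": truth.ancestral[sid]}
         for sid, cls in truth.site_class.items()]
    ).to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)

    paths["tree"] = str(outdir / "tree.nwk")
    Path(paths["tree"]).write_text(SPECIES_TREE_NEWICK + "\n")

    sim = simulate_archaic_calls(panel, error_rate=0.02, mq_mean=37.0, seed=seed + 1)
    paths["archaic_calls"] = str(outdir / "archaic_calls.tsv")
    archaic_calls_frame(sim.calls).to_csv(paths["archaic_calls"], sep="\t", index=False)

    sites = [p.site_id for p in panel]
    groups = [sites[0:3], sites[4:6]] if len(sites) >= 6 else [sites[:2]]
    hap = simulate_haplotypes(BlockSpec(groups, 0.9, 0.2, 200), seed + 2, site_ids=sites)
    paths["haplotypes"] = str(outdir / "haplotypes.vcf")
    write_phased_vcf(paths["haplotypes"], hap)

    assoc = simulate_association_table(
        {"SYNGENE": (0.5, 0.3, 0.2), "SYNGENE2": (0.2, 0.3, 0.5)},
        n_snps=8, studies_per_snp=6, seed=seed + 3)
    paths["associations"] = str(outdir / "associations.tsv")
    assoc.to_csv(paths["associations"], sep="\t", index=False)

    rng = __import__("numpy").random.default_rng(seed + 4)
    scores = pd.DataFrame(
        [{"site_id": sid, "tool": "CADD", "value": float(rng.uniform(0, 30))}
         for sid in sites[:10]]
        + [{"site_id": sid, "tool": "GERP", "value": float(rng.uniform(-3, 3))}
           for sid in sites[:10]])
    paths["scores"] = str(outdir / "scores.tsv")
    scores.to_csv(paths["scores"], sep="\t", index=False)

    sel = pd.DataFrame(
        [{"site_id": sid, "test": "FDIST", "statistic_kind": "p",
          "value": float(rng.uniform(0, 1))} for sid in sites[:10]])
    paths["selection"] = str(outdir / "selection.tsv")
    sel.to_csv(paths["selection"], sep="\t", index=False)

    config = {
        "inputs": {k: str(Path(v)) for k, v in paths.items()},
        "thresholds": {"mq_threshold": 25, "min_genomes": 2,
                       "r2_threshold": 0.8, "alpha": 0.05},
        "seed": seed,
        "outdir": str(outdir / "results"),
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=True))
    paths["config"] = str(cfg_path)
    return paths
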