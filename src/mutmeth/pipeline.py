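"""Configuration-driven end-to-end run over one cohort.

Stages execute in dependency order: probe filtering -> aberrant calling
-> {PC association, HyperZ/HypoZ indices, site scan} -> subtyping ->
integration.  Every output TSV lands under the configured directory and
the run manifest (JSON) records stage outputs, counts, warnings, the
seed and a hash of the configuration, so identical inputs + config +
seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import data_model as dm
from .genome_indices import associate_genes_with_index, compute_hyperz_hypoz
from .integration import (
    call_group_aberrant_probes,
    classify_group_specific_genes,
    correlate_methylation_expression,
    map_probes_to_genes,
)
from .pca_assoc import associate_genes_with_pcs, fit_methylation_pca
from .preprocess import call_aberrant_probes, filter_probes
from .site_assoc import (
    associate_genes_with_probes,
    estimate_empirical_fdr,
    summarize_dominance,
)
from .subtyping import cluster_samples, select_top_associated_probes


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one cohort run."""

    beta_path: str = ""
    groups_path: str = ""
    mutations_path: str = ""
    annotation_path: str = ""
    expression_path: str = ""
    out_dir: str = "results"
    # thresholds (defaults are the analysis' fixed constants)
    alpha: float = 0.05
    min_mutated: int = 5
    missing_threshold: float = 0.9
    n_pcs: int = 5
    z_cut: float = 2.0
    k_top_probes: int = 500
    n_clusters: int = 2
    tss_window: int = 1500
    min_beta_diff: float = 0.0
    min_expr_diff: float = 0.0
    n_permutations: int = 10
    seed: int = 0
    stages: tuple[str, ...] = ("filter", "diffmeth", "pca", "indices",
                               "site", "subtype", "integrate")
    subtype_genes: tuple[str, ...] = ()
    integration_groups: dict[str, str] = field(default_factory=dict)
    # gene -> group label; groups are defined by mutation status

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise dm.ValidationError(f"alpha={self.alpha} outside (0, 1]")
        if not 0 < self.missing_threshold <= 1:
            raise dm.ValidationError("missing_threshold outside (0, 1]")
        if self.min_mutated < 1 or self.n_pcs < 1 or self.n_permutations < 1:
            raise dm.ValidationError("counts must be positive")
        for name in ("beta_path", "groups_path", "mutations_path",
                     "annotation_path"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise dm.ValidationError(f"{name} does not exist: {path}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed,
                      "stages": {}, "warnings": []}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, out, manifest)
        manifest["warnings"] = [str(w.message) for w in caught]

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    beta = dm.load_beta_matrix(config.beta_path, config.groups_path)
    mut = dm.load_mutations(config.mutations_path)
    ann = dm.load_probe_annotation(config.annotation_path)
    expr = dm.load_expression(config.expression_path) \
        if config.expression_path else None

    stage_set = set(config.stages)

    if "filter" in stage_set:
        beta, report = filter_probes(beta, ann, config.missing_threshold)
        path = out / "probe_filter_report.tsv"
        pd.DataFrame(
            [(r, p) for r, ps in report.removed.items() for p in ps],
            columns=["reason", "probe"]).to_csv(path, sep="\t", index=False)
        manifest["stages"]["filter"] = {
            "kept": len(report.kept), "removed": report.n_removed,
            "output": str(path)}

    aberrant = None
    if "diffmeth" in stage_set:
        aberrant = call_aberrant_probes(beta, config.alpha)
        path = out / "aberrant_calls.tsv"
        aberrant.table.to_csv(path, sep="\t")
        manifest["stages"]["diffmeth"] = {
            "callable": aberrant.callable_,
            "n_hyper": len(aberrant.probes_called("hyper")),
            "n_hypo": len(aberrant.probes_called("hypo")),
            "output": str(path)}

    if "pca" in stage_set:
        pca = fit_methylation_pca(beta, n_components=config.n_pcs)
        assoc = associate_genes_with_pcs(pca, mut, config.min_mutated,
                                         config.alpha)
        spath = out / "pca_scores.tsv"
        apath = out / "pc_associations.tsv"
        pca.scores.to_csv(spath, sep="\t")
        assoc.records.to_csv(apath, sep="\t", index=False)
        manifest["stages"]["pca"] = {
            "n_tests": len(assoc), "n_significant": len(assoc.significant()),
            "explained_variance": [float(v) for v in pca.explained_variance],
            "scores": str(spath), "associations": str(apath)}

    if "indices" in stage_set:
        idx = compute_hyperz_hypoz(beta, ann, z_cut=config.z_cut)
        ipath = out / "hyperz_hypoz.tsv"
        idx.table.to_csv(ipath, sep="\t")
        stage = {"computable": idx.computable, "output": str(ipath)}
        if idx.computable:
            for which in ("hyperz", "hypoz"):
                a = associate_genes_with_index(idx, mut, which,
                                               config.min_mutated,
                                               config.alpha)
                p = out / f"{which}_associations.tsv"
                a.records.to_csv(p, sep="\t", index=False)
                stage[f"{which}_significant"] = len(a.significant())
        manifest["stages"]["indices"] = stage

    site = None
    if "site" in stage_set:
        site = associate_genes_with_probes(beta, mut, ann,
                                           config.min_mutated, config.alpha)
        tpath = out / "site_associations.tsv"
        site.significant().to_csv(tpath, sep="\t", index=False)
        fdr = estimate_empirical_fdr(beta, mut, config.alpha,
                                     config.n_permutations, config.seed,
                                     config.min_mutated)
        dom = summarize_dominance(site, aberrant)
        dpath = out / "dominance.tsv"
        dom.per_gene.to_csv(dpath, sep="\t")
        manifest["stages"]["site"] = {
            "n_tests": len(site.records),
            "n_significant": site.n_discoveries(),
            "empirical_fdr": fdr.empirical_fdr,
            "mean_null_discoveries": fdr.mean_null_discoveries,
            "associations": str(tpath), "dominance": str(dpath)}

    if "subtype" in stage_set and site is not None:
        genes = list(config.subtype_genes)
        if not genes:
            dom = summarize_dominance(site, aberrant)
            if not dom.per_gene.empty:
                genes = list(dom.per_gene.sort_values(
                    "n_assoc", ascending=False).index[:3])
        if genes:
            panel = select_top_associated_probes(site, genes,
                                                 config.k_top_probes)
            assign = cluster_samples(beta, panel, config.n_clusters)
            cpath = out / "subtypes.tsv"
            assign.labels.rename("cluster").to_csv(cpath, sep="\t",
                                                   index_label="sample_id")
            manifest["stages"]["subtype"] = {
                "genes": genes, "panel_size": len(panel),
                "output": str(cpath)}
        else:
            manifest["stages"]["subtype"] = {"skipped": "no associated genes"}

    if "integrate" in stage_set and expr is not None \
            and config.integration_groups:
        groups: dict[str, list[str]] = {}
        for gene, label in config.integration_groups.items():
            groups.setdefault(label, [])
            groups[label].extend(mut.mutated_samples(gene))
        groups = {k: sorted(set(v)) for k, v in groups.items()}
        links = map_probes_to_genes(ann, tss_window=config.tss_window)
        linked = correlate_methylation_expression(beta, expr, links,
                                                  config.alpha)
        aberr = call_group_aberrant_probes(beta, groups, config.alpha,
                                           config.min_beta_diff)
        cats = classify_group_specific_genes(
            linked, aberr, expr, groups, beta.normal_samples,
            config.alpha, config.min_expr_diff)
        cpath = out / "expression_categories.tsv"
        cats.records.to_csv(cpath, sep="\t", index=False)
        manifest["stages"]["integrate"] = {
            "n_links_tested": len(linked.records),
            "n_links_significant": len(linked.significant()),
            "n_categorized": int((cats.records["category"] != "none").sum()),
            "output": str(cpath)}
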