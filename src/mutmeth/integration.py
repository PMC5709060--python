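"""Mutation -> methylation -> expression integration.

The four-step procedure: (1) link probes to genes (promoter = within a
TSS window, body = inside the gene span) and keep links whose
methylation correlates with the gene's expression across tumors
(Spearman, BH over all links); (2) call probes aberrantly hyper- or
hypomethylated per mutation group relative to normals; (3+4) classify
genes into direction-consistent group-specific expression categories —
up/down only in group A or only in group B, each backed by at least one
significant link whose methylation call and correlation sign agree with
the expression change.  Follow-ups: the highly-transcribed filter,
hypergeometric gene-set enrichment, and cross-cohort shared gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    BetaMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    ValidationError,
)
from .stats import (
    bh_qvalues,
    hypergeometric_enrichment,
    rank_sum_matrix,
    spearman_correlation,
)

CATEGORIES = ("up_in_A_only", "up_in_B_only", "down_in_A_only",
              "down_in_B_only", "none")


def map_probes_to_genes(ann: ProbeAnnotation,
                        gene_coords: pd.DataFrame | None = None,
                        tss_window: int = 1500) -> pd.DataFrame:
    """Probe -> (gene, region) links.

    With ``gene_coords`` (columns gene, chromosome, start, end, strand)
    the links are computed from coordinates: promoter when the probe
    lies within ``tss_window`` bp of the strand-resolved TSS (inclusive),
    body when inside the gene span but outside the promoter window.  A
    probe may link to several genes.  Without coordinates the
    annotation's own linked_gene/link_region columns are used.
    """
    if gene_coords is None:
        t = ann.table
        linked = t[(t["linked_gene"] != "") & (t["link_region"] != "none")]
        return pd.DataFrame({
            "probe": linked.index,
            "gene": linked["linked_gene"].to_numpy(),
            "region": linked["link_region"].to_numpy(),
        }).reset_index(drop=True)

    required = {"gene", "chromosome", "start", "end", "strand"}
    missing = required - set(gene_coords.columns)
    if missing:
        raise ValidationError(f"gene_coords missing columns: {sorted(missing)}")
    rows = []
    probes = ann.table
    for g in gene_coords.itertuples(index=False):
        if pd.isna(g.start) or pd.isna(g.end):
            warnings.warn(f"gene {g.gene} lacks coordinates; skipped",
                          stacklevel=2)
            continue
        tss = g.start if g.strand == "+" else g.end
        on_chrom = probes[probes["chromosome"] == g.chromosome]
        pos = on_chrom["position"]
        promoter = (pos - tss).abs() <= tss_window
        body = (pos >= min(g.start, g.end)) & (pos <= max(g.start, g.end)) \
            & ~promoter
        for probe in on_chrom.index[promoter]:
            rows.append((probe, g.gene, "promoter"))
        for probe in on_chrom.index[body]:
            rows.append((probe, g.gene, "body"))
    return pd.DataFrame(rows, columns=["probe", "gene", "region"])


@dataclass
class ProbeGeneLinkTable:
    """Spearman-tested probe-gene links; BH over all computed links."""

    records: pd.DataFrame  # probe, gene, region, rho, p, q
    alpha: float = 0.05

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.records[self.records["q"] < a]


def correlate_methylation_expression(beta: BetaMatrix, expr: ExpressionMatrix,
                                     links: pd.DataFrame, alpha: float = 0.05
                                     ) -> ProbeGeneLinkTable:
    """Spearman correlation of each link's probe beta and gene
    expression across shared tumors; links with < 3 complete pairs or a
    constant member are skipped, not errors."""
    tumors = [s for s in beta.tumor_samples if s in expr.values.columns]
    if len(tumors) < 3:
        raise ValidationError("need >= 3 shared tumor samples")
    rows = []
    for link in links.itertuples(index=False):
        if link.probe not in beta.values.index or \
                link.gene not in expr.values.index:
            continue
        b = beta.values.loc[link.probe, tumors].to_numpy()
        e = expr.values.loc[link.gene, tumors].to_numpy()
        try:
            rho, p = spearman_correlation(b, e)
        except ValueError:
            continue
        rows.append((link.probe, link.gene, link.region, rho, p))
    records = pd.DataFrame(rows, columns=["probe", "gene", "region", "rho", "p"])
    records["q"] = bh_qvalues(records["p"].to_numpy()) if len(records) else \
        pd.Series(dtype=float)
    return ProbeGeneLinkTable(records, alpha=alpha)


@dataclass
class GroupAberrantTable:
    """Per mutation group and probe: hyper/hypo/none call vs normals."""

    records: pd.DataFrame  # group, probe, p, q, median_diff, call
    alpha: float = 0.05
    min_abs_median_diff: float = 0.0

    def calls_for(self, group: str) -> pd.Series:
        sub = self.records[self.records["group"] == group]
        return pd.Series(sub["call"].to_numpy(), index=sub["probe"])


def call_group_aberrant_probes(beta: BetaMatrix,
                               groups: dict[str, list[str]],
                               alpha: float = 0.05,
                               min_abs_median_diff: float = 0.0
                               ) -> GroupAberrantTable:
    """Two-sided rank-sum of each group's tumors vs normals per probe,
    BH across probes within each group; hyper/hypo by the sign of the
    median beta difference, gated on ``|median_diff| >=
    min_abs_median_diff``."""
    normals = beta.normal_values().to_numpy()
    if normals.shape[1] == 0:
        raise ValidationError(
            "group aberrant calling is defined relative to normal samples")
    probes = np.array(beta.probe_ids)
    frames = []
    for group, samples in groups.items():
        samples = [s for s in samples if s in beta.values.columns]
        if not samples:
            raise ValidationError(f"group {group!r} has no samples in matrix")
        g = beta.values[samples].to_numpy()
        p, med_diff = rank_sum_matrix(g, normals)
        q = bh_qvalues(p)
        call = np.full(len(probes), "none", dtype=object)
        strong = np.abs(med_diff) >= min_abs_median_diff
        call[(q < alpha) & strong & (med_diff > 0)] = "hyper"
        call[(q < alpha) & strong & (med_diff < 0)] = "hypo"
        frames.append(pd.DataFrame({
            "group": group, "probe": probes, "p": p, "q": q,
            "median_diff": med_diff, "call": call,
        }))
    return GroupAberrantTable(pd.concat(frames, ignore_index=True),
                              alpha=alpha,
                              min_abs_median_diff=min_abs_median_diff)


@dataclass
class ExpressionCategoryTable:
    """Gene -> group-specific expression category with support."""

    records: pd.DataFrame  # gene, category, supporting_probes,
                           # median_A, median_B, median_normal,
                           # expr_diff, highly_transcribed
    group_a: str = "A"
    group_b: str = "B"

    def genes_in(self, category: str) -> list[str]:
        return list(self.records.loc[self.records["category"] == category,
                                     "gene"])


def _expression_calls(expr: ExpressionMatrix, groups: dict[str, list[str]],
                      normals: list[str], genes: list[str], alpha: float,
                      min_expr_diff: float,
                      second_reference: dict[str, list[str]] | None = None
                      ) -> pd.DataFrame:
    """Per (gene, group): up/down/none vs normals (and optionally vs a
    second reference group), BH over all gene x group tests."""
    nvals = expr.values.loc[genes, normals].to_numpy()
    rows = []
    for group, samples in groups.items():
        gvals = expr.values.loc[genes, samples].to_numpy()
        p, med_diff = rank_sum_matrix(gvals, nvals)
        rows.append(pd.DataFrame({
            "gene": genes, "group": group, "p": p, "median_diff": med_diff,
        }))
    records = pd.concat(rows, ignore_index=True)
    records["q"] = bh_qvalues(records["p"].to_numpy())
    call = np.full(len(records), "none", dtype=object)
    ok = (records["q"] < alpha) & \
        (records["median_diff"].abs() >= min_expr_diff)
    call[ok & (records["median_diff"] > 0)] = "up"
    call[ok & (records["median_diff"] < 0)] = "down"
    records["call"] = call
    if second_reference is not None:
        # the change must also hold against the second reference
        for group, ref in second_reference.items():
            rvals = expr.values.loc[genes, ref].to_numpy()
            gvals = expr.values.loc[genes, groups[group]].to_numpy()
            _, ref_diff = rank_sum_matrix(gvals, rvals)
            mask = records["group"] == group
            gate_up = pd.Series(ref_diff >= min_expr_diff, index=genes)
            gate_dn = pd.Series(ref_diff <= -min_expr_diff, index=genes)
            sub = records.loc[mask]
            keep_up = sub["gene"].map(gate_up).to_numpy()
            keep_dn = sub["gene"].map(gate_dn).to_numpy()
            new_call = sub["call"].to_numpy(copy=True)
            new_call[(new_call == "up") & ~keep_up] = "none"
            new_call[(new_call == "down") & ~keep_dn] = "none"
            records.loc[mask, "call"] = new_call
    return records


def _link_supports(direction: str, meth_call: str, rho: float) -> bool:
    """Does (methylation call, correlation sign) predict the expression
    direction?  hyper with rho>0 or hypo with rho<0 supports up; hyper
    with rho<0 or hypo with rho>0 supports down."""
    if meth_call not in ("hyper", "hypo"):
        return False
    predicted = "up" if (meth_call == "hyper") == (rho > 0) else "down"
    return predicted == direction


def classify_group_specific_genes(links: ProbeGeneLinkTable,
                                  aberrant: GroupAberrantTable,
                                  expr: ExpressionMatrix,
                                  groups: dict[str, list[str]],
                                  normals: list[str],
                                  alpha: float = 0.05,
                                  min_expr_diff: float = 0.0,
                                  second_reference: dict[str, list[str]] | None = None
                                  ) -> ExpressionCategoryTable:
    """Assign genes to the four group-exclusive expression categories.

    A gene enters e.g. ``up_in_A_only`` iff its expression is up vs
    normals in A (q < alpha, median diff >= min_expr_diff) and not up in
    B, and at least one significant methylation-expression link supports
    the change: the probe's aberrant call in A is direction-consistent
    with the link's rho, while in B the probe is unchanged or opposite.
    If several categories match (possible when A and B move in opposite
    directions), the one with the larger expression effect wins.
    """
    if len(groups) != 2:
        raise ValidationError("classification needs exactly two groups")
    for g in groups:
        if not groups[g]:
            raise ValidationError(f"group {g!r} is empty")
    group_a, group_b = list(groups)
    sig_links = links.significant()
    genes = sorted(set(sig_links["gene"]) & set(expr.values.index))
    if not genes:
        return ExpressionCategoryTable(
            pd.DataFrame(columns=["gene", "category", "supporting_probes",
                                  "median_A", "median_B", "median_normal",
                                  "expr_diff", "highly_transcribed"]),
            group_a, group_b)
    expr_calls = _expression_calls(expr, groups, normals, genes, alpha,
                                   min_expr_diff, second_reference)
    calls = expr_calls.pivot(index="gene", columns="group", values="call")
    diffs = expr_calls.pivot(index="gene", columns="group",
                             values="median_diff")
    rows = []
    med_normal = expr.values.loc[genes, normals].median(axis=1)
    for gene in genes:
        glinks = sig_links[sig_links["gene"] == gene]
        candidates = []
        for this, other, tag in ((group_a, group_b, "A"),
                                 (group_b, group_a, "B")):
            direction = calls.at[gene, this]
            if direction == "none" or calls.at[gene, other] == direction:
                continue
            calls_this = aberrant.calls_for(this)
            calls_other = aberrant.calls_for(other)
            support = []
            for link in glinks.itertuples(index=False):
                mc = calls_this.get(link.probe, "none")
                oc = calls_other.get(link.probe, "none")
                if _link_supports(direction, mc, link.rho) and oc != mc:
                    support.append(link.probe)
            if support:
                candidates.append((abs(diffs.at[gene, this]),
                                   f"{direction}_in_{tag}_only", support,
                                   diffs.at[gene, this]))
        if candidates:
            _, category, support, eff = max(candidates, key=lambda c: c[0])
        else:
            category, support, eff = "none", [], np.nan
        rows.append({
            "gene": gene, "category": category,
            "supporting_probes": ";".join(sorted(support)),
            "median_A": expr.values.loc[gene, groups[group_a]].median(),
            "median_B": expr.values.loc[gene, groups[group_b]].median(),
            "median_normal": med_normal[gene],
            "expr_diff": eff,
            "highly_transcribed": False,
        })
    return ExpressionCategoryTable(pd.DataFrame(rows), group_a, group_b)


def filter_highly_transcribed(table: ExpressionCategoryTable,
                              expr: ExpressionMatrix,
                              groups: dict[str, list[str]],
                              normals: list[str],
                              level_cut: float = 10.0,
                              diff_cut: float = 1.0) -> list[str]:
    """Categorized genes whose own group's median expression exceeds
    ``level_cut`` log2 RSEM and sits more than ``diff_cut`` log2 units
    (a doubling at 1.0) above the normal median."""
    kept = []
    med_n = expr.values[normals].median(axis=1)
    for rec in table.records.itertuples(index=False):
        if rec.category == "none":
            continue
        tag = rec.category.split("_in_")[1][0]  # 'A' or 'B'
        group = table.group_a if tag == "A" else table.group_b
        med = expr.values.loc[rec.gene, groups[group]].median()
        if med > level_cut and med - med_n[rec.gene] > diff_cut:
            kept.append(rec.gene)
    mask = table.records["gene"].isin(kept)
    table.records["highly_transcribed"] = mask.to_numpy()
    return kept


@dataclass
class EnrichmentTable:
    records: pd.DataFrame  # set_name, hits, draw, set_size, universe, p, q
    alpha: float = 0.05

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.records[self.records["q"] < a]


def enrich_gene_sets(genes: list[str], sets: GeneSetCollection,
                     universe: list[str], alpha: float = 0.05
                     ) -> EnrichmentTable:
    """Hypergeometric upper-tail enrichment of ``genes`` in each set,
    restricted to the universe; BH across sets."""
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty universe")
    draw = set(genes)
    if not draw <= universe_set:
        raise ValidationError("genes must be a subset of the universe")
    rows = []
    for name, members in sets.sets.items():
        in_universe = set(members) & universe_set
        if not in_universe:
            continue
        hits = len(draw & in_universe)
        p = hypergeometric_enrichment(hits, len(draw), len(in_universe),
                                      len(universe_set))
        rows.append((name, hits, len(draw), len(in_universe),
                     len(universe_set), p))
    records = pd.DataFrame(rows, columns=["set_name", "hits", "draw",
                                          "set_size", "universe", "p"])
    records["q"] = bh_qvalues(records["p"].to_numpy()) if len(records) else \
        pd.Series(dtype=float)
    return EnrichmentTable(records, alpha=alpha)


def cross_cancer_shared_genes(tables: list[ExpressionCategoryTable],
                              min_cohorts: int = 2
                              ) -> tuple[list[str], list[str]]:
    """Genes falling in the same up/down category in at least
    ``min_cohorts`` cohorts: (up_shared, down_shared)."""
    if len(tables) < 2:
        raise ValidationError("need >= 2 cohort tables")
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    for t in tables:
        for rec in t.records.itertuples(index=False):
            if rec.category.startswith("up"):
                up[rec.gene] = up.get(rec.gene, 0) + 1
            elif rec.category.startswith("down"):
                down[rec.gene] = down.get(rec.gene, 0) + 1
    up_shared = sorted(g for g, n in up.items() if n >= min_cohorts)
    down_shared = sorted(g for g, n in down.items() if n >= min_cohorts)
    return up_shared, down_shared
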