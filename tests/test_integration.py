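"""Probe-gene linkage, methylation-expression correlation, and the
four-category group-specific classification."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mutmeth import (
    CoupledGene,
    DriverSpec,
    ExpressionMatrix,
    GeneSetCollection,
    PlantedEffect,
    SimulationConfig,
    ValidationError,
    call_group_aberrant_probes,
    classify_group_specific_genes,
    correlate_methylation_expression,
    cross_cancer_shared_genes,
    enrich_gene_sets,
    filter_highly_transcribed,
    generate_cohort,
    hypergeometric_enrichment,
    map_probes_to_genes,
)
from mutmeth.integration import ExpressionCategoryTable
from mutmeth.synthetic import probe_names
from conftest import make_annotation, make_beta


class TestProbeGeneMapping:
    def _genes(self):
        return pd.DataFrame([
            {"gene": "GENE1", "chromosome": "chr1", "start": 10_000,
             "end": 30_000, "strand": "+"},
        ])

    def _ann(self, positions):
        probes = [f"p{i}" for i in range(len(positions))]
        return make_annotation(probes, position=positions)

    def test_tss_window_boundary_inclusive(self):
        ann = self._ann([11_500, 11_501, 29_000, 50_000])
        links = map_probes_to_genes(ann, self._genes(), tss_window=1500)
        by_probe = dict(zip(links["probe"], links["region"]))
        assert by_probe["p0"] == "promoter"   # TSS + 1500 exactly
        assert by_probe["p1"] == "body"       # TSS + 1501, inside span
        assert by_probe["p2"] == "body"
        assert "p3" not in by_probe

    def test_matches_interval_oracle(self):
        rng = np.random.default_rng(0)
        genes = pd.DataFrame([
            {"gene": f"G{i}", "chromosome": "chr1",
             "start": int(s), "end": int(s + 8000),
             "strand": rng.choice(["+", "-"])}
            for i, s in enumerate(rng.integers(0, 60_000, 5))])
        positions = sorted(rng.integers(0, 70_000, 20).tolist())
        ann = self._ann(positions)
        links = map_probes_to_genes(ann, genes, tss_window=1500)
        got = {(r.probe, r.gene, r.region)
               for r in links.itertuples(index=False)}
        want = set()
        for g in genes.itertuples(index=False):
            tss = g.start if g.strand == "+" else g.end
            for probe, pos in zip(ann.probe_ids, positions):
                if abs(pos - tss) <= 1500:
                    want.add((probe, g.gene, "promoter"))
                elif g.start <= pos <= g.end:
                    want.add((probe, g.gene, "body"))
        assert got == want

    def test_annotation_linkage_mode(self):
        ann = make_annotation(["p0", "p1", "p2"],
                              linked_gene=["GENE1", "", "GENE2"],
                              link_region=["promoter", "none", "body"])
        links = map_probes_to_genes(ann)
        assert len(links) == 2
        assert set(links["gene"]) == {"GENE1", "GENE2"}


def _thca_like_cohort(seed=0, n_coupled=6):
    """Two mutually exclusive groups; coupled genes planted per group
    with known expected categories."""
    cfg = SimulationConfig(
        n_tumors=120, n_normals=30,
        probes_per_subset={"CGI": 150, "SS": 50, "open_sea": 150},
        driver_genes=(DriverSpec("BRAFL", 0.5, "grp"),
                      DriverSpec("RASL", 0.5, "grp")),
        seed=seed)
    probes = probe_names(cfg)
    cgi = [p for p in probes if p.startswith("cg_cgi")]
    sea = [p for p in probes if p.startswith("cg_sea")]
    effects, coupled, expected = [], [], {}
    combos = [("BRAFL", 0.3, -1, "down_in_A_only"),
              ("BRAFL", -0.3, -1, "up_in_A_only"),
              ("RASL", 0.3, 1, "up_in_B_only"),
              ("RASL", -0.3, 1, "down_in_B_only")]
    for i in range(n_coupled):
        gene_name = f"CPL{i:02d}"
        gene, delta, sign, category = combos[i % len(combos)]
        probe = (cgi if delta > 0 else sea)[i]
        effects.append(PlantedEffect(gene, (probe,), delta))
        coupled.append(CoupledGene(gene_name, probe, sign))
        up = (sign * delta) > 0
        expected[gene_name] = category.replace(
            category.split("_")[0], "up" if up else "down")
    cfg = dataclasses.replace(cfg, planted_effects=tuple(effects),
                              coupled_genes=tuple(coupled))
    ds, truth = generate_cohort(cfg)
    groups = {"A": ds.mutations.mutated_samples("BRAFL"),
              "B": ds.mutations.mutated_samples("RASL")}
    return ds, groups, expected


class TestCorrelationStep:
    def test_planted_zero_noise_link_is_exact(self):
        cfg = SimulationConfig(
            n_tumors=40, n_normals=10,
            probes_per_subset={"CGI": 30, "SS": 0, "open_sea": 0},
            driver_genes=(DriverSpec("D", 0.4),),
            expression_noise_sd=0.0, seed=1)
        probe = probe_names(cfg)[0]
        cfg = dataclasses.replace(cfg,
                                  coupled_genes=(CoupledGene("C", probe, -1),))
        ds, _ = generate_cohort(cfg)
        links = map_probes_to_genes(ds.annotation)
        table = correlate_methylation_expression(ds.beta, ds.expression,
                                                 links)
        rec = table.records.iloc[0]
        assert rec["rho"] == pytest.approx(-1.0)
        assert rec["q"] == table.records["q"].min()

    def test_constant_expression_skipped_not_fatal(self):
        beta = make_beta(np.random.default_rng(2).uniform(size=(3, 10)),
                         n_tumors=10)
        expr = ExpressionMatrix(pd.DataFrame(
            {s: [5.0, 1.0] for s in beta.sample_ids},
            index=["FLAT", "VAR"]).astype(float))
        expr.values.loc["VAR"] = np.arange(10, dtype=float)
        links = pd.DataFrame({"probe": ["cg0000", "cg0001"],
                              "gene": ["FLAT", "VAR"],
                              "region": ["promoter", "promoter"]})
        table = correlate_methylation_expression(beta, expr, links)
        assert set(table.records["gene"]) == {"VAR"}

    def test_null_links_type_one_rate(self):
        rng = np.random.default_rng(3)
        beta = make_beta(rng.uniform(size=(100, 50)), n_tumors=50)
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(100, 50)),
            index=[f"g{i}" for i in range(100)], columns=beta.sample_ids))
        links = pd.DataFrame({"probe": beta.probe_ids,
                              "gene": [f"g{i}" for i in range(100)],
                              "region": "promoter"})
        table = correlate_methylation_expression(beta, expr, links)
        # raw p below 0.05 near the nominal rate; BH keeps none
        assert (table.records["p"] < 0.05).mean() < 0.15
        assert len(table.significant()) <= 1


class TestGroupAberrant:
    def test_shifted_group_called_hyper(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.3, 0.5, size=(5, 90))
        vals[0, :30] += 0.3  # group A tumors at probe 0
        beta = make_beta(np.clip(vals, 0, 1), n_tumors=60, n_normals=30)
        groups = {"A": beta.tumor_samples[:30], "B": beta.tumor_samples[30:]}
        table = call_group_aberrant_probes(beta, groups)
        assert table.calls_for("A")["cg0000"] == "hyper"
        assert table.calls_for("B")["cg0000"] == "none"

    def test_effect_threshold_gates_calls(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.4, 0.005, size=(3, 60))
        vals[0, :20] += 0.05  # significant but small shift
        beta = make_beta(np.clip(vals, 0, 1), n_tumors=20, n_normals=40)
        groups = {"A": beta.tumor_samples}
        loose = call_group_aberrant_probes(beta, groups)
        strict = call_group_aberrant_probes(beta, groups,
                                            min_abs_median_diff=0.1)
        assert loose.calls_for("A")["cg0000"] == "hyper"
        assert strict.calls_for("A")["cg0000"] == "none"

    def test_no_normals_errors(self):
        beta = make_beta(np.full((2, 5), 0.5), n_tumors=5)
        with pytest.raises(ValidationError):
            call_group_aberrant_probes(beta, {"A": beta.tumor_samples})


class TestClassification:
    def test_planted_categories_recovered(self):
        ds, groups, expected = _thca_like_cohort(seed=6, n_coupled=8)
        links = map_probes_to_genes(ds.annotation)
        linked = correlate_methylation_expression(ds.beta, ds.expression,
                                                  links)
        aberrant = call_group_aberrant_probes(ds.beta, groups)
        table = classify_group_specific_genes(
            linked, aberrant, ds.expression, groups, ds.beta.normal_samples)
        got = dict(zip(table.records["gene"], table.records["category"]))
        correct = sum(got.get(g) == c for g, c in expected.items())
        wrong = sum(g in got and got[g] not in (c, "none")
                    for g, c in expected.items())
        assert correct >= 6 and wrong == 0

    def test_swapping_groups_mirrors_categories(self):
        ds, groups, _ = _thca_like_cohort(seed=7, n_coupled=4)
        links = map_probes_to_genes(ds.annotation)
        linked = correlate_methylation_expression(ds.beta, ds.expression,
                                                  links)
        aberrant = call_group_aberrant_probes(ds.beta, groups)
        t1 = classify_group_specific_genes(
            linked, aberrant, ds.expression, groups, ds.beta.normal_samples)
        swapped = {"A": groups["B"], "B": groups["A"]}
        ab2 = call_group_aberrant_probes(ds.beta, swapped)
        t2 = classify_group_specific_genes(
            linked, ab2, ds.expression, swapped, ds.beta.normal_samples)
        m1 = dict(zip(t1.records["gene"], t1.records["category"]))
        m2 = dict(zip(t2.records["gene"], t2.records["category"]))
        flip = {"up_in_A_only": "up_in_B_only",
                "up_in_B_only": "up_in_A_only",
                "down_in_A_only": "down_in_B_only",
                "down_in_B_only": "down_in_A_only", "none": "none"}
        assert m1.keys() == m2.keys()
        for g in m1:
            assert flip[m1[g]] == m2[g]

    def test_categories_mutually_exclusive(self):
        ds, groups, _ = _thca_like_cohort(seed=8, n_coupled=4)
        links = map_probes_to_genes(ds.annotation)
        linked = correlate_methylation_expression(ds.beta, ds.expression,
                                                  links)
        aberrant = call_group_aberrant_probes(ds.beta, groups)
        table = classify_group_specific_genes(
            linked, aberrant, ds.expression, groups, ds.beta.normal_samples)
        assert (table.records.groupby("gene")["category"].nunique() == 1).all()


class TestHighlyTranscribed:
    def _table(self, genes):
        df = pd.DataFrame({"gene": genes,
                           "category": ["up_in_A_only"] * len(genes),
                           "supporting_probes": "", "median_A": np.nan,
                           "median_B": np.nan, "median_normal": np.nan,
                           "expr_diff": 1.0, "highly_transcribed": False})
        return ExpressionCategoryTable(df, "A", "B")

    def test_level_and_doubling_gates(self):
        samples = [f"t{i}" for i in range(4)] + ["n0", "n1"]
        expr = ExpressionMatrix(pd.DataFrame(
            {"t0": [11.0, 9.9, 10.5], "t1": [11.0, 9.9, 10.5],
             "t2": [11.0, 9.9, 10.5], "t3": [11.0, 9.9, 10.5],
             "n0": [9.5, 5.0, 10.0], "n1": [9.5, 5.0, 10.0]},
            index=["KEEP", "LOWLEVEL", "SMALLDIFF"]))
        table = self._table(["KEEP", "LOWLEVEL", "SMALLDIFF"])
        groups = {"A": [f"t{i}" for i in range(4)], "B": []}
        kept = filter_highly_transcribed(table, expr, groups, ["n0", "n1"])
        assert kept == ["KEEP"]


class TestEnrichment:
    def test_whole_set_is_top_hit(self):
        sets = GeneSetCollection({"TARGET": [f"g{i}" for i in range(5)],
                                  "OTHER": [f"h{i}" for i in range(5)]})
        universe = [f"g{i}" for i in range(5)] + \
            [f"h{i}" for i in range(5)] + [f"x{i}" for i in range(40)]
        table = enrich_gene_sets([f"g{i}" for i in range(5)], sets, universe)
        best = table.records.sort_values("p").iloc[0]
        assert best["set_name"] == "TARGET"
        assert best["p"] == table.records["p"].min()

    def test_matches_kernel_oracle(self):
        sets = GeneSetCollection({"S": [f"g{i}" for i in range(5)]})
        universe = [f"g{i}" for i in range(10)]
        table = enrich_gene_sets([f"g{i}" for i in range(4)], sets, universe)
        assert table.records.iloc[0]["p"] == pytest.approx(
            hypergeometric_enrichment(4, 4, 5, 10))

    def test_empty_universe_errors(self):
        sets = GeneSetCollection({"S": ["g1"]})
        with pytest.raises(ValidationError):
            enrich_gene_sets([], sets, [])


class TestCrossCancer:
    def _cat_table(self, mapping):
        df = pd.DataFrame({"gene": list(mapping),
                           "category": list(mapping.values()),
                           "supporting_probes": "", "median_A": np.nan,
                           "median_B": np.nan, "median_normal": np.nan,
                           "expr_diff": np.nan, "highly_transcribed": False})
        return ExpressionCategoryTable(df, "A", "B")

    def test_shared_and_conflicting_genes(self):
        tabs = [self._cat_table({"g1": "up_in_A_only", "g2": "up_in_A_only",
                                 "g3": "down_in_A_only"}),
                self._cat_table({"g1": "up_in_A_only",
                                 "g3": "up_in_A_only"}),
                self._cat_table({"g2": "none"})]
        up, down = cross_cancer_shared_genes(tabs, min_cohorts=2)
        assert up == ["g1"]      # g3 up once + down once -> neither
        assert down == []

    def test_matches_multiset_oracle(self):
        rng = np.random.default_rng(9)
        cats = ["up_in_A_only", "down_in_B_only", "none"]
        tabs, tallies_up, tallies_down = [], {}, {}
        for _ in range(4):
            mapping = {f"g{i}": rng.choice(cats) for i in range(12)}
            tabs.append(self._cat_table(mapping))
            for g, c in mapping.items():
                if c.startswith("up"):
                    tallies_up[g] = tallies_up.get(g, 0) + 1
                elif c.startswith("down"):
                    tallies_down[g] = tallies_down.get(g, 0) + 1
        up, down = cross_cancer_shared_genes(tabs, min_cohorts=2)
        assert up == sorted(g for g, n in tallies_up.items() if n >= 2)
        assert down == sorted(g for g, n in tallies_down.items() if n >= 2)
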