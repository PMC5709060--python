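"""Gene x probe scan, empirical FDR, dominance, sharing, re-correction."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mutmeth import (
    DriverSpec,
    MutationMatrix,
    PlantedEffect,
    SimulationConfig,
    ValidationError,
    associate_genes_with_probes,
    call_aberrant_probes,
    count_shared_probes,
    estimate_empirical_fdr,
    generate_cohort,
    generate_null_cohort,
    reassociate_single_gene,
    summarize_dominance,
)
from mutmeth.site_assoc import SiteAssociationTable
from mutmeth.synthetic import probe_names
from conftest import make_beta


class TestScan:
    def test_planted_recovery(self, planted_cohort):
        ds, truth = planted_cohort
        table = associate_genes_with_probes(ds.beta, ds.mutations,
                                            ds.annotation)
        sig = table.significant()
        planted = truth.planted_probes
        found = set(sig.loc[sig["gene"] == "G000", "probe"])
        assert len(found & planted) >= 15  # 20 planted on a small cohort
        # sign of the planted effect is recovered
        pos = sig[(sig["gene"] == "G000") & sig["probe"].isin(planted)]
        assert (pos["direction"] == 1).all()

    def test_zero_mutated_gene_absent(self, planted_cohort):
        ds, _ = planted_cohort
        status = ds.mutations.status.copy()
        status.loc["G001"] = 0
        table = associate_genes_with_probes(ds.beta,
                                            MutationMatrix(status))
        assert "G001" not in set(table.records["gene"])

    def test_invariant_to_sample_and_probe_order(self, planted_cohort):
        ds, _ = planted_cohort
        t1 = associate_genes_with_probes(ds.beta, ds.mutations)
        rng = np.random.default_rng(0)
        probe_perm = rng.permutation(len(ds.beta.probe_ids))
        sample_perm = rng.permutation(ds.beta.sample_ids)
        shuffled = dataclasses.replace(ds.beta)
        shuffled.values = ds.beta.values.iloc[probe_perm][sample_perm]
        shuffled.sample_group = ds.beta.sample_group[sample_perm]
        t2 = associate_genes_with_probes(shuffled, ds.mutations)
        a = t1.records.set_index(["gene", "probe"]).sort_index()
        b = t2.records.set_index(["gene", "probe"]).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_direction_flips_under_label_complement(self, planted_cohort):
        ds, _ = planted_cohort
        t1 = associate_genes_with_probes(ds.beta, ds.mutations,
                                         min_mutated=5)
        flipped = MutationMatrix(1 - ds.mutations.status)
        genes = set(t1.records["gene"]) & set(
            associate_genes_with_probes(ds.beta, flipped,
                                        min_mutated=5).records["gene"])
        t2 = associate_genes_with_probes(ds.beta, flipped, min_mutated=5)
        a = t1.records.set_index(["gene", "probe"])
        b = t2.records.set_index(["gene", "probe"])
        for gene in genes:
            ga = a.loc[gene].sort_index()
            gb = b.loc[gene].sort_index()
            assert (ga["direction"] == -gb["direction"]).all()
            assert np.allclose(ga["median_diff"], -gb["median_diff"])

    def test_missing_heavy_probes_skipped(self, small_cohort_config):
        ds, _ = generate_null_cohort(small_cohort_config)
        beta = ds.beta
        victim = beta.probe_ids[0]
        tumors = beta.tumor_samples
        beta.values.loc[victim, tumors[:45]] = np.nan  # 75% of tumors
        table = associate_genes_with_probes(beta, ds.mutations)
        assert victim not in set(table.records["probe"])


class TestEmpiricalFdr:
    def test_null_scan_rarely_discovers(self, small_cohort_config):
        ds, _ = generate_null_cohort(small_cohort_config)
        table = associate_genes_with_probes(ds.beta, ds.mutations)
        assert table.n_discoveries() <= 2

    def test_planted_cohort_fdr_small(self, planted_cohort):
        ds, _ = planted_cohort
        est = estimate_empirical_fdr(ds.beta, ds.mutations,
                                     n_permutations=5, seed=3)
        assert est.n_observed > 0
        assert est.empirical_fdr < 0.05

    def test_seed_determinism(self, planted_cohort):
        ds, _ = planted_cohort
        a = estimate_empirical_fdr(ds.beta, ds.mutations,
                                   n_permutations=3, seed=7)
        b = estimate_empirical_fdr(ds.beta, ds.mutations,
                                   n_permutations=3, seed=7)
        assert a == b

    def test_bad_permutation_count_errors(self, planted_cohort):
        ds, _ = planted_cohort
        with pytest.raises(ValidationError):
            estimate_empirical_fdr(ds.beta, ds.mutations, n_permutations=0)

    def test_joint_mode_preserves_comutation(self, planted_cohort):
        ds, _ = planted_cohort
        est = estimate_empirical_fdr(ds.beta, ds.mutations,
                                     n_permutations=2, seed=1, mode="joint")
        assert est.empirical_fdr <= 1.0


class TestDominance:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "probe", "p", "q",
                                         "direction", "median_diff",
                                         "cpg_subset"])
        return SiteAssociationTable(df)

    def test_single_gene_owns_everything(self):
        rows = [("G1", f"p{i}", 1e-5, 1e-4, 1, 0.2, "CGI")
                for i in range(10)]
        dom = summarize_dominance(self._table(rows))
        assert dom.per_gene.loc["G1", "frac_of_total"] == 1.0
        assert bool(dom.per_gene.loc["G1", "dominant"])

    def test_hand_tallied_splits(self):
        rows = [
            ("G1", "p1", 1e-5, 1e-4, 1, 0.2, "CGI"),
            ("G1", "p2", 1e-5, 1e-4, 1, 0.2, "CGI"),
            ("G1", "p3", 1e-5, 1e-4, -1, -0.2, "open_sea"),
            ("G2", "p4", 1e-5, 1e-4, -1, -0.2, "SS"),
            ("G2", "p5", 1e-5, 1e-4, -1, -0.2, "SS"),
            ("G2", "p1", 1e-5, 1e-4, 1, 0.2, "CGI"),
        ]
        dom = summarize_dominance(self._table(rows))
        g1 = dom.per_gene.loc["G1"]
        assert g1["n_assoc"] == 3
        assert g1["pos_CGI"] == 2 and g1["neg_open_sea"] == 1
        g2 = dom.per_gene.loc["G2"]
        assert g2["neg_SS"] == 2 and g2["pos_CGI"] == 1
        # 5 unique probes; G1 has 3 -> dominant at >10%
        assert dom.n_total_probes == 5
        assert g1["frac_of_total"] == pytest.approx(3 / 5)

    def test_joint_aberrant_direction_counts(self, planted_cohort):
        ds, truth = planted_cohort
        table = associate_genes_with_probes(ds.beta, ds.mutations,
                                            ds.annotation)
        aberrant = call_aberrant_probes(ds.beta)
        dom = summarize_dominance(table, aberrant)
        if "G000" in dom.per_gene.index:
            g = dom.per_gene.loc["G000"]
            assert g["pos_and_hyper"] <= g["n_assoc"]


class TestSharing:
    def _sig_table(self, gene, probes, direction=-1):
        df = pd.DataFrame({
            "gene": gene, "probe": probes, "p": 1e-6, "q": 1e-5,
            "direction": direction, "median_diff": 0.2 * direction,
        })
        return SiteAssociationTable(df)

    def test_identical_probe_sets_across_cohorts(self):
        tabs = [self._sig_table("TP53", [f"p{i}" for i in range(5)])
                for _ in range(3)]
        counts = count_shared_probes(tabs, "TP53", -1)
        assert counts == {1: 5, 2: 5, 3: 5}

    def test_disjoint_sets(self):
        tabs = [self._sig_table("TP53", ["a", "b"]),
                self._sig_table("TP53", ["c", "d"])]
        counts = count_shared_probes(tabs, "TP53", -1)
        assert counts[2] == 0 and counts[1] == 4

    def test_random_overlap_matches_set_oracle(self):
        rng = np.random.default_rng(1)
        universe = [f"p{i}" for i in range(30)]
        sets = [sorted(rng.choice(universe, 12, replace=False))
                for _ in range(4)]
        tabs = [self._sig_table("G", s) for s in sets]
        counts = count_shared_probes(tabs, "G", -1)
        for k in range(1, 5):
            want = sum(1 for p in universe
                       if sum(p in s for s in sets) >= k)
            assert counts.get(k, 0) == want

    def test_absent_gene_empty(self):
        tabs = [self._sig_table("G1", ["a"]), self._sig_table("G1", ["b"])]
        assert count_shared_probes(tabs, "G2", 1) == {}


class TestSingleGeneRecorrection:
    def test_q_no_larger_than_joint_family(self, planted_cohort):
        ds, _ = planted_cohort
        joint = associate_genes_with_probes(ds.beta, ds.mutations)
        single = reassociate_single_gene(ds.beta, ds.mutations, "G000")
        j = joint.records[joint.records["gene"] == "G000"].set_index("probe")
        s = single.records.set_index("probe")
        # away from the q ~ 1 tail the smaller family can only shrink q
        head = j.index[j["q"] < 0.5]
        assert (s.loc[head, "q"] <= j.loc[head, "q"] + 1e-12).all()
        # and the recovered probe set is a superset
        assert set(j[j["q"] < 0.05].index) <= set(s[s["q"] < 0.05].index)

    def test_ineligible_gene_errors(self, planted_cohort):
        ds, _ = planted_cohort
        status = ds.mutations.status.copy()
        status.loc["G001"] = 0
        with pytest.raises(ValidationError):
            reassociate_single_gene(ds.beta, MutationMatrix(status), "G001")
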