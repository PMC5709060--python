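"""Reference experiments on synthetic cohorts.

Each function generates cohorts under the package's standard study
conditions (100 tumors, 30 adjacent normals, 5,000 probes across the
three CpG subsets, 20 driver genes with frequencies in 0.05-0.3 unless
stated otherwise), runs one analysis stage end to end, and measures a
recovery or error-control property against the planted truth.  They are
the backing computations for the validation suite and the analysis
drivers; every replicate's seed derives from the caller's base seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .genome_indices import associate_genes_with_index, compute_hyperz_hypoz
from .integration import (
    call_group_aberrant_probes,
    classify_group_specific_genes,
    correlate_methylation_expression,
    map_probes_to_genes,
)
from .site_assoc import associate_genes_with_probes
from .subtyping import (
    cluster_samples,
    select_top_associated_probes,
    select_top_variance_probes,
)
from .synthetic import (
    CoupledGene,
    DriverSpec,
    PlantedEffect,
    SimulationConfig,
    default_null_drivers,
    generate_cohort,
    generate_null_cohort,
    probe_names,
)

_SEED_MOD = 2**31 - 1


def _sub_seed(base: int, stream: int, rep: int) -> int:
    return (base * 1_000_003 + stream * 7_919 + rep) % _SEED_MOD


def _standard_config(seed: int, n_genes: int = 20) -> SimulationConfig:
    return SimulationConfig(
        driver_genes=default_null_drivers(n_genes,
                                          seed=_sub_seed(seed, 99, 0)),
        seed=seed)


@dataclass
class NullFdpResult:
    """Realized false-discovery proportions on all-null cohorts."""

    fdp: list[float]          # V / max(R, 1) per replicate; V = R here
    discoveries: list[int]
    n_tests: int

    @property
    def mean_fdp(self) -> float:
        return float(np.mean(self.fdp))


def null_scan_fdp(seed: int, n_replicates: int = 20, alpha: float = 0.05
                  ) -> NullFdpResult:
    """Site-association scan on null cohorts: every q < alpha discovery
    is false by construction, so FDP = V / max(R, 1) with V = R."""
    fdps, counts, n_tests = [], [], 0
    for rep in range(n_replicates):
        cfg = _standard_config(_sub_seed(seed, 1, rep))
        ds, _ = generate_null_cohort(cfg)
        table = associate_genes_with_probes(ds.beta, ds.mutations,
                                            alpha=alpha)
        r = table.n_discoveries()
        counts.append(r)
        fdps.append(r / max(r, 1))
        n_tests = len(table.records)
    return NullFdpResult(fdps, counts, n_tests)


@dataclass
class RecoveryResult:
    sensitivity: list[float]
    precision: list[float]

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))


def planted_recovery(seed: int, n_seeds: int = 20, delta_beta: float = 0.3,
                     n_planted: int = 50, frequency: float = 0.3,
                     alpha: float = 0.05) -> RecoveryResult:
    """One gene plants ``delta_beta`` on ``n_planted`` CGI probes;
    sensitivity and precision of the scan's discovery set at q < alpha."""
    sens, prec = [], []
    for rep in range(n_seeds):
        cfg = _standard_config(_sub_seed(seed, 2, rep))
        drivers = (DriverSpec("G000", frequency),) + cfg.driver_genes[1:]
        probes = tuple(probe_names(cfg)[:n_planted])
        cfg = dataclasses.replace(
            cfg, driver_genes=drivers,
            planted_effects=(PlantedEffect("G000", probes, delta_beta),))
        ds, truth = generate_cohort(cfg)
        table = associate_genes_with_probes(ds.beta, ds.mutations,
                                            alpha=alpha)
        sig = table.significant()
        planted = truth.planted_probes
        found_for_gene = set(sig.loc[sig["gene"] == "G000", "probe"])
        true_pairs = len(found_for_gene & planted)
        sens.append(true_pairs / n_planted)
        prec.append(true_pairs / max(len(sig), 1))
    return RecoveryResult(sens, prec)


@dataclass
class SubtypeRecoveryResult:
    ari_association_panel: list[float]
    ari_variance_panel: list[float]
    panel_concordance: list[float]  # ARI between the two partitions

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.ari_association_panel))

    @property
    def mean_concordance(self) -> float:
        return float(np.mean(self.panel_concordance))


def subtype_recovery(seed: int, n_seeds: int = 20, delta_beta: float = 0.3,
                     panel_size: int = 200, k_top: int = 500
                     ) -> SubtypeRecoveryResult:
    """Two mutually exclusive genes plant opposite-sign effects on
    disjoint panels; hierarchical clustering of the top-k association
    union (and of the top-1% variance panel) vs the planted labels."""
    aris, aris_var, concord = [], [], []
    for rep in range(n_seeds):
        cfg = SimulationConfig(
            driver_genes=(DriverSpec("GA", 0.5, "sub"),
                          DriverSpec("GB", 0.5, "sub")),
            seed=_sub_seed(seed, 3, rep))
        probes = probe_names(cfg)
        cgi = [p for p in probes if p.startswith("cg_cgi")]
        sea = [p for p in probes if p.startswith("cg_sea")]
        cfg = dataclasses.replace(cfg, planted_effects=(
            PlantedEffect("GA", tuple(cgi[:panel_size]), delta_beta),
            PlantedEffect("GB", tuple(sea[:panel_size]), -delta_beta),
        ))
        ds, truth = generate_cohort(cfg)
        table = associate_genes_with_probes(ds.beta, ds.mutations)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            panel = select_top_associated_probes(table, ["GA", "GB"], k_top)
        assign = cluster_samples(ds.beta, panel, k_clusters=2)
        labels_true = truth.subtype_labels[assign.labels.index]
        aris.append(adjusted_rand_score(labels_true, assign.labels))
        var_panel = select_top_variance_probes(ds.beta, 0.01)
        assign_var = cluster_samples(ds.beta, var_panel, k_clusters=2)
        aris_var.append(adjusted_rand_score(labels_true, assign_var.labels))
        concord.append(adjusted_rand_score(assign.labels, assign_var.labels))
    return SubtypeRecoveryResult(aris, aris_var, concord)


@dataclass
class HyperZRecoveryResult:
    n_seeds: int
    n_recovered: int  # seeds where the planting gene is q<0.05, positive

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_seeds


def hyperz_planted_association(seed: int, n_seeds: int = 20,
                               delta_beta: float = 0.3,
                               cgi_fraction: float = 0.3,
                               frequency: float = 0.3,
                               alpha: float = 0.05) -> HyperZRecoveryResult:
    """A CIMP-like gene raises a fraction of all CGI probes in its
    mutated tumors; count seeds where it lands a positive HyperZ
    association at q < alpha."""
    hits = 0
    for rep in range(n_seeds):
        cfg = _standard_config(_sub_seed(seed, 4, rep))
        drivers = (DriverSpec("CIMP", frequency),) + cfg.driver_genes[1:]
        cgi = [p for p in probe_names(cfg) if p.startswith("cg_cgi")]
        n_plant = int(len(cgi) * cgi_fraction)
        cfg = dataclasses.replace(
            cfg, driver_genes=drivers,
            planted_effects=(PlantedEffect("CIMP", tuple(cgi[:n_plant]),
                                           delta_beta),))
        ds, _ = generate_cohort(cfg)
        idx = compute_hyperz_hypoz(ds.beta, ds.annotation)
        assoc = associate_genes_with_index(idx, ds.mutations, "hyperz",
                                           alpha=alpha)
        rec = assoc.records.set_index("gene")
        if "CIMP" in rec.index and rec.at["CIMP", "q"] < alpha \
                and rec.at["CIMP", "direction"] == 1:
            hits += 1
    return HyperZRecoveryResult(n_seeds, hits)


@dataclass
class IntegrationRecoveryResult:
    n_planted: int
    correct: list[int]   # per seed: genes in their planted category
    wrong: list[int]     # per seed: genes in a different (non-none) slot

    @property
    def mean_correct(self) -> float:
        return float(np.mean(self.correct))

    @property
    def total_wrong(self) -> int:
        return int(np.sum(self.wrong))


def integration_recovery(seed: int, n_seeds: int = 20,
                         n_coupled: int = 20, delta_beta: float = 0.3,
                         alpha: float = 0.05) -> IntegrationRecoveryResult:
    """Twenty methylation-coupled genes with group-specific planted
    effects; how many land in their planted four-category slot."""
    combos = [("GA", 1, -1), ("GA", -1, -1), ("GB", 1, 1), ("GB", -1, 1)]
    correct, wrong = [], []
    for rep in range(n_seeds):
        cfg = SimulationConfig(
            n_tumors=200, n_normals=30,
            driver_genes=(DriverSpec("GA", 0.5, "grp"),
                          DriverSpec("GB", 0.5, "grp")),
            seed=_sub_seed(seed, 5, rep))
        probes = probe_names(cfg)
        cgi = [p for p in probes if p.startswith("cg_cgi")]
        sea = [p for p in probes if p.startswith("cg_sea")]
        effects, coupled, expected = [], [], {}
        for i in range(n_coupled):
            gene, sgn_delta, sign = combos[i % 4]
            delta = sgn_delta * delta_beta
            probe = (cgi if delta > 0 else sea)[i]
            name = f"CPL{i:02d}"
            effects.append(PlantedEffect(gene, (probe,), delta))
            coupled.append(CoupledGene(name, probe, sign))
            updown = "up" if sign * delta > 0 else "down"
            tag = "A" if gene == "GA" else "B"
            expected[name] = f"{updown}_in_{tag}_only"
        cfg = dataclasses.replace(cfg, planted_effects=tuple(effects),
                                  coupled_genes=tuple(coupled))
        ds, _ = generate_cohort(cfg)
        groups = {"A": ds.mutations.mutated_samples("GA"),
                  "B": ds.mutations.mutated_samples("GB")}
        links = map_probes_to_genes(ds.annotation)
        linked = correlate_methylation_expression(ds.beta, ds.expression,
                                                  links, alpha=alpha)
        aberrant = call_group_aberrant_probes(ds.beta, groups, alpha=alpha)
        table = classify_group_specific_genes(
            linked, aberrant, ds.expression, groups,
            ds.beta.normal_samples, alpha=alpha)
        got = dict(zip(table.records["gene"], table.records["category"]))
        correct.append(sum(got.get(g) == c for g, c in expected.items()))
        wrong.append(sum(g in got and got[g] not in (c, "none")
                         for g, c in expected.items()))
    return IntegrationRecoveryResult(n_coupled, correct, wrong)
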