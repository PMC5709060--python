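"""Synthetic tumor-cohort generator with planted ground truth.

Emulates the statistical structure the association pipeline assumes:
450K-style beta values with CpG-subset-specific baselines (CGI low, open
sea high, shores/shelves intermediate), matched adjacent normals drawn
from the same per-probe baselines, binary driver-gene mutations with
optional mutual-exclusivity groups, planted mutation->methylation shifts
of configurable signed magnitude, and expression coupled positively or
negatively to chosen probes.  Every draw derives from one integer seed.

Beta noise is Gaussian on the logit scale followed by the inverse logit,
which keeps values inside (0, 1) and compresses variance near the
boundaries the way array betas do.  A planted effect ``delta_beta`` is
the target difference in expected beta between mutated and non-mutated
tumors; the corresponding logit-scale shift is found by numeric
inversion so recovery thresholds stay interpretable in beta units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data_model import (
    BetaMatrix,
    CohortDataset,
    ExpressionMatrix,
    MutationMatrix,
    ProbeAnnotation,
    ValidationError,
    write_beta_matrix,
    write_expression,
    write_mutations,
    write_probe_annotation,
)

#: Gauss-Hermite nodes reused for all expected-beta evaluations
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass(frozen=True)
class DriverSpec:
    """One simulated driver gene: name, mutation frequency, optional
    mutual-exclusivity group shared with other drivers."""

    gene: str
    frequency: float
    exclusivity_group: str | None = None


@dataclass(frozen=True)
class PlantedEffect:
    """A mutation->methylation effect: tumors mutated in ``gene`` have
    their expected beta shifted by ``delta_beta`` at ``probes``."""

    gene: str
    probes: tuple[str, ...]
    delta_beta: float


@dataclass(frozen=True)
class CoupledGene:
    """Expression of ``gene`` tracks beta at ``probe`` with the given
    sign; ``slope`` is log2 expression units per beta unit."""

    gene: str
    probe: str
    sign: int
    slope: float = 8.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the regime the pipeline is exercised in: 100
    tumors with 30 adjacent normals over 5,000 probes split across the
    three CpG subsets, subset baselines 0.15 (CGI) / 0.5 (SS) / 0.8
    (open sea), and beta-scale noise of roughly 0.1 SD at baseline.
    """

    n_tumors: int = 100
    n_normals: int = 30
    probes_per_subset: Mapping[str, int] = field(
        default_factory=lambda: {"CGI": 2000, "SS": 1500, "open_sea": 1500})
    baseline_means: Mapping[str, float] = field(
        default_factory=lambda: {"CGI": 0.15, "SS": 0.5, "open_sea": 0.8})
    noise_sd: float = 0.1  # target beta-scale SD at the subset baseline
    probe_baseline_sd: float = 0.3  # logit-scale per-probe baseline jitter
    driver_genes: tuple[DriverSpec, ...] = ()
    planted_effects: tuple[PlantedEffect, ...] = ()
    coupled_genes: tuple[CoupledGene, ...] = ()
    expression_baseline: float = 8.0  # log2 RSEM units
    expression_noise_sd: float = 0.5
    n_background_genes: int = 0
    seed: int = 0

    def validate(self) -> None:
        for d in self.driver_genes:
            if not 0 < d.frequency < 1:
                raise ValidationError(
                    f"mutation frequency for {d.gene} must be in (0, 1)")
        probe_ids = set(probe_names(self))
        for eff in self.planted_effects:
            if abs(eff.delta_beta) > 0.8:
                raise ValidationError("|delta_beta| must be <= 0.8")
            missing = set(eff.probes) - probe_ids
            if missing:
                raise ValidationError(
                    f"planted probes do not exist: {sorted(missing)[:5]}")
        groups: dict[str, float] = {}
        for d in self.driver_genes:
            if d.exclusivity_group is not None:
                groups[d.exclusivity_group] = (
                    groups.get(d.exclusivity_group, 0.0) + d.frequency)
        for name, total in groups.items():
            if total > 1:
                raise ValidationError(
                    f"exclusivity group {name!r}: summed frequencies {total} > 1")


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort, for recovery testing."""

    effect_map: dict[str, dict[str, float]]  # gene -> probe -> delta_beta
    subtype_labels: pd.Series  # tumor sample -> label
    coupled_pairs: list[tuple[str, str, int]]  # (gene, probe, sign)

    @property
    def planted_probes(self) -> set[str]:
        out: set[str] = set()
        for probes in self.effect_map.values():
            out |= set(probes)
        return out


def probe_names(config: SimulationConfig) -> list[str]:
    """Deterministic probe ids, grouped by CpG subset in declared order."""
    names = []
    for subset in ("CGI", "SS", "open_sea"):
        n = int(config.probes_per_subset.get(subset, 0))
        tag = {"CGI": "cgi", "SS": "ss", "open_sea": "sea"}[subset]
        names.extend(f"cg_{tag}_{i:05d}" for i in range(n))
    return names


def _probe_subsets(config: SimulationConfig) -> np.ndarray:
    subsets = []
    for subset in ("CGI", "SS", "open_sea"):
        subsets.extend([subset] * int(config.probes_per_subset.get(subset, 0)))
    return np.array(subsets)


def _expected_beta(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """E[expit(mu + sigma Z)] by Gauss-Hermite quadrature."""
    grid = mu[..., None] + sigma[..., None] * _GH_NODES
    return expit(grid) @ _GH_WEIGHTS


def _center_for_mean(target: float, sd: float) -> float:
    """Logit center whose logit-normal expected beta equals ``target``."""

    def f(m: float) -> float:
        return float(_expected_beta(np.array([m]), np.array([sd]))[0]) - target

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _shift_for_delta(mu: float, sigma: float, delta: float) -> float:
    """Logit shift whose expected-beta change equals ``delta``."""
    base = float(_expected_beta(np.array([mu]), np.array([sigma]))[0])
    target = np.clip(base + delta, 1e-4, 1 - 1e-4)

    def f(s: float) -> float:
        return float(_expected_beta(np.array([mu + s]),
                                    np.array([sigma]))[0]) - target

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _draw_mutations(config: SimulationConfig, tumor_ids: list[str],
                    rng: np.random.Generator) -> pd.DataFrame:
    status = pd.DataFrame(0, index=[d.gene for d in config.driver_genes],
                          columns=tumor_ids, dtype=np.int8)
    independents = [d for d in config.driver_genes if d.exclusivity_group is None]
    for d in independents:
        status.loc[d.gene] = (rng.random(len(tumor_ids)) < d.frequency
                              ).astype(np.int8)
    groups: dict[str, list[DriverSpec]] = {}
    for d in config.driver_genes:
        if d.exclusivity_group is not None:
            groups.setdefault(d.exclusivity_group, []).append(d)
    for members in groups.values():
        probs = [m.frequency for m in members]
        probs.append(1.0 - sum(probs))
        choice = rng.choice(len(members) + 1, size=len(tumor_ids), p=probs)
        for i, m in enumerate(members):
            status.loc[m.gene] = (choice == i).astype(np.int8)
    return status


def generate_cohort(config: SimulationConfig) -> tuple[CohortDataset, PlantedTruth]:
    """Draw one cohort plus its planted ground truth, reproducibly."""
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    rng_probes, rng_mut, rng_beta, rng_expr = (
        np.random.default_rng(s) for s in seq.spawn(4))

    probes = probe_names(config)
    subsets = _probe_subsets(config)
    n_probes = len(probes)
    tumor_ids = [f"T{i:04d}" for i in range(config.n_tumors)]
    normal_ids = [f"N{i:04d}" for i in range(config.n_normals)]
    samples = tumor_ids + normal_ids

    base = np.array([config.baseline_means[s] for s in subsets])
    # logit-scale SD chosen so the beta-scale SD near the subset baseline
    # is about noise_sd (delta method: d beta / d logit = b(1-b))
    sigma = config.noise_sd / (base * (1.0 - base))
    # center each subset so the logit-normal's EXPECTED beta (probe
    # jitter + noise combined) equals the configured baseline mean
    total_sd = np.sqrt(config.probe_baseline_sd ** 2 + sigma ** 2)
    mu_center = np.empty(n_probes)
    for b, sd in set(zip(base, total_sd)):
        mu_center[(base == b) & (total_sd == sd)] = _center_for_mean(b, sd)
    mu = mu_center + rng_probes.normal(0.0, config.probe_baseline_sd, n_probes)

    status = _draw_mutations(config, tumor_ids, rng_mut)

    probe_pos = {p: i for i, p in enumerate(probes)}
    shift = np.zeros((n_probes, len(samples)))
    effect_map: dict[str, dict[str, float]] = {}
    for eff in config.planted_effects:
        effect_map.setdefault(eff.gene, {})
        carriers = [j for j, s in enumerate(tumor_ids)
                    if status.at[eff.gene, s] == 1]
        for probe in eff.probes:
            i = probe_pos[probe]
            effect_map[eff.gene][probe] = eff.delta_beta
            s = _shift_for_delta(mu[i], sigma[i], eff.delta_beta)
            shift[i, carriers] += s

    z = rng_beta.standard_normal((n_probes, len(samples)))
    betas = expit(mu[:, None] + shift + sigma[:, None] * z)
    beta_df = pd.DataFrame(betas, index=probes, columns=samples)
    groups = pd.Series(["tumor"] * len(tumor_ids) + ["normal"] * len(normal_ids),
                       index=samples)
    beta = BetaMatrix(beta_df, groups)

    annotation = _build_annotation(config, probes, subsets)
    mutations = MutationMatrix(status)
    expression = _draw_expression(config, beta, rng_expr)

    planting_genes = sorted(effect_map)
    labels = []
    for s in tumor_ids:
        hit = [g for g in planting_genes if status.at[g, s] == 1]
        labels.append("+".join(hit) if hit else "none")
    truth = PlantedTruth(
        effect_map=effect_map,
        subtype_labels=pd.Series(labels, index=tumor_ids),
        coupled_pairs=[(c.gene, c.probe, c.sign) for c in config.coupled_genes],
    )
    driver_counts = status.sum(axis=1)
    dataset = CohortDataset(beta=beta, mutations=mutations,
                            annotation=annotation,
                            driver_genes=driver_counts,
                            expression=expression)
    return dataset, truth


def generate_null_cohort(config: SimulationConfig
                         ) -> tuple[CohortDataset, PlantedTruth]:
    """Same cohort machinery with no planted effects or couplings: every
    downstream discovery is false by construction."""
    null_cfg = replace(config, planted_effects=(), coupled_genes=())
    return generate_cohort(null_cfg)


def _build_annotation(config: SimulationConfig, probes: list[str],
                      subsets: np.ndarray) -> ProbeAnnotation:
    coupled_by_probe: dict[str, str] = {
        c.probe: c.gene for c in config.coupled_genes}
    chroms = [f"chr{(i % 22) + 1}" for i in range(len(probes))]
    positions = [1000 + 137 * i for i in range(len(probes))]
    table = pd.DataFrame({
        "chromosome": chroms,
        "position": positions,
        "cpg_subset": subsets,
        "linked_gene": [coupled_by_probe.get(p, "") for p in probes],
        "link_region": ["promoter" if p in coupled_by_probe else "none"
                        for p in probes],
        "flags": [frozenset() for _ in probes],
    }, index=pd.Index(probes, name="probe_id"))
    return ProbeAnnotation(table)


def _draw_expression(config: SimulationConfig, beta: BetaMatrix,
                     rng: np.random.Generator) -> ExpressionMatrix | None:
    genes = [d.gene for d in config.driver_genes]
    genes += [c.gene for c in config.coupled_genes if c.gene not in genes]
    genes += [f"BG{i:04d}" for i in range(config.n_background_genes)]
    if not genes:
        return None
    samples = beta.sample_ids
    subsets = dict(zip(beta.probe_ids,
                       _probe_subsets(config)))
    values = np.full((len(genes), len(samples)), config.expression_baseline)
    values = values + rng.normal(0.0, config.expression_noise_sd,
                                 values.shape)
    idx = {g: i for i, g in enumerate(genes)}
    for c in config.coupled_genes:
        b = beta.values.loc[c.probe].to_numpy()
        centered = b - config.baseline_means[subsets[c.probe]]
        values[idx[c.gene]] += c.slope * c.sign * centered
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def write_cohort(dataset: CohortDataset, truth: PlantedTruth,
                 outdir: str | Path) -> dict[str, str]:
    """Write the cohort as standard TSVs plus a truth JSON; returns the
    path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": str(outdir / "beta.tsv"),
        "groups": str(outdir / "groups.tsv"),
        "mutations": str(outdir / "mutations.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_beta_matrix(dataset.beta, paths["beta"], paths["groups"])
    write_mutations(dataset.mutations, paths["mutations"])
    write_probe_annotation(dataset.annotation, paths["annotation"])
    if dataset.expression is not None:
        paths["expression"] = str(outdir / "expression.tsv")
        write_expression(dataset.expression, paths["expression"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump({
            "effect_map": truth.effect_map,
            "subtype_labels": truth.subtype_labels.to_dict(),
            "coupled_pairs": [list(t) for t in truth.coupled_pairs],
        }, fh, indent=1)
    return paths


def default_null_drivers(n_genes: int = 20, seed: int = 0,
                         freq_range: tuple[float, float] = (0.05, 0.3)
                         ) -> tuple[DriverSpec, ...]:
    """Driver panel used for null-cohort experiments: ``n_genes`` genes
    with mutation frequencies drawn uniformly in ``freq_range``."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, n_genes)
    return tuple(DriverSpec(f"G{i:03d}", float(f)) for i, f in enumerate(freqs))
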