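"""Shared fixtures: small synthetic cohorts and hand-built matrices."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mutmeth import (
    BetaMatrix,
    DriverSpec,
    MutationMatrix,
    PlantedEffect,
    ProbeAnnotation,
    SimulationConfig,
    default_null_drivers,
    generate_cohort,
)
from mutmeth.synthetic import probe_names


def make_beta(values: np.ndarray, n_tumors: int, n_normals: int = 0,
              probe_prefix: str = "cg") -> BetaMatrix:
    n_probes, n_samples = values.shape
    assert n_samples == n_tumors + n_normals
    samples = [f"T{i}" for i in range(n_tumors)] + \
        [f"N{i}" for i in range(n_normals)]
    groups = pd.Series(["tumor"] * n_tumors + ["normal"] * n_normals,
                       index=samples)
    df = pd.DataFrame(values, index=[f"{probe_prefix}{i:04d}"
                                     for i in range(n_probes)],
                      columns=samples)
    return BetaMatrix(df, groups)


def make_annotation(probes: list[str], subset: str = "CGI",
                    **overrides) -> ProbeAnnotation:
    table = pd.DataFrame({
        "chromosome": ["chr1"] * len(probes),
        "position": [1000 + 100 * i for i in range(len(probes))],
        "cpg_subset": [subset] * len(probes),
        "linked_gene": [""] * len(probes),
        "link_region": ["none"] * len(probes),
        "flags": [frozenset() for _ in probes],
    }, index=pd.Index(probes, name="probe_id"))
    for col, vals in overrides.items():
        table[col] = vals
    return ProbeAnnotation(table)


@pytest.fixture(scope="session")
def small_cohort_config() -> SimulationConfig:
    """A fast cohort: 60 tumors, 20 normals, 600 probes, 8 drivers."""
    return SimulationConfig(
        n_tumors=60, n_normals=20,
        probes_per_subset={"CGI": 200, "SS": 200, "open_sea": 200},
        driver_genes=default_null_drivers(8, seed=3, freq_range=(0.1, 0.3)),
        seed=42,
    )


@pytest.fixture(scope="session")
def planted_cohort(small_cohort_config):
    """Small cohort with one gene planting +0.3 on 20 CGI probes."""
    probes = probe_names(small_cohort_config)
    cfg = dataclasses.replace(
        small_cohort_config,
        driver_genes=tuple(
            DriverSpec("G000", 0.3) if d.gene == "G000" else d
            for d in small_cohort_config.driver_genes),
        planted_effects=(PlantedEffect("G000", tuple(probes[:20]), 0.3),),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_block_cohort():
    """Two planted subtypes driven by an exclusivity pair: one gene
    raises CGI betas, the other lowers open-sea betas, on disjoint
    30-probe panels; every tumor carries exactly one of the two."""
    cfg = SimulationConfig(
        n_tumors=80, n_normals=20,
        probes_per_subset={"CGI": 250, "SS": 100, "open_sea": 250},
        driver_genes=(
            DriverSpec("GA", 0.5, "sub"), DriverSpec("GB", 0.5, "sub"),
            DriverSpec("GX", 0.2),
        ),
        seed=7,
    )
    probes = probe_names(cfg)
    cgi = [p for p in probes if p.startswith("cg_cgi")]
    sea = [p for p in probes if p.startswith("cg_sea")]
    cfg = dataclasses.replace(cfg, planted_effects=(
        PlantedEffect("GA", tuple(cgi[:30]), 0.3),
        PlantedEffect("GB", tuple(sea[:30]), -0.3),
    ))
    return generate_cohort(cfg)
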