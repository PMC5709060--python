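#!/usr/bin/env python
"""Generate the study's synthetic cohorts and write them as TSVs.

Three cohorts under results/cohorts/:
  * planted  — 100 tumors / 30 normals / 5,000 probes; gene G000 plants
    a +0.3 beta shift on 50 CGI probes at mutation frequency 0.3.
  * null     — same conditions with no planted effects (every downstream
    discovery is false by construction).
  * subtyped — two mutually exclusive drivers planting opposite-sign
    effects on disjoint 200-probe panels, defining two subtypes.
"""

import dataclasses
from pathlib import Path

from mutmeth import (
    DriverSpec,
    PlantedEffect,
    default_null_drivers,
    generate_cohort,
    generate_null_cohort,
    write_cohort,
)
from mutmeth.synthetic import SimulationConfig, probe_names

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"
SEED = 11


def main() -> None:
    base = SimulationConfig(driver_genes=default_null_drivers(20, seed=SEED),
                            seed=SEED)
    probes = probe_names(base)

    planted_cfg = dataclasses.replace(
        base,
        driver_genes=(DriverSpec("G000", 0.3),) + base.driver_genes[1:],
        planted_effects=(PlantedEffect("G000", tuple(probes[:50]), 0.3),))
    ds, truth = generate_cohort(planted_cfg)
    write_cohort(ds, truth, OUT / "planted")
    print(f"planted: {ds.beta.values.shape[0]} probes x "
          f"{ds.beta.values.shape[1]} samples; G000 mutated in "
          f"{len(ds.mutations.mutated_samples('G000'))} tumors, "
          f"50 probes shifted by +0.3")

    ds_null, truth_null = generate_null_cohort(planted_cfg)
    write_cohort(ds_null, truth_null, OUT / "null")
    print(f"null: same conditions, planted effect map is empty "
          f"({len(truth_null.effect_map)} entries)")

    cgi = [p for p in probes if p.startswith("cg_cgi")]
    sea = [p for p in probes if p.startswith("cg_sea")]
    sub_cfg = dataclasses.replace(
        base,
        driver_genes=(DriverSpec("GA", 0.5, "sub"),
                      DriverSpec("GB", 0.5, "sub")),
        planted_effects=(PlantedEffect("GA", tuple(cgi[:200]), 0.3),
                         PlantedEffect("GB", tuple(sea[:200]), -0.3)))
    ds_sub, truth_sub = generate_cohort(sub_cfg)
    write_cohort(ds_sub, truth_sub, OUT / "subtyped")
    counts = truth_sub.subtype_labels.value_counts().to_dict()
    print(f"subtyped: planted subtype sizes {counts}")


if __name__ == "__main__":
    main()
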