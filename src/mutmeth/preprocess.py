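"""Probe filtering and tumor-vs-normal aberrant methylation calling.

Filtering removes probes on sex chromosomes, cross-reactive probes,
probes adjacent to SNPs (all injected as annotation flags) and probes
with missing rates at or above a threshold across all samples.  Aberrant
calling compares tumors with matched normals per probe using one-sided
rank-sum tests, one per direction, BH-corrected within each direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import BetaMatrix, ProbeAnnotation, ValidationError
from .stats import bh_qvalues, rank_sum_matrix

#: removal reasons in priority order — a probe matching several is
#: reported under the first
REMOVAL_REASONS = ("sex_chromosome", "cross_reactive", "snp_adjacent",
                   "high_missingness")


@dataclass
class ProbeFilterReport:
    kept: list[str]
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


def filter_probes(beta: BetaMatrix, ann: ProbeAnnotation,
                  missing_threshold: float = 0.9
                  ) -> tuple[BetaMatrix, ProbeFilterReport]:
    """Drop flagged and high-missingness probes; order is preserved.

    Missingness is the fraction of missing cells across all samples
    (tumors and normals jointly); removal is inclusive at the threshold.
    """
    unannotated = set(beta.probe_ids) - set(ann.probe_ids)
    if unannotated:
        raise ValidationError(
            f"probes absent from annotation: {sorted(unannotated)[:5]}")
    flags = ann.table.loc[beta.probe_ids, "flags"]
    missing_frac = beta.values.isna().mean(axis=1)

    removed: dict[str, list[str]] = {r: [] for r in REMOVAL_REASONS}
    kept: list[str] = []
    for probe in beta.probe_ids:
        f = flags[probe]
        if "sex_chromosome" in f:
            removed["sex_chromosome"].append(probe)
        elif "cross_reactive" in f:
            removed["cross_reactive"].append(probe)
        elif "snp_adjacent" in f:
            removed["snp_adjacent"].append(probe)
        elif missing_frac[probe] >= missing_threshold:
            removed["high_missingness"].append(probe)
        else:
            kept.append(probe)
    report = ProbeFilterReport(kept=kept,
                               removed={k: v for k, v in removed.items()})
    return beta.subset_probes(kept), report


@dataclass
class AberrantCallTable:
    """Per-probe hyper/hypo/none calls against matched normals.

    When the cohort has no normal samples the table is explicitly
    uncallable (``callable_`` False, every call ``none``) rather than an
    error, since downstream strata simply skip the hyper/hypo split.
    """

    table: pd.DataFrame  # index probe; p_hyper p_hypo q_hyper q_hypo
                         # median_tumor median_normal call
    alpha: float = 0.05
    callable_: bool = True
    reason: str = ""

    def probes_called(self, call: str) -> list[str]:
        return list(self.table.index[self.table["call"] == call])


def call_aberrant_probes(beta: BetaMatrix, alpha: float = 0.05
                         ) -> AberrantCallTable:
    """One-sided rank-sum tests of tumors vs normals, per direction.

    ``hyper`` requires q_hyper < alpha and a tumor median above the
    normal median; ``hypo`` symmetrically.  The two calls are mutually
    exclusive by construction.
    """
    tumors = beta.tumor_values().to_numpy()
    normals = beta.normal_values().to_numpy()
    probes = beta.probe_ids
    if normals.shape[1] == 0:
        empty = pd.DataFrame({
            "p_hyper": np.nan, "p_hypo": np.nan,
            "q_hyper": np.nan, "q_hypo": np.nan,
            "median_tumor": np.nanmedian(tumors, axis=1) if tumors.size else np.nan,
            "median_normal": np.nan,
            "call": "none",
        }, index=pd.Index(probes, name="probe_id"))
        return AberrantCallTable(empty, alpha=alpha, callable_=False,
                                 reason="no normal samples")

    p_hyper, med_diff = rank_sum_matrix(tumors, normals, "greater")
    p_hypo, _ = rank_sum_matrix(tumors, normals, "less")
    q_hyper = bh_qvalues(p_hyper)
    q_hypo = bh_qvalues(p_hypo)
    med_t = np.nanmedian(tumors, axis=1)
    med_n = np.nanmedian(normals, axis=1)

    call = np.full(len(probes), "none", dtype=object)
    hyper = (q_hyper < alpha) & (med_t > med_n)
    hypo = (q_hypo < alpha) & (med_t < med_n)
    call[hyper] = "hyper"
    call[hypo & ~hyper] = "hypo"

    table = pd.DataFrame({
        "p_hyper": p_hyper, "p_hypo": p_hypo,
        "q_hyper": q_hyper, "q_hypo": q_hypo,
        "median_tumor": med_t, "median_normal": med_n,
        "call": call,
    }, index=pd.Index(probes, name="probe_id"))
    return AberrantCallTable(table, alpha=alpha)
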