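"""Per-sample HyperZ / HypoZ genome-wide methylation-alteration indices.

HyperZ summarizes aberrant CGI hypermethylation: the fraction of
hyper-eligible CGI probes (normally unmethylated, mean normal beta below
``unmeth_cut``) whose z-score against the normal distribution exceeds
``z_cut`` in a tumor sample.  HypoZ symmetrically summarizes open-sea
hypomethylation over probes that are normally methylated (mean normal
beta above ``meth_cut``).  Eligibility restricts scoring to probes where
a shift is genuinely aberrant relative to normals, so a high HyperZ
reads as "hypermethylation exists in many CGIs".  Both indices are
bounded fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationTable, eligible_genes
from .data_model import BetaMatrix, MutationMatrix, ProbeAnnotation, ValidationError
from .stats import bh_qvalues, rank_sum_test


@dataclass
class ZScoreParams:
    """Normal-reference mean/SD per probe plus hyper/hypo eligibility."""

    mu_normal: pd.Series
    sigma_normal: pd.Series  # floored at sigma_floor
    eligibility: pd.Series   # 'hyper_eligible' | 'hypo_eligible' | 'neither'


@dataclass
class SampleIndexTable:
    """HyperZ/HypoZ per tumor sample.

    When fewer than two normals exist the indices are not computable
    (``computable`` False) — mirrored from cohorts lacking normal
    tissue.  Zero eligible probes yields NaN, never a silent 0.
    """

    table: pd.DataFrame  # index sample; columns hyperz, hypoz
    eligible_cgi_count: int = 0
    eligible_opensea_count: int = 0
    computable: bool = True
    reason: str = ""
    params: ZScoreParams | None = None


def compute_zscore_params(beta: BetaMatrix, ann: ProbeAnnotation,
                          unmeth_cut: float = 0.3, meth_cut: float = 0.7,
                          sigma_floor: float = 0.01) -> ZScoreParams:
    normals = beta.normal_values()
    mu = normals.mean(axis=1, skipna=True)
    sigma = normals.std(axis=1, ddof=1, skipna=True).fillna(0.0)
    sigma = sigma.clip(lower=sigma_floor)
    subset = ann.table.loc[beta.probe_ids, "cpg_subset"]
    elig = pd.Series("neither", index=beta.probe_ids, dtype=object)
    elig[(subset == "CGI") & (mu < unmeth_cut)] = "hyper_eligible"
    elig[(subset == "open_sea") & (mu > meth_cut)] = "hypo_eligible"
    return ZScoreParams(mu_normal=mu, sigma_normal=sigma, eligibility=elig)


def compute_hyperz_hypoz(beta: BetaMatrix, ann: ProbeAnnotation,
                         z_cut: float = 2.0, unmeth_cut: float = 0.3,
                         meth_cut: float = 0.7, sigma_floor: float = 0.01
                         ) -> SampleIndexTable:
    """Outlier-fraction HyperZ/HypoZ per tumor sample.

    ``z = (beta - mu_normal) / max(sigma_normal, floor)`` per probe;
    HyperZ is the fraction of hyper-eligible CGI probes with z > z_cut,
    HypoZ the fraction of hypo-eligible open-sea probes with z < -z_cut.
    """
    tumors = beta.tumor_samples
    if len(beta.normal_samples) < 2:
        empty = pd.DataFrame(
            {"hyperz": np.nan, "hypoz": np.nan},
            index=pd.Index(tumors, name="sample_id"))
        return SampleIndexTable(empty, computable=False,
                                reason="fewer than 2 normal samples")
    params = compute_zscore_params(beta, ann, unmeth_cut, meth_cut, sigma_floor)
    t = beta.values[tumors]
    z = t.sub(params.mu_normal, axis=0).div(params.sigma_normal, axis=0)

    hyper_probes = params.eligibility.index[params.eligibility == "hyper_eligible"]
    hypo_probes = params.eligibility.index[params.eligibility == "hypo_eligible"]

    def _fraction(zs: pd.DataFrame, exceed: pd.DataFrame) -> pd.Series:
        # NaN betas drop out of both numerator and denominator
        valid = zs.notna().sum(axis=0)
        frac = exceed.sum(axis=0) / valid
        return frac.where(valid > 0, np.nan)

    z_hyper = z.loc[hyper_probes]
    z_hypo = z.loc[hypo_probes]
    hyperz = _fraction(z_hyper, z_hyper > z_cut) if len(hyper_probes) else \
        pd.Series(np.nan, index=tumors)
    hypoz = _fraction(z_hypo, z_hypo < -z_cut) if len(hypo_probes) else \
        pd.Series(np.nan, index=tumors)

    table = pd.DataFrame({"hyperz": hyperz, "hypoz": hypoz},
                         index=pd.Index(tumors, name="sample_id"))
    return SampleIndexTable(table,
                            eligible_cgi_count=len(hyper_probes),
                            eligible_opensea_count=len(hypo_probes),
                            params=params)


def associate_genes_with_index(idx: SampleIndexTable, mut: MutationMatrix,
                               which: str = "hyperz", min_mutated: int = 5,
                               alpha: float = 0.05) -> AssociationTable:
    """Two-sided rank-sum of the index between mutated and non-mutated
    tumors, BH across genes."""
    if which not in ("hyperz", "hypoz"):
        raise ValidationError(f"unknown index {which!r}")
    if not idx.computable:
        raise ValidationError(f"index not computable: {idx.reason}")
    values = idx.table[which].dropna()
    samples = [s for s in values.index if s in mut.status.columns]
    genes = eligible_genes(mut, samples, min_mutated)
    rows = []
    for gene in genes:
        carriers = set(mut.mutated_samples(gene))
        is_mut = np.array([s in carriers for s in samples])
        v = values.loc[samples].to_numpy()
        res = rank_sum_test(v[is_mut], v[~is_mut])
        rows.append((gene, which, res.p_value, res.direction, res.effect,
                     int(is_mut.sum()), int((~is_mut).sum())))
    records = pd.DataFrame(rows, columns=["gene", "target", "p", "direction",
                                          "effect", "n_mut", "n_non"])
    records["q"] = bh_qvalues(records["p"].to_numpy()) if len(records) else \
        pd.Series(dtype=float)
    records = records[list(AssociationTable.COLUMNS)]
    return AssociationTable(records, alpha=alpha, family=f"gene_x_{which}")
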