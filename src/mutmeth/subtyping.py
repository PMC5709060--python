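"""Mutation-anchored methylation subtype discovery.

Tumors are clustered hierarchically (Ward linkage on Euclidean
distances by default) over a probe panel: either the union of the top-k
probes most significantly associated with each of a few dominant driver
genes, or the top fraction of most-variable probes.  Both panels should
recover the same partition when planted effects dominate the variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .data_model import BetaMatrix, ValidationError
from .site_assoc import SiteAssociationTable


@dataclass
class SubtypeAssignment:
    labels: pd.Series             # sample -> cluster label (1..k)
    linkage_matrix: np.ndarray    # scipy merge tree with heights
    probe_panel: list[str]
    method: dict = field(default_factory=dict)


def select_top_associated_probes(table: SiteAssociationTable,
                                 genes: list[str], k: int = 500) -> list[str]:
    """Union over genes of each gene's k most significant probes.

    Per gene, probes are ranked by smallest p, ties broken by larger
    |median_diff| then probe id; a gene with fewer than k associated
    probes contributes them all (with a warning).  The union is
    deduplicated and returned sorted for determinism.
    """
    sig = table.significant()
    panel: set[str] = set()
    for gene in genes:
        grp = sig[sig["gene"] == gene]
        if grp.empty:
            raise ValidationError(f"no associated probes for gene {gene!r}")
        if len(grp) < k:
            warnings.warn(
                f"gene {gene!r} has only {len(grp)} associated probes "
                f"(< {k}); taking all", stacklevel=2)
        ranked = grp.assign(abs_diff=grp["median_diff"].abs()).sort_values(
            ["p", "abs_diff", "probe"], ascending=[True, False, True])
        panel |= set(ranked["probe"].head(k))
    return sorted(panel)


def select_top_variance_probes(beta: BetaMatrix,
                               fraction: float = 0.01) -> list[str]:
    """Top ceil(fraction x n_probes) probes by variance across tumors;
    ties broken by probe id for determinism."""
    tumors = beta.tumor_values()
    if tumors.shape[1] < 2:
        raise ValidationError("need >= 2 tumor samples for variance ranking")
    var = tumors.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    n_top = math.ceil(fraction * len(var))
    # stable sort over an id-sorted index: equal variances break by probe id
    order = var.loc[sorted(var.index)].sort_values(
        ascending=False, kind="mergesort")
    return list(order.index[:n_top])


def cluster_samples(beta: BetaMatrix, probes: list[str], k_clusters: int = 2,
                    method: str = "ward", metric: str = "euclidean"
                    ) -> SubtypeAssignment:
    """Agglomerative clustering of tumors on the probe panel.

    Missing betas are mean-imputed per probe before distances; the panel
    is sorted by probe id so the result is invariant to panel order.
    ``(method='average', metric='correlation')`` gives the
    1 - Pearson alternative.
    """
    tumors = beta.tumor_samples
    if k_clusters < 1:
        raise ValidationError("k_clusters must be >= 1")
    if k_clusters > len(tumors):
        raise ValidationError(
            f"k_clusters={k_clusters} exceeds {len(tumors)} tumor samples")
    panel = sorted(dict.fromkeys(probes))
    missing = set(panel) - set(beta.probe_ids)
    if missing:
        raise ValidationError(f"panel probes not in matrix: {sorted(missing)[:5]}")
    x = beta.values.loc[panel, tumors].to_numpy().T  # samples x probes
    if np.isnan(x).any():
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = np.where(np.isfinite(col_mean), col_mean, 0.0)[idx[1]]
    if k_clusters == 1:
        labels = pd.Series(1, index=tumors)
        lm = linkage(pdist(x, metric=metric), method=method) \
            if len(tumors) > 1 else np.empty((0, 4))
        return SubtypeAssignment(labels, lm, panel,
                                 {"method": method, "metric": metric, "k": 1})
    lm = linkage(pdist(x, metric=metric), method=method)
    flat = fcluster(lm, t=k_clusters, criterion="maxclust")
    labels = pd.Series(flat, index=tumors)
    return SubtypeAssignment(labels, lm, panel,
                             {"method": method, "metric": metric,
                              "k": k_clusters})
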