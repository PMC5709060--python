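"""Methylome PCA and driver-gene-to-PC association.

Tumor samples are projected onto the top principal components of the
(optionally stratified) beta matrix; a driver gene is associated with a
PC when its mutated samples sit unevenly toward one extreme of that
component (two-sided rank-sum on the PC coordinates, BH over all
gene x PC tests of the cohort).  Also provides per-sample feature-list
indices (mean beta over an epiTOC-style CpG list, or mean expression
over a mitotic gene list) and the decorrelate-and-reassociate variant
that removes index-correlated probes before refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .association import AssociationTable, eligible_genes
from .data_model import BetaMatrix, ExpressionMatrix, MutationMatrix, ValidationError
from .stats import bh_qvalues, rank_sum_test


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of one stratum.

    Components are ordered by non-increasing explained variance.  Signs
    are fixed so each component's largest-magnitude loading is positive,
    making the +/- extreme labels reproducible across runs.
    """

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # probes x components
    explained_variance: np.ndarray
    probe_subset_label: str = "all"

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _impute_probe_means(x: np.ndarray) -> np.ndarray:
    """Column-wise (per-probe) mean imputation of missing cells."""
    if not np.isnan(x).any():
        return x
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(np.isnan(x))
    x = x.copy()
    x[idx] = col_mean[idx[1]]
    return x


def fit_methylation_pca(beta: BetaMatrix, n_components: int = 5,
                        stratum: list[str] | None = None,
                        label: str = "all") -> PcaResult:
    """PCA of tumor samples on the given probe stratum.

    Probes are centered but not scaled (betas share one scale); missing
    cells are mean-imputed per probe before the fit.
    """
    probes = beta.probe_ids if stratum is None else list(stratum)
    if len(probes) < n_components:
        raise ValidationError(
            f"stratum of {len(probes)} probes < {n_components} components")
    tumors = beta.tumor_samples
    if len(tumors) < n_components + 1:
        raise ValidationError("not enough tumor samples for the requested PCs")
    x = beta.values.loc[probes, tumors].to_numpy().T  # samples x probes
    x = _impute_probe_means(x)
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValidationError("zero variance across all probes in stratum")

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # probes x components

    # sign convention: largest |loading| per component is positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=tumors, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=probes, columns=comp_names),
        explained_variance=pca.explained_variance_ratio_.copy(),
        probe_subset_label=label,
    )


def associate_genes_with_pcs(pca: PcaResult, mut: MutationMatrix,
                             min_mutated: int = 5, alpha: float = 0.05
                             ) -> AssociationTable:
    """Two-sided rank-sum of mutated vs non-mutated PC coordinates.

    The BH family is all gene x PC tests of the cohort; a positive
    direction means mutated samples sit toward the positive extreme.
    """
    samples = [s for s in pca.scores.index if s in mut.status.columns]
    genes = eligible_genes(mut, samples, min_mutated)
    rows = []
    for gene in genes:
        carriers = set(mut.mutated_samples(gene))
        is_mut = np.array([s in carriers for s in samples])
        for comp in pca.scores.columns:
            coord = pca.scores.loc[samples, comp].to_numpy()
            res = rank_sum_test(coord[is_mut], coord[~is_mut])
            rows.append((gene, comp, res.p_value, res.direction, res.effect,
                         int(is_mut.sum()), int((~is_mut).sum())))
    records = pd.DataFrame(rows, columns=["gene", "target", "p", "direction",
                                          "effect", "n_mut", "n_non"])
    if records.empty:
        import warnings
        warnings.warn("no eligible genes for PC association", stacklevel=2)
        records["q"] = pd.Series(dtype=float)
    else:
        records["q"] = bh_qvalues(records["p"].to_numpy())
    records = records[list(AssociationTable.COLUMNS)]
    return AssociationTable(records, alpha=alpha,
                            family=f"gene_x_pc[{pca.probe_subset_label}]")


@dataclass
class FeatureIndex:
    """Per-sample arithmetic mean over a fixed feature list."""

    values: pd.Series  # sample -> index value
    feature_list: list[str]
    kind: str = "dnam_mitotic"


def compute_feature_index(matrix: BetaMatrix | ExpressionMatrix,
                          feature_list: list[str],
                          kind: str = "dnam_mitotic") -> FeatureIndex:
    """Mean of the listed features (rows) per sample, ignoring missing
    cells and absent features."""
    df = matrix.values
    present = [f for f in feature_list if f in df.index]
    if not present:
        raise ValidationError("none of the listed features are present")
    values = df.loc[present].mean(axis=0, skipna=True)
    return FeatureIndex(values=values, feature_list=present, kind=kind)


def _pearson_p_vs_index(x: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Vectorized Pearson p-value of each row of ``x`` against ``index``."""
    n = index.size
    xm = x - x.mean(axis=1, keepdims=True)
    im = index - index.mean()
    denom = np.sqrt((xm ** 2).sum(axis=1) * (im ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ im) / denom
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(p), p, 1.0)  # constant probes carry no signal
    return p


def decorrelate_and_reassociate(beta: BetaMatrix, mut: MutationMatrix,
                                index: FeatureIndex, p_cut: float = 0.05,
                                n_components: int = 5, min_mutated: int = 5,
                                alpha: float = 0.05
                                ) -> tuple[PcaResult, AssociationTable]:
    """Drop probes Pearson-correlated with the index (p < p_cut across
    tumors), refit the PCA and re-run the gene-PC association."""
    tumors = [s for s in beta.tumor_samples if s in index.values.index]
    x = beta.values[tumors].to_numpy()
    x = _impute_probe_means(x.T).T
    p = _pearson_p_vs_index(x, index.values.loc[tumors].to_numpy())
    keep = [probe for probe, pv in zip(beta.probe_ids, p) if pv >= p_cut]
    if not keep:
        raise ValidationError("decorrelation removed every probe")
    pca = fit_methylation_pca(beta, n_components=n_components, stratum=keep,
                              label="index_decorrelated")
    assoc = associate_genes_with_pcs(pca, mut, min_mutated=min_mutated,
                                     alpha=alpha)
    return pca, assoc
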