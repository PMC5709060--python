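"""Exhaustive driver-gene x probe association scan.

Every eligible driver gene (>= min_mutated mutated tumors) is tested
against every probe with a two-sided rank-sum comparison of beta values
between mutated and non-mutated tumors.  Benjamini-Hochberg correction
is applied over ALL gene x probe tests of the cohort jointly.  The
module also provides the permutation-based empirical FDR estimate (each
gene's mutation labels shuffled independently, scan re-run), dominance
summaries (which genes account for the bulk of associations, split by
direction and CpG subset), cross-cohort probe sharing, and the
single-gene re-correction variant whose BH family is one gene's probe
tests only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import eligible_genes
from .data_model import (
    BetaMatrix,
    MutationMatrix,
    ProbeAnnotation,
    ValidationError,
)
from .preprocess import AberrantCallTable
from .stats import bh_qvalues, rank_sum_matrix

#: a gene accounting for more than this fraction of all associated
#: probes in a cohort is flagged dominant
DOMINANCE_THRESHOLD = 0.1


@dataclass
class SiteAssociationTable:
    """All gene x probe test records of one cohort.

    ``q`` is BH over every record in the table (one family per cohort,
    or one gene's probes for the single-gene variant — see ``family``).
    ``significant()`` gives the discovery set at the stored alpha.
    """

    records: pd.DataFrame  # gene, probe, p, q, direction, median_diff
                           # [, cpg_subset]
    alpha: float = 0.05
    min_mutated: int = 5
    family: str = "all_pairs"

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.records[self.records["q"] < a]

    def n_discoveries(self, alpha: float | None = None) -> int:
        return len(self.significant(alpha))

    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.records["gene"]))


def _scan_genes(beta: BetaMatrix, mut: MutationMatrix, genes: list[str],
                samples: list[str], max_missing_frac: float = 0.5
                ) -> pd.DataFrame:
    """Vectorized per-gene scans; probes missing in more than
    ``max_missing_frac`` of either group are skipped for that pair."""
    values = beta.values[samples]
    x = values.to_numpy()
    probes = np.array(beta.probe_ids)
    frames = []
    for gene in genes:
        carriers = set(mut.mutated_samples(gene))
        is_mut = np.array([s in carriers for s in samples])
        xm, xn = x[:, is_mut], x[:, ~is_mut]
        ok = (np.isnan(xm).mean(axis=1) <= max_missing_frac) & \
             (np.isnan(xn).mean(axis=1) <= max_missing_frac)
        p, med_diff = rank_sum_matrix(xm[ok], xn[ok])
        frames.append(pd.DataFrame({
            "gene": gene,
            "probe": probes[ok],
            "p": p,
            "direction": np.sign(med_diff).astype(int),
            "median_diff": med_diff,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "probe", "p", "direction", "median_diff"])


def associate_genes_with_probes(beta: BetaMatrix, mut: MutationMatrix,
                                ann: ProbeAnnotation | None = None,
                                min_mutated: int = 5, alpha: float = 0.05
                                ) -> SiteAssociationTable:
    """The full scan: one BH family over all gene x probe tests."""
    samples = [s for s in beta.tumor_samples if s in mut.status.columns]
    if not samples:
        raise ValidationError("no shared tumor samples between beta and mutations")
    genes = eligible_genes(mut, samples, min_mutated)
    records = _scan_genes(beta, mut, genes, samples)
    records["q"] = bh_qvalues(records["p"].to_numpy()) if len(records) else \
        pd.Series(dtype=float)
    if ann is not None:
        records["cpg_subset"] = ann.table.loc[records["probe"],
                                              "cpg_subset"].to_numpy() \
            if len(records) else pd.Series(dtype=object)
    return SiteAssociationTable(records, alpha=alpha, min_mutated=min_mutated)


def reassociate_single_gene(beta: BetaMatrix, mut: MutationMatrix, gene: str,
                            ann: ProbeAnnotation | None = None,
                            min_mutated: int = 5, alpha: float = 0.05
                            ) -> SiteAssociationTable:
    """Scan with the BH family restricted to one gene's probe tests.

    The smaller family can only make q-values smaller, so this recovers
    at least the probes the joint scan found for the gene.
    """
    samples = [s for s in beta.tumor_samples if s in mut.status.columns]
    if gene not in eligible_genes(mut, samples, min_mutated, warn=False):
        raise ValidationError(
            f"gene {gene!r} is not eligible (needs >= {min_mutated} mutated "
            "and >= 1 non-mutated sample)")
    records = _scan_genes(beta, mut, [gene], samples)
    records["q"] = bh_qvalues(records["p"].to_numpy())
    if ann is not None:
        records["cpg_subset"] = ann.table.loc[records["probe"],
                                              "cpg_subset"].to_numpy()
    return SiteAssociationTable(records, alpha=alpha, min_mutated=min_mutated,
                                family=f"single_gene[{gene}]")


@dataclass
class EmpiricalFdrEstimate:
    """Permutation estimate of the realized FDR at a nominal q cutoff.

    ``empirical_fdr = mean_null_discoveries / max(n_observed, 1)``,
    capped at 1.
    """

    nominal_q: float
    n_observed: int
    mean_null_discoveries: float
    empirical_fdr: float
    n_permutations: int


def estimate_empirical_fdr(beta: BetaMatrix, mut: MutationMatrix,
                           alpha: float = 0.05, n_permutations: int = 10,
                           seed: int = 0, min_mutated: int = 5,
                           mode: str = "per_gene") -> EmpiricalFdrEstimate:
    """Re-run the full scan on label-permuted cohorts.

    ``per_gene`` shuffles each gene's mutation labels independently
    across samples (preserving per-gene mutation counts, breaking any
    gene-probe linkage); ``joint`` applies one sample permutation to all
    genes, preserving co-mutation structure.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if mode not in ("per_gene", "joint"):
        raise ValidationError(f"unknown permutation mode {mode!r}")
    observed = associate_genes_with_probes(beta, mut, min_mutated=min_mutated,
                                           alpha=alpha)
    n_obs = observed.n_discoveries()
    rng = np.random.default_rng(seed)
    samples = [s for s in beta.tumor_samples if s in mut.status.columns]
    sub = mut.status[samples]
    null_counts = []
    for _ in range(n_permutations):
        if mode == "per_gene":
            perm = np.vstack([rng.permutation(row) for row in sub.to_numpy()])
        else:
            perm = sub.to_numpy()[:, rng.permutation(sub.shape[1])]
        mut_perm = MutationMatrix(pd.DataFrame(perm, index=sub.index,
                                               columns=sub.columns))
        null = associate_genes_with_probes(beta, mut_perm,
                                           min_mutated=min_mutated,
                                           alpha=alpha)
        null_counts.append(null.n_discoveries())
    mean_null = float(np.mean(null_counts))
    fdr = min(1.0, mean_null / max(n_obs, 1))
    return EmpiricalFdrEstimate(nominal_q=alpha, n_observed=n_obs,
                                mean_null_discoveries=mean_null,
                                empirical_fdr=fdr,
                                n_permutations=n_permutations)


@dataclass
class DominanceSummary:
    """Which genes account for the associated probes, and how the
    associations split by direction, CpG subset and aberrant status.

    ``frac_of_total`` divides by the number of unique probes associated
    with any gene, so genes sharing probes can sum above 1.
    """

    per_gene: pd.DataFrame  # index gene; n_assoc, frac_of_total, dominant,
                            # per (direction x subset) counts,
                            # pos_and_hyper, neg_and_hypo
    n_total_probes: int = 0
    dominance_threshold: float = DOMINANCE_THRESHOLD


def summarize_dominance(table: SiteAssociationTable,
                        aberrant: AberrantCallTable | None = None,
                        dominance_threshold: float = DOMINANCE_THRESHOLD
                        ) -> DominanceSummary:
    sig = table.significant()
    if sig.empty:
        return DominanceSummary(pd.DataFrame(), 0, dominance_threshold)
    n_total = sig["probe"].nunique()
    rows = {}
    for gene, grp in sig.groupby("gene", sort=False):
        row = {"n_assoc": len(grp),
               "frac_of_total": grp["probe"].nunique() / n_total}
        row["dominant"] = row["frac_of_total"] > dominance_threshold
        if "cpg_subset" in grp.columns:
            for subset in ("CGI", "SS", "open_sea"):
                for d, tag in ((1, "pos"), (-1, "neg")):
                    row[f"{tag}_{subset}"] = int(
                        ((grp["cpg_subset"] == subset)
                         & (grp["direction"] == d)).sum())
        if aberrant is not None and aberrant.callable_:
            call = aberrant.table.loc[grp["probe"], "call"].to_numpy()
            row["pos_and_hyper"] = int(((grp["direction"] == 1)
                                        & (call == "hyper")).sum())
            row["neg_and_hypo"] = int(((grp["direction"] == -1)
                                       & (call == "hypo")).sum())
        rows[gene] = row
    per_gene = pd.DataFrame.from_dict(rows, orient="index")
    per_gene.index.name = "gene"
    return DominanceSummary(per_gene, n_total, dominance_threshold)


def count_shared_probes(tables: list[SiteAssociationTable], gene: str,
                        direction: int) -> dict[int, int]:
    """For k = 1..K cohorts: how many probes are associated with ``gene``
    in the stated direction in at least k cohorts."""
    if len(tables) < 2:
        raise ValidationError("need at least 2 cohort tables")
    per_cohort = []
    for t in tables:
        sig = t.significant()
        hit = sig[(sig["gene"] == gene) & (sig["direction"] == direction)]
        per_cohort.append(set(hit["probe"]))
    counts = pd.Series(
        [p for s in per_cohort for p in s]).value_counts() \
        if any(per_cohort) else pd.Series(dtype=int)
    if counts.empty:
        return {}
    return {k: int((counts >= k).sum()) for k in range(1, len(tables) + 1)}
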