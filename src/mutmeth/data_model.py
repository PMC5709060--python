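"""Domain containers and TSV/GMT readers-writers.

All tabular formats are UTF-8 tab-separated text with a header row and
the probe/gene identifier in the first column.  Missing methylation
values are written as ``NA`` and kept as NaN internally — they are never
silently zero.  Loading preserves file order of probes, genes and
samples so downstream stages are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CPG_SUBSETS = ("CGI", "SS", "open_sea")
LINK_REGIONS = ("promoter", "body", "none")
PROBE_FLAGS = ("sex_chromosome", "cross_reactive", "snp_adjacent")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Methylation beta values (probes x samples) with tumor/normal labels."""

    values: pd.DataFrame  # probes x samples, float, NaN = missing
    sample_group: pd.Series  # sample -> 'tumor' | 'normal'

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "probe_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        self.sample_group = self.sample_group.reindex(self.values.columns)
        if self.sample_group.isna().any():
            missing = self.sample_group.index[self.sample_group.isna()].tolist()
            raise ValidationError(f"samples without group label: {missing[:5]}")
        bad = ~self.sample_group.isin(["tumor", "normal"])
        if bad.any():
            raise ValidationError(
                f"unknown sample group: {self.sample_group[bad].unique().tolist()}"
            )
        vals = self.values.to_numpy()
        out = (vals < 0) | (vals > 1)
        if np.any(out & np.isfinite(vals)):
            i, j = np.argwhere(out & np.isfinite(vals))[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if not (self.sample_group == "tumor").any():
            raise ValidationError("need at least one tumor sample")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == "tumor"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == "normal"])

    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]

    def normal_values(self) -> pd.DataFrame:
        return self.values[self.normal_samples]

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probes)], self.sample_group.copy())


@dataclass
class MutationMatrix:
    """Binary driver-gene mutation status (genes x samples)."""

    status: pd.DataFrame  # genes x samples, values in {0, 1}

    def __post_init__(self) -> None:
        _check_unique(self.status.index, "gene ids")
        _check_unique(self.status.columns, "sample ids")
        vals = self.status.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation status must be binary 0/1")
        self.status = self.status.astype(np.int8)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.status.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.columns)

    def mutated_samples(self, gene: str) -> list[str]:
        row = self.status.loc[gene]
        return list(row.index[row == 1])


@dataclass
class ExpressionMatrix:
    """Gene expression (genes x samples), log2 RSEM scale."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Per-probe location, CpG subset, gene linkage and exclusion flags.

    ``cpg_subset`` is the three-way stratification CGI / SS (shores and
    shelves, pre-collapsed) / open_sea.  ``flags`` holds exclusion
    markers (sex_chromosome, cross_reactive, snp_adjacent) as a
    semicolon-joined field in TSV form.
    """

    table: pd.DataFrame  # index probe_id

    REQUIRED = ("chromosome", "position", "cpg_subset", "linked_gene",
                "link_region", "flags")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        _check_unique(self.table.index, "probe ids")
        bad = ~self.table["cpg_subset"].isin(CPG_SUBSETS)
        if bad.any():
            raise ValidationError(
                "unknown cpg_subset label(s): "
                f"{sorted(self.table.loc[bad, 'cpg_subset'].unique())} "
                f"(expected one of {list(CPG_SUBSETS)})"
            )
        bad = ~self.table["link_region"].isin(LINK_REGIONS)
        if bad.any():
            raise ValidationError(
                f"unknown link_region: {sorted(self.table.loc[bad, 'link_region'].unique())}"
            )
        self.table["flags"] = self.table["flags"].map(_normalize_flags)
        unknown = set().union(*self.table["flags"]) - set(PROBE_FLAGS)
        if unknown:
            raise ValidationError(f"unknown probe flags: {sorted(unknown)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def flagged(self, flag: str) -> list[str]:
        return list(self.table.index[self.table["flags"].map(lambda f: flag in f)])

    def probes_in_subset(self, subset: str) -> list[str]:
        if subset not in CPG_SUBSETS:
            raise ValidationError(f"unknown cpg_subset {subset!r}")
        return list(self.table.index[self.table["cpg_subset"] == subset])


def _normalize_flags(raw) -> frozenset:
    if isinstance(raw, frozenset):
        return raw
    if isinstance(raw, (set, list, tuple)):
        return frozenset(raw)
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    s = str(raw).strip()
    if not s:
        return frozenset()
    return frozenset(part for part in s.split(";") if part)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class CohortDataset:
    """One cohort's matrices plus its driver-gene list."""

    beta: BetaMatrix
    mutations: MutationMatrix
    annotation: ProbeAnnotation
    driver_genes: pd.Series  # gene -> mutated sample count
    expression: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        tumors = set(self.beta.tumor_samples)
        if not set(self.mutations.sample_ids) <= set(self.beta.sample_ids):
            raise ValidationError("mutation samples not contained in beta samples")
        if not set(self.mutations.sample_ids) <= tumors:
            raise ValidationError("mutation matrix contains non-tumor samples")
        if not set(self.driver_genes.index) <= set(self.mutations.gene_ids):
            raise ValidationError("driver gene absent from mutation matrix")
        if not set(self.beta.probe_ids) <= set(self.annotation.probe_ids):
            raise ValidationError("beta probes missing from annotation")


# ---------------------------------------------------------------------------
# readers / writers


def load_beta_matrix(path: str | Path, groups_path: str | Path) -> BetaMatrix:
    """Load a probes x samples beta TSV plus a (sample, group) file."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    values = df.apply(lambda col: pd.to_numeric(col.replace("NA", np.nan)))
    groups = _load_groups(groups_path)
    return BetaMatrix(values, groups)


def _load_groups(groups_path: str | Path) -> pd.Series:
    g = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(g.columns[:2]) != ["sample_id", "group"]:
        raise ValidationError(
            "groups file must have columns sample_id, group "
            f"(got {list(g.columns)})"
        )
    return pd.Series(g["group"].values, index=g["sample_id"].values)


def write_beta_matrix(beta: BetaMatrix, path: str | Path,
                      groups_path: str | Path | None = None) -> None:
    beta.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")
    if groups_path is not None:
        pd.DataFrame({"sample_id": beta.sample_ids,
                      "group": beta.sample_group.values}
                     ).to_csv(groups_path, sep="\t", index=False)


def load_mutations(path: str | Path, mode: str = "binary",
                   samples: Sequence[str] | None = None) -> MutationMatrix:
    """Load mutation calls.

    ``binary`` mode reads a gene x sample 0/1 TSV.  ``records`` mode
    reads per-mutation rows (columns ``gene``, ``sample``, optionally a
    variant class, which is ignored) and collapses them to gene-level
    presence/absence; ``samples`` supplies the cohort's full sample
    universe so unmutated samples appear as zero columns.
    """
    if mode == "binary":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return MutationMatrix(df)
    if mode == "records":
        rec = pd.read_csv(path, sep="\t", dtype=str)
        if "gene" not in rec.columns or "sample" not in rec.columns:
            raise ValidationError("records file needs 'gene' and 'sample' columns")
        genes = list(dict.fromkeys(rec["gene"]))
        cols = list(samples) if samples is not None else list(dict.fromkeys(rec["sample"]))
        status = pd.DataFrame(0, index=genes, columns=cols, dtype=np.int8)
        for gene, sample in zip(rec["gene"], rec["sample"]):
            if sample not in status.columns:
                raise ValidationError(
                    f"mutation record for unknown sample {sample!r}")
            status.loc[gene, sample] = 1
        return MutationMatrix(status)
    raise ValidationError(f"unknown mutation file mode {mode!r}")


def write_mutations(mut: MutationMatrix, path: str | Path) -> None:
    mut.status.to_csv(path, sep="\t", index_label="gene_id")


def load_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    df["position"] = pd.to_numeric(df["position"]).astype(int)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    out = ann.table.copy()
    out["flags"] = out["flags"].map(lambda f: ";".join(sorted(f)))
    out.to_csv(path, sep="\t", index_label="probe_id")


def load_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = df.select_dtypes(exclude="number").columns.tolist()
    if non_numeric:
        raise ValidationError(f"non-numeric expression columns: {non_numeric}")
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = parts
            members = list(dict.fromkeys(m for m in members if m))
            if name in sets:
                raise ValidationError(f"GMT line {lineno}: duplicate set {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
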