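"""Shared association-result container and gene-eligibility helper."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .data_model import MutationMatrix


@dataclass
class AssociationTable:
    """Per (gene, target) test records.

    ``direction`` is +1 when the mutated group sits higher on the tested
    variable (PC score, index, or probe beta), -1 when lower; ``effect``
    is the median difference in the variable's units.  ``q`` is BH over
    the family recorded in ``family`` (e.g. all gene x PC tests of the
    cohort).
    """

    records: pd.DataFrame  # gene, target, p, q, direction, effect, n_mut, n_non
    alpha: float = 0.05
    family: str = ""

    COLUMNS = ("gene", "target", "p", "q", "direction", "effect",
               "n_mut", "n_non")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.records.columns:
                raise ValueError(f"association table missing column {col!r}")

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.records[self.records["q"] < a]

    def __len__(self) -> int:
        return len(self.records)


def eligible_genes(mut: MutationMatrix, samples: list[str],
                   min_mutated: int = 5, warn: bool = True) -> list[str]:
    """Genes testable on ``samples``: at least ``min_mutated`` mutated
    samples and at least one non-mutated sample."""
    sub = mut.status[[s for s in samples if s in mut.status.columns]]
    n_mut = sub.sum(axis=1)
    keep = [g for g in sub.index
            if n_mut[g] >= min_mutated and n_mut[g] < sub.shape[1]]
    skipped_full = [g for g in sub.index if n_mut[g] == sub.shape[1]]
    if skipped_full and warn:
        warnings.warn(
            f"genes mutated in every sample skipped: {skipped_full}",
            stacklevel=2)
    return keep
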