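"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical reserve labels
RESERVE = "reserve"
LOSS_RESERVE = "loss_reserve"
NOT_EVALUABLE = "not_evaluable"

#: canonical severity groups, ordered by disease progression
SEVERITY_ORDER = ("control", "incipient", "moderate", "severe")

#: phenotype columns recognised by the readers
PHENOTYPE_COLUMNS = ("mmse", "braak", "nft", "age", "sex", "pmi",
                     "diagnosis_group", "reserve_label")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``values`` is a DataFrame whose index holds gene identifiers and whose
    columns hold sample identifiers.  ``normalized`` records whether rows
    have been z-scored (mean 0, unit sample standard deviation per gene).
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in genes: {bad[:10]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ModulePartition:
    """Gene -> module assignment.

    ``labels`` maps every clustered gene to an integer module label; label 0
    is the unassigned ("grey") pool.  Non-grey labels are 1..K ordered by
    decreasing module size.
    """

    labels: pd.Series
    min_module_size: int = 2
    sizes: dict = field(init=False)

    def __post_init__(self) -> None:
        counts = self.labels.value_counts()
        self.sizes = {int(k): int(v) for k, v in counts.items()}
        for lab, size in self.sizes.items():
            if lab != 0 and size < self.min_module_size:
                raise ValueError(
                    f"module {lab} has {size} genes < min_module_size={self.min_module_size}"
                )

    @property
    def module_labels(self) -> list[int]:
        """Non-grey labels, ascending (1..K, largest module first)."""
        return sorted(lab for lab in self.sizes if lab != 0)

    def genes_in(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Range-check a phenotype table (samples in the index)."""
    if "mmse" in pheno:
        bad = pheno.index[(pheno["mmse"] < 0) | (pheno["mmse"] > 30)].tolist()
        if bad:
            raise ValueError(f"mmse outside [0, 30] for samples: {bad}")
    if "braak" in pheno:
        bad = pheno.index[(pheno["braak"] < 0) | (pheno["braak"] > 6)].tolist()
        if bad:
            raise ValueError(f"braak outside [0, 6] for samples: {bad}")
    if "nft" in pheno:
        bad = pheno.index[pheno["nft"] < 0].tolist()
        if bad:
            raise ValueError(f"negative nft for samples: {bad}")
    return pheno
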