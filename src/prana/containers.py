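"""Lightweight labelled-array containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "AssociationMatrix",
    "ConnectivityVector",
    "PseudoValueMatrix",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")


@dataclass
class ExpressionMatrix:
    """n samples x p genes of nonnegative expression values (counts or normalized).

    Rows are samples, columns are genes. No missing entries are allowed; MI
    estimation additionally requires n >= 3 and p >= 2.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(map(str, self.sample_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise ValueError("id lengths do not match value dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing entries)")
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.gene_ids, "gene_ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            self.gene_ids,
        )


@dataclass
class AssociationMatrix:
    """p x p symmetric nonnegative mutual-information matrix with zero diagonal."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.gene_ids)
        if self.values.shape != (p, p):
            raise ValueError("association matrix must be square and match gene_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("association matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("association matrix entries must be nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class ConnectivityVector:
    """Per-gene total connectivity: column sums of an association matrix."""

    theta: np.ndarray
    gene_ids: list[str]
    group_label: object = None


@dataclass
class PseudoValueMatrix:
    """n x p leave-one-out jackknife pseudo-values, computed within groups.

    Row i is derived only from the samples sharing ``group_of_sample[i]``.
    Pseudo-values may be negative even though connectivities are nonnegative.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    group_of_sample: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.group_of_sample is not None:
            self.group_of_sample = np.asarray(self.group_of_sample)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        if self.group_of_sample is not None:
            df.insert(0, "group", self.group_of_sample)
        return df
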