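"""Core in-memory containers: expression matrix, trait table, gene sets.

All downstream analysis operates on an :class:`ExpressionMatrix` (genes in
rows, samples in columns, values already normalized / on a log scale) aligned
with a :class:`TraitTable` carrying a binary trait (e.g. sex coded 0/1) and a
categorical stage per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "TraitTable", "GeneSet", "KeyGeneList"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(map(str, dups))}")


class ExpressionMatrix:
    """Genes x samples numeric matrix with unique string identifiers.

    Values are assumed normalized (log intensities or log-CPM); no transform
    is applied internally. All values must be finite.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        _check_unique(data.index, "gene")
        _check_unique(data.columns, "sample")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        self._data = data.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes]
        missing = set(genes) - set(self._data.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:10]}")
        # preserve matrix row order, not the order of the query
        keep = self._data.index.isin(set(genes))
        return ExpressionMatrix(self._data.loc[keep])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [s for s in samples]
        missing = set(samples) - set(self._data.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:10]}")
        return ExpressionMatrix(self._data.loc[:, samples])

    def drop_zero_variance_genes(self) -> tuple["ExpressionMatrix", list[str]]:
        """Remove genes with zero variance across samples.

        Returns the reduced matrix and the list of dropped gene ids.
        """
        var = self._data.var(axis=1, ddof=1).to_numpy()
        dropped = [g for g, v in zip(self._data.index, var) if v <= 0]
        if not dropped:
            return self, []
        keep = self._data.loc[var > 0]
        return ExpressionMatrix(keep), dropped

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self._data.equals(other._data)


class TraitTable:
    """Per-sample trait annotations.

    Binary traits must be coded 0/1 (convention: 0 = female, 1 = male for a
    sex trait); categorical traits (developmental stage) are kept as labels.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (samples x traits)")
        _check_unique(data.index, "sample")
        self._data = data.copy()

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    def binary_trait(self, name: str) -> np.ndarray:
        """Return a trait column validated as 0/1 and coded as an int array."""
        if name not in self._data.columns:
            raise KeyError(f"trait {name!r} not in trait table")
        col = self._data[name]
        vals = pd.unique(col)
        if not set(np.asarray(vals).tolist()) <= {0, 1}:
            raise ValueError(f"trait {name!r} is not binary 0/1: values {list(vals)}")
        return col.to_numpy(dtype=int)

    def column(self, name: str) -> pd.Series:
        if name not in self._data.columns:
            raise KeyError(f"trait {name!r} not in trait table")
        return self._data[name]

    def subset_samples(self, samples: Iterable[str]) -> "TraitTable":
        samples = [s for s in samples]
        missing = set(samples) - set(self._data.index)
        if missing:
            raise KeyError(f"samples not in trait table: {sorted(missing)[:10]}")
        return TraitTable(self._data.loc[samples])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TraitTable) and self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitTable({len(self._data)} samples, traits={list(self._data.columns)})"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __and__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.name}&{other.name}", self.genes & other.genes)

    def __or__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.name}|{other.name}", self.genes | other.genes)

    def check_subset_of(self, em: ExpressionMatrix) -> None:
        extra = self.genes - set(em.gene_ids)
        if extra:
            raise ValueError(
                f"gene set {self.name!r} contains identifiers absent from the "
                f"matrix: {sorted(extra)[:10]}"
            )


@dataclass(frozen=True)
class KeyGeneList:
    """Curated list of genes known to be involved in the process under study."""

    genes: tuple
    source: str = ""

    def __post_init__(self):
        genes = tuple(self.genes)
        if not genes:
            raise ValueError("key gene list is empty")
        _check_unique(genes, "key gene")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
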