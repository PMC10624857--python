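"""Phenotypic trait panel: one row per genotype, one column per trait."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraitPanel"]


@dataclass
class TraitPanel:
    """n x m matrix of per-genotype phenotypic values with labels.

    Parameters
    ----------
    X : ndarray, shape (n, m)
        Phenotypic values, one row per genotype, one column per trait.
    genotype_ids : sequence of str
        n genotype labels (order defines rank tie-breaking downstream).
    trait_names : sequence of str
        m trait labels, used to check alignment against P/G/a/d inputs.
    """

    X: np.ndarray
    genotype_ids: list[str] = field(default=None)
    trait_names: list[str] = field(default=None)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D (genotypes x traits) array")
        n, m = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 genotypes, got {n}")
        if np.isnan(self.X).any():
            bad = np.argwhere(np.isnan(self.X))[0]
            raise ValueError(
                f"missing value at genotype row {bad[0]}, trait column {bad[1]}; "
                "missing data is not imputed"
            )
        if self.genotype_ids is None:
            self.genotype_ids = [str(i + 1) for i in range(n)]
        else:
            self.genotype_ids = [str(g) for g in self.genotype_ids]
        if self.trait_names is None:
            self.trait_names = [f"trait_{j + 1}" for j in range(m)]
        else:
            self.trait_names = [str(t) for t in self.trait_names]
        if len(self.genotype_ids) != n:
            raise ValueError("genotype_ids length does not match X rows")
        if len(self.trait_names) != m:
            raise ValueError("trait_names length does not match X columns")

    @property
    def n_genotypes(self) -> int:
        return self.X.shape[0]

    @property
    def n_traits(self) -> int:
        return self.X.shape[1]

    def trait_index(self, trait: int | str) -> int:
        """Resolve a trait given by 0-based index or by name."""
        if isinstance(trait, str):
            try:
                return self.trait_names.index(trait)
            except ValueError:
                raise KeyError(
                    f"trait {trait!r} not among {self.trait_names}"
                ) from None
        j = int(trait)
        if not 0 <= j < self.n_traits:
            raise IndexError(f"trait index {j} out of range for m={self.n_traits}")
        return j

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, genotype_col: str = "genotype") -> "TraitPanel":
        df = df.copy()
        if genotype_col in df.columns:
            ids = df.pop(genotype_col).astype(str).tolist()
        else:
            ids = [str(i + 1) for i in range(len(df))]
        return cls(df.to_numpy(dtype=float), ids, list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.genotype_ids, name="genotype"),
                            columns=self.trait_names)
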