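"""Variance components, P and G matrices, and heritability from RCBD trials.

A balanced randomized complete block design (every genotype observed once in
every replicate block) admits the classical two-way ANOVA decomposition per
trait, and the analogous analysis of mean cross-products between trait pairs.
Equating observed mean squares to their expectations under the random-genotype
model gives

    sigma2_g = (MS_g - MS_e) / r        sigma2_e = MS_e

and identically for genotypic covariances via mean cross-products. Phenotypic
(co)variances follow on either the plot basis (sigma2_g + sigma2_e) or the
genotype-mean basis (sigma2_g + sigma2_e / r). Broad-sense heritability is
h2 = sigma2_g / sigma2_p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import TraitPanel

__all__ = [
    "RCBDTrial",
    "VarCompResult",
    "CorrelationPair",
    "estimate_components",
    "correlation_matrices",
    "genotype_means",
]


@dataclass
class RCBDTrial:
    """Plot-level data from a balanced randomized complete block trial.

    Parameters
    ----------
    genotype_id, replicate_id : sequences of labels, one per plot.
    values : ndarray, shape (n_plots, m)
        Trait measurements per plot.
    trait_names : m trait labels.
    """

    genotype_id: np.ndarray
    replicate_id: np.ndarray
    values: np.ndarray
    trait_names: list[str] = field(default=None)

    def __post_init__(self):
        self.genotype_id = np.asarray(self.genotype_id).astype(str)
        self.replicate_id = np.asarray(self.replicate_id).astype(str)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n_plots, m = self.values.shape
        if len(self.genotype_id) != n_plots or len(self.replicate_id) != n_plots:
            raise ValueError("genotype_id/replicate_id length must match rows of values")
        if self.trait_names is None:
            self.trait_names = [f"trait_{j + 1}" for j in range(m)]
        if len(self.trait_names) != m:
            raise ValueError("trait_names length does not match trait columns")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value for genotype {self.genotype_id[i]!r}, "
                f"replicate {self.replicate_id[i]!r}, trait {self.trait_names[j]!r}; "
                "missing plots are rejected, not imputed"
            )
        self._validate_balance()

    def _validate_balance(self):
        # stable first-appearance order for genotypes and replicates
        self.genotypes = list(dict.fromkeys(self.genotype_id))
        self.replicates = list(dict.fromkeys(self.replicate_id))
        n, r = len(self.genotypes), len(self.replicates)
        if n < 2:
            raise ValueError(f"need at least 2 genotypes, got {n}")
        if r < 2:
            raise ValueError(
                f"need at least 2 replicates to separate genotypic from error "
                f"variance, got {r}"
            )
        counts = pd.crosstab(pd.Series(self.genotype_id), pd.Series(self.replicate_id))
        counts = counts.reindex(index=self.genotypes, columns=self.replicates,
                                fill_value=0)
        bad = np.argwhere(counts.to_numpy() != 1)
        if bad.size:
            g, b = bad[0]
            raise ValueError(
                f"unbalanced design: genotype {self.genotypes[g]!r} appears "
                f"{counts.iat[g, b]} times in replicate {self.replicates[b]!r} "
                "(expected exactly 1)"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, genotype_col: str = "genotype",
                       replicate_col: str = "replicate") -> "RCBDTrial":
        for col in (genotype_col, replicate_col):
            if col not in df.columns:
                raise ValueError(f"trial table lacks required column {col!r}")
        traits = [c for c in df.columns if c not in (genotype_col, replicate_col)]
        if not traits:
            raise ValueError("trial table has no trait columns")
        return cls(df[genotype_col].to_numpy(), df[replicate_col].to_numpy(),
                   df[traits].to_numpy(dtype=float), traits)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"genotype": self.genotype_id,
                            "replicate": self.replicate_id})
        for j, t in enumerate(self.trait_names):
            out[t] = self.values[:, j]
        return out

    def _cell_means(self) -> np.ndarray:
        """(n, r, m) array of plot values ordered by genotype x replicate."""
        gi = {g: i for i, g in enumerate(self.genotypes)}
        ri = {b: i for i, b in enumerate(self.replicates)}
        cube = np.empty((self.n_genotypes, self.n_reps, self.n_traits))
        for row, (g, b) in enumerate(zip(self.genotype_id, self.replicate_id)):
            cube[gi[g], ri[b]] = self.values[row]
        return cube


@dataclass
class VarCompResult:
    """Variance components and covariance matrices from one RCBD trial."""

    sigma2_g: np.ndarray
    sigma2_e: np.ndarray
    sigma2_p: np.ndarray
    h2_broad: np.ndarray
    P: np.ndarray
    G: np.ndarray
    r_reps: int
    basis: str
    trait_names: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sigma2_g": self.sigma2_g, "sigma2_e": self.sigma2_e,
             "sigma2_p": self.sigma2_p, "h2_broad": self.h2_broad},
            index=pd.Index(self.trait_names, name="trait"),
        )


@dataclass
class CorrelationPair:
    """Genetic and phenotypic correlation matrices (NaN where undefined)."""

    r_g: np.ndarray
    r_p: np.ndarray
    trait_names: list[str]


def _cross_products(trial: RCBDTrial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sums of cross-products for the genotype, replicate and error strata."""
    cube = trial._cell_means()           # (n, r, m)
    n, r, m = cube.shape
    grand = cube.mean(axis=(0, 1))
    gmeans = cube.mean(axis=1) - grand   # (n, m)
    rmeans = cube.mean(axis=0) - grand   # (r, m)
    dev = cube - grand
    scp_g = r * gmeans.T @ gmeans
    scp_rep = n * rmeans.T @ rmeans
    scp_tot = np.einsum("ijk,ijl->kl", dev, dev)
    scp_e = scp_tot - scp_g - scp_rep
    return scp_g, scp_rep, scp_e


def estimate_components(trial: RCBDTrial, basis: str = "plot",
                        clamp_negative: bool = False) -> VarCompResult:
    """Estimate variance components and the P and G matrices from a trial.

    Parameters
    ----------
    trial : RCBDTrial
        Balanced plot-level data (validated on construction).
    basis : {"plot", "mean"}
        Scale of the phenotypic (co)variance: per-plot observations
        (sigma2_g + sigma2_e) or genotype means over r replicates
        (sigma2_g + sigma2_e / r).
    clamp_negative : bool
        Clamp negative genotypic variance estimates (and the matching G
        diagonal) to zero. Off by default because clamping breaks the
        sum-of-squares identity; a warning is always emitted for negative
        estimates.
    """
    if basis not in ("plot", "mean"):
        raise ValueError(f"basis must be 'plot' or 'mean', got {basis!r}")
    n, r = trial.n_genotypes, trial.n_reps
    scp_g, _, scp_e = _cross_products(trial)
    mcp_g = scp_g / (n - 1)
    mcp_e = scp_e / ((n - 1) * (r - 1))
    G = (mcp_g - mcp_e) / r
    E = mcp_e
    neg = np.diag(G) < 0
    if neg.any():
        bad = [trial.trait_names[j] for j in np.where(neg)[0]]
        warnings.warn(
            f"negative genotypic variance estimate for trait(s) {bad}; "
            + ("clamped to zero" if clamp_negative else
               "reported as estimated (use clamp_negative=True to clamp)"),
            stacklevel=2,
        )
        if clamp_negative:
            G = G.copy()
            idx = np.where(neg)[0]
            G[idx, idx] = 0.0
    P = G + (E if basis == "plot" else E / r)
    sigma2_g = np.diag(G).copy()
    sigma2_e = np.diag(E).copy()
    sigma2_p = np.diag(P).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(sigma2_p > 0, sigma2_g / sigma2_p, np.nan)
    if np.isnan(h2).any():
        bad = [trial.trait_names[j] for j in np.where(np.isnan(h2))[0]]
        warnings.warn(f"heritability undefined (zero phenotypic variance) for {bad}",
                      stacklevel=2)
    return VarCompResult(sigma2_g, sigma2_e, sigma2_p, h2, P, G, r, basis,
                         list(trial.trait_names))


def correlation_matrices(vc: VarCompResult) -> CorrelationPair:
    """Genetic and phenotypic correlations from the covariance matrices.

    Entries whose parent trait has nonpositive variance are NaN (undefined),
    never silently zero.
    """
    def corr(C):
        d = np.diag(C).copy()
        d[d <= 0] = np.nan
        s = np.sqrt(d)
        with np.errstate(invalid="ignore"):
            R = C / np.outer(s, s)
        np.fill_diagonal(R, np.where(np.isnan(d), np.nan, 1.0))
        return R

    return CorrelationPair(corr(vc.G), corr(vc.P), list(vc.trait_names))


def genotype_means(trial: RCBDTrial) -> TraitPanel:
    """Per-genotype trait means over replicates, in first-appearance order."""
    cube = trial._cell_means()
    return TraitPanel(cube.mean(axis=1), trial.genotypes, list(trial.trait_names))
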