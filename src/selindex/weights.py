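"""Economic-weight vectors a and the desired-gains vector d.

Three weighting schemes feed the optimum and base indices: equal weight for
every trait, the correlation of each trait with the target trait, and the
standardized beta coefficients of a stepwise regression of the target on the
remaining traits (non-entered traits get weight 0). The Pesek-Baker index
instead takes a desired-gains vector d, by default one genetic standard
deviation per trait, d = sqrt(diag(G)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .panel import TraitPanel
from .varcomp import CorrelationPair

__all__ = [
    "EconomicWeights",
    "DesiredGains",
    "unit_weights",
    "correlation_weights",
    "stepwise_beta_weights",
    "desired_gains",
]

#: SAS PROC REG `selection=stepwise` entry/stay significance defaults.
DEFAULT_SLE = 0.15
DEFAULT_SLS = 0.15

_COND_LIMIT = 1e12


@dataclass
class EconomicWeights:
    """Relative economic values per trait (dimensionless)."""

    a: np.ndarray
    scheme: str = "user"
    trait_names: list[str] = field(default=None)

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float).ravel()
        if not np.all(np.isfinite(self.a)):
            raise ValueError("economic weights must be finite")
        if self.trait_names is not None and len(self.trait_names) != self.a.size:
            raise ValueError("trait_names length does not match weight vector")


@dataclass
class DesiredGains:
    """Desired genetic gain per trait, in trait units."""

    d: np.ndarray
    trait_names: list[str] = field(default=None)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float).ravel()
        if not np.all(np.isfinite(self.d)):
            raise ValueError("desired gains must be finite")


def unit_weights(m: int, trait_names: list[str] | None = None) -> EconomicWeights:
    """Equal economic value 1 for each of m traits."""
    if m < 1:
        raise ValueError("need at least one trait")
    return EconomicWeights(np.ones(m), "unit", trait_names)


def correlation_weights(panel: TraitPanel | None, target: int | str,
                        source: str = "total",
                        corr: CorrelationPair | None = None) -> EconomicWeights:
    """Weights = correlation of each trait with the target trait.

    source="total" uses the Pearson correlation across the rows of the trait
    panel (genotype-level records); "phenotypic"/"genotypic" read the matching
    row of a precomputed :class:`CorrelationPair`. The target trait itself
    gets weight 1.
    """
    if source == "total":
        if panel is None:
            raise ValueError("source='total' requires a TraitPanel")
        j = panel.trait_index(target)
        X = panel.X
        sd = X.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if zero.size:
            bad = [panel.trait_names[z] for z in zero]
            raise ValueError(f"zero-variance trait(s) {bad}: correlation undefined")
        Xc = (X - X.mean(axis=0)) / sd
        a = Xc.T @ Xc[:, j] / (X.shape[0] - 1)
        names = panel.trait_names
    elif source in ("phenotypic", "genotypic"):
        if corr is None:
            raise ValueError(f"source={source!r} requires a CorrelationPair")
        R = corr.r_p if source == "phenotypic" else corr.r_g
        names = corr.trait_names
        j = names.index(target) if isinstance(target, str) else int(target)
        a = R[:, j].copy()
        if np.isnan(a).any():
            bad = [names[z] for z in np.where(np.isnan(a))[0]]
            raise ValueError(f"undefined correlation for trait(s) {bad}")
    else:
        raise ValueError(f"unknown source {source!r}")
    a[j] = 1.0
    return EconomicWeights(a, "correlation", list(names) if names else None)


def _partial_f_pvalue(y, Xcand, Xbase):
    """p-value of the F test for adding one column to the base OLS model."""
    n = y.size
    fit0 = sm.OLS(y, Xbase).fit()
    fit1 = sm.OLS(y, np.column_stack([Xbase, Xcand])).fit()
    df_e = n - Xbase.shape[1] - 1
    if df_e <= 0:
        return 1.0, 0.0
    sse0, sse1 = fit0.ssr, fit1.ssr
    if sse1 <= 1e-12 * max(fit0.centered_tss, 1.0):
        return 0.0, np.inf          # essentially perfect fit
    F = (sse0 - sse1) / (sse1 / df_e)
    return float(stats.f.sf(F, 1, df_e)), float(F)


def stepwise_beta_weights(panel: TraitPanel, target: int | str,
                          sle: float = DEFAULT_SLE,
                          sls: float = DEFAULT_SLS) -> EconomicWeights:
    """Standardized betas of a stepwise regression of the target on the rest.

    Forward selection with an F-test entry threshold ``sle`` and backward
    removal at ``sls`` (the classical stepwise procedure). Entered traits get
    their standardized regression coefficient, non-entered traits get 0, the
    target gets 1. Entry ties break toward the lowest column index.
    """
    if not (0 < sle < 1 and 0 < sls < 1):
        raise ValueError("sle and sls must lie in (0, 1)")
    j = panel.trait_index(target)
    X, names = panel.X, panel.trait_names
    n, m = X.shape
    if n <= m:
        raise ValueError(f"need more genotypes ({n}) than traits ({m}) for regression")
    y = X[:, j]
    candidates = [c for c in range(m) if c != j]
    const = np.ones((n, 1))
    entered: list[int] = []

    def design(cols):
        return np.column_stack([const] + [X[:, [c]] for c in cols])

    for _ in range(2 * m + 2):
        # entry step: best candidate by partial F
        best, best_p, best_F = None, None, -np.inf
        base = design(entered)
        for c in candidates:
            if c in entered:
                continue
            trial = design(entered + [c])
            if np.linalg.cond(trial.T @ trial) > _COND_LIMIT:
                raise ValueError(
                    f"collinear predictors: adding trait {names[c]!r} to "
                    f"{[names[e] for e in entered]} makes the normal equations singular"
                )
            p, F = _partial_f_pvalue(y, X[:, [c]], base)
            if p < sle and F > best_F:
                best, best_p, best_F = c, p, F
        if best is None:
            break
        entered.append(best)
        # removal step: worst included variable by partial t/F
        fit = sm.OLS(y, design(entered)).fit()
        pvals = np.asarray(fit.pvalues)[1:]          # skip intercept
        worst = int(np.argmax(pvals)) if pvals.size else None
        if worst is not None and pvals[worst] > sls:
            removed = entered.pop(worst)
            if removed == best:
                break                                # SAS stopping rule
        if fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0):
            break                                    # perfect fit, nothing to add

    a = np.zeros(m)
    a[j] = 1.0
    if entered:
        fit = sm.OLS(y, design(entered)).fit()
        betas = np.asarray(fit.params)[1:]
        sy = y.std(ddof=1)
        for c, beta in zip(entered, betas):
            a[c] = beta * X[:, c].std(ddof=1) / sy
    return EconomicWeights(a, "stepwise_beta", list(names))


def desired_gains(G: np.ndarray, override: np.ndarray | None = None,
                  trait_names: list[str] | None = None) -> DesiredGains:
    """Desired-gains vector d = sqrt(diag(G)), or a breeder-supplied override."""
    if override is not None:
        return DesiredGains(np.asarray(override, dtype=float), trait_names)
    diag = np.diag(np.asarray(G, dtype=float))
    if (diag < 0).any():
        bad = np.where(diag < 0)[0].tolist()
        raise ValueError(
            f"negative genotypic variance at trait position(s) {bad}; supply an "
            "explicit override for d"
        )
    return DesiredGains(np.sqrt(diag), trait_names)
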