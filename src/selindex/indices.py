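"""Selection-index coefficient vectors, genotype scores and rankings.

Three classical linear indices I = sum_i b_i X_i over m traits:

* optimum (Smith-Hazel):   b solves P b = G a, maximizing corr(I, H) where
  H = a'g is the aggregate breeding value;
* base (Brim):             b = a, the economic weights used directly;
* Pesek-Baker:             b solves G b = d, targeting desired gains d.

Linear systems are solved, never inverted explicitly; an ill-conditioned P or
G (condition number above 1e12) raises with a suggestion to drop traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .panel import TraitPanel
from .weights import DesiredGains, EconomicWeights

__all__ = [
    "SelectionIndexModel",
    "IndexScores",
    "optimum_coefficients",
    "base_coefficients",
    "pesek_baker_coefficients",
    "score_genotypes",
    "rank_and_select",
    "index_score_correlation",
]

COND_LIMIT = 1e12

METHODS = ("optimum", "base", "pesek_baker")


@dataclass
class SelectionIndexModel:
    """Index coefficients b for one method/weighting pairing."""

    method: str
    b: np.ndarray
    weights_used: EconomicWeights | DesiredGains | None = None
    trait_names: list[str] = field(default=None)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        self.b = np.asarray(self.b, dtype=float).ravel()
        if not np.all(np.isfinite(self.b)):
            raise ValueError("index coefficients must be finite")


@dataclass
class IndexScores:
    """Per-genotype index scores I = X b with descending-score ranks."""

    I: np.ndarray
    ranks: np.ndarray
    genotype_ids: list[str]
    mean_score: float
    sd_score: float

    @property
    def order(self) -> np.ndarray:
        """Genotype row positions sorted best-first (stable in input order)."""
        return np.argsort(-self.I, kind="stable")


def _as_matrix(M, name):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, rtol=0, atol=1e-8 * (1 + np.abs(M).max())):
        raise ValueError(f"{name} must be symmetric")
    return M


def _guarded_solve(M, rhs, name):
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"{name} is singular or ill-conditioned (condition number {cond:.3g} "
            f"> {COND_LIMIT:g}); consider removing redundant/collinear traits"
        )
    return scipy.linalg.solve(M, rhs, assume_a="sym")


def optimum_coefficients(P: np.ndarray, G: np.ndarray,
                         a: EconomicWeights | np.ndarray,
                         trait_names: list[str] | None = None) -> SelectionIndexModel:
    """Smith-Hazel optimum index: b solves P b = G a."""
    P = _as_matrix(P, "P")
    G = _as_matrix(G, "G")
    w = a if isinstance(a, EconomicWeights) else EconomicWeights(a)
    if P.shape[0] != G.shape[0] or w.a.size != P.shape[0]:
        raise ValueError(
            f"dimension mismatch: P is {P.shape}, G is {G.shape}, a has {w.a.size}"
        )
    b = _guarded_solve(P, G @ w.a, "P")
    return SelectionIndexModel("optimum", b, w, trait_names)


def base_coefficients(a: EconomicWeights | np.ndarray,
                      trait_names: list[str] | None = None) -> SelectionIndexModel:
    """Brim base index: coefficients are the economic weights themselves."""
    w = a if isinstance(a, EconomicWeights) else EconomicWeights(a)
    return SelectionIndexModel("base", w.a.copy(), w, trait_names)


def pesek_baker_coefficients(G: np.ndarray, d: DesiredGains | np.ndarray,
                             trait_names: list[str] | None = None,
                             allow_pinv: bool = False) -> SelectionIndexModel:
    """Pesek-Baker desired-gains index: b solves G b = d.

    A singular G raises unless ``allow_pinv`` explicitly requests the
    minimum-norm pseudo-inverse solution.
    """
    G = _as_matrix(G, "G")
    dg = d if isinstance(d, DesiredGains) else DesiredGains(d)
    if dg.d.size != G.shape[0]:
        raise ValueError(f"G is {G.shape} but d has {dg.d.size} entries")
    try:
        b = _guarded_solve(G, dg.d, "G")
    except np.linalg.LinAlgError:
        if not allow_pinv:
            raise
        b = np.linalg.pinv(G) @ dg.d
    return SelectionIndexModel("pesek_baker", b, dg, trait_names)


def score_genotypes(panel: TraitPanel, model: SelectionIndexModel) -> IndexScores:
    """Score I = X b per genotype; rank 1 is the highest score, ties stable."""
    if model.b.size != panel.n_traits:
        raise ValueError(
            f"panel has {panel.n_traits} traits but model has {model.b.size} "
            "coefficients"
        )
    if model.trait_names and panel.trait_names and \
            model.trait_names != panel.trait_names:
        raise ValueError(
            f"trait order mismatch: panel {panel.trait_names} vs "
            f"model {model.trait_names}"
        )
    I = panel.X @ model.b
    order = np.argsort(-I, kind="stable")
    ranks = np.empty(I.size, dtype=int)
    ranks[order] = np.arange(1, I.size + 1)
    return IndexScores(I, ranks, list(panel.genotype_ids),
                       float(I.mean()), float(I.std(ddof=1)))


def rank_and_select(scores: IndexScores, intensity: float) -> list[str]:
    """Top ceil(n * intensity) genotype ids by rank."""
    if not 0 < intensity <= 1:
        raise ValueError(f"selection intensity must lie in (0, 1], got {intensity}")
    n_sel = int(np.ceil(len(scores.genotype_ids) * intensity))
    return [scores.genotype_ids[i] for i in scores.order[:n_sel]]


def index_score_correlation(score_sets: list[IndexScores],
                            labels: list[str] | None = None) -> np.ndarray:
    """Pearson correlation matrix between the score vectors of several indices."""
    ids = score_sets[0].genotype_ids
    for s in score_sets[1:]:
        if s.genotype_ids != ids:
            raise ValueError("score sets cover different genotype sets")
    S = np.column_stack([s.I for s in score_sets])
    sd = S.std(axis=0, ddof=1)
    if (sd == 0).any():
        which = np.where(sd == 0)[0].tolist()
        warnings.warn(f"constant score vector(s) at position(s) {which}: "
                      "correlation undefined (NaN)", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(S, rowvar=False)
    R = np.atleast_2d(R)
    return R
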