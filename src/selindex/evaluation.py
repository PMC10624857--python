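"""Evaluation criteria for selection indices.

For an index with coefficients b and weights w (economic values a, or desired
gains d for the Pesek-Baker index), with H = w'g the aggregate genotype:

* accuracy          R_HI  = b'Gw / sqrt(b'Pb * w'Gw)
* total gain        dH    = k * R_HI * sigma_H,  sigma_H = sqrt(w'Gw)
* per-trait gain    delta = k * G b / sqrt(b'Pb)
* relative efficiency against direct selection on a target trait A:
                    RE    = r_GAI / h_A,
                    r_GAI = b'g / sqrt(G_AA * b'Pb),  h_A = sqrt(G_AA / P_AA)
* variability       CV_I  = 100 * sd(I) / mean(I) over realized scores

k is the standardized selection differential of truncation selection: for a
selected proportion p from a normal distribution, k = phi(z)/p with z the
upper-p quantile (about 1.755 at p = 0.10, commonly rounded to 1.76).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import IndexScores, SelectionIndexModel
from .panel import TraitPanel
from .weights import DesiredGains, EconomicWeights

__all__ = [
    "EvaluationCriteria",
    "selection_differential",
    "response_correlation",
    "aggregate_gain",
    "per_trait_gain",
    "relative_efficiency",
    "index_cv",
    "evaluate_index",
]


@dataclass
class EvaluationCriteria:
    """The evaluation-report row for one index/weighting pairing."""

    method: str
    scheme: str
    k: float
    R_HI: float
    sigma_H: float
    delta_H: float
    delta: np.ndarray
    r_GAI: float
    h_A: float
    RE: float
    CV_I: float
    trait_names: list[str] = field(default=None)

    def as_series(self, decimals: int | None = None) -> pd.Series:
        names = self.trait_names or [f"trait_{j+1}" for j in range(self.delta.size)]
        data = {f"delta[{t}]": v for t, v in zip(names, self.delta)}
        data.update({"R_HI": self.R_HI, "delta_H": self.delta_H,
                     "RE": self.RE, "CV_I": self.CV_I})
        s = pd.Series(data, name=f"{self.method}/{self.scheme}")
        return s.round(decimals) if decimals is not None else s


def selection_differential(p: float) -> float:
    """Standardized selection differential k = phi(z)/p for truncation at p."""
    if not 0 < p < 1:
        raise ValueError(f"selected proportion must lie in (0, 1), got {p}")
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)


def _weight_vector(w) -> np.ndarray:
    if isinstance(w, EconomicWeights):
        return w.a
    if isinstance(w, DesiredGains):
        return w.d
    return np.asarray(w, dtype=float).ravel()


def response_correlation(model: SelectionIndexModel, P: np.ndarray, G: np.ndarray,
                         w) -> tuple[float, float]:
    """Accuracy R_HI = cov(I,H)/(sigma_I sigma_H) and sigma_H = sqrt(w'Gw).

    The general covariance form is used for every method; the optimum-only
    simplification sqrt(b'Ga/a'Ga) would overstate the accuracy of the base
    and Pesek-Baker indices.
    """
    b, wv = model.b, _weight_vector(w)
    var_I = float(b @ P @ b)
    var_H = float(wv @ G @ wv)
    if var_I <= 0 or var_H <= 0:
        raise ValueError(
            f"nonpositive quadratic form (b'Pb={var_I:.3g}, w'Gw={var_H:.3g}); "
            "the covariance estimates are indefinite"
        )
    r = float(b @ G @ wv) / np.sqrt(var_I * var_H)
    return r, float(np.sqrt(var_H))


def aggregate_gain(k: float, R_HI: float, sigma_H: float) -> float:
    """Expected total genetic gain dH = k * R_HI * sigma_H per cycle."""
    return float(k * R_HI * sigma_H)


def per_trait_gain(k: float, G: np.ndarray, model: SelectionIndexModel,
                   P: np.ndarray) -> np.ndarray:
    """Expected per-trait gains delta = k G b / sqrt(b'Pb), in trait units."""
    b = model.b
    var_I = float(b @ P @ b)
    if var_I <= 0:
        raise ValueError(f"b'Pb = {var_I:.3g} is not positive; the index is "
                         "degenerate (zero or indefinite variance)")
    return k * (np.asarray(G) @ b) / np.sqrt(var_I)


def relative_efficiency(model: SelectionIndexModel, P: np.ndarray, G: np.ndarray,
                        target: int) -> tuple[float, float, float]:
    """Efficiency of index selection relative to direct selection on a trait.

    Returns (RE, r_GAI, h_A) for target trait A at 0-based position ``target``.
    """
    P, G = np.asarray(P, float), np.asarray(G, float)
    A = int(target)
    g = G[:, A]
    if G[A, A] <= 0:
        raise ValueError(f"target trait {A} has nonpositive genotypic variance")
    if P[A, A] <= 0:
        raise ValueError(f"target trait {A} has nonpositive phenotypic variance")
    b = model.b
    var_I = float(b @ P @ b)
    if var_I <= 0:
        raise ValueError("b'Pb must be positive")
    r_GAI = float(b @ g) / np.sqrt(G[A, A] * var_I)
    h_A = float(np.sqrt(G[A, A] / P[A, A]))
    return r_GAI / h_A, r_GAI, h_A


def index_cv(scores: IndexScores, tol: float = 1e-12) -> float:
    """Coefficient of variation of the realized scores, 100 * sd/mean (%)."""
    if abs(scores.mean_score) <= tol * max(1.0, scores.sd_score):
        raise ValueError(
            f"mean index score {scores.mean_score:.3g} is too close to zero; "
            "CV_I is undefined for a zero-mean index"
        )
    return float(100.0 * scores.sd_score / scores.mean_score)


def evaluate_index(model: SelectionIndexModel, P: np.ndarray, G: np.ndarray, w,
                   panel: TraitPanel | None = None, target: int = 0,
                   p: float = 0.10, k: float | None = None,
                   scores: IndexScores | None = None) -> EvaluationCriteria:
    """Assemble the full criteria row for one index/weighting pairing.

    CV_I needs realized scores, so either a trait panel or precomputed
    ``scores`` must be supplied; with neither, CV_I is NaN.
    """
    from .indices import score_genotypes

    if k is None:
        k = selection_differential(p)
    R_HI, sigma_H = response_correlation(model, P, G, w)
    dH = aggregate_gain(k, R_HI, sigma_H)
    delta = per_trait_gain(k, G, model, P)
    RE, r_GAI, h_A = relative_efficiency(model, P, G, target)
    if scores is None and panel is not None:
        scores = score_genotypes(panel, model)
    cv = index_cv(scores) if scores is not None else float("nan")
    scheme = getattr(model.weights_used, "scheme", None) or (
        "desired_gains" if isinstance(model.weights_used, DesiredGains) else "user")
    return EvaluationCriteria(model.method, scheme, k, R_HI, sigma_H, dH, delta,
                              r_GAI, h_A, RE, cv, model.trait_names)
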