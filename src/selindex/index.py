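"""Model/Results interface tying the whole workflow together.

``SelectionIndex`` is constructed from data (a trait panel plus covariance
matrices, or a raw RCBD trial) and a weighting; ``fit()`` returns a
``SelectionIndexResults`` carrying the coefficient vector, per-genotype
scores and ranks, the evaluation criteria, and a ``summary()`` table —
mirroring the model/results split familiar from statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import indices as _ix
from .evaluation import EvaluationCriteria, evaluate_index, selection_differential
from .panel import TraitPanel
from .varcomp import RCBDTrial, estimate_components, genotype_means
from .weights import DesiredGains, EconomicWeights, desired_gains, unit_weights

__all__ = ["SelectionIndex", "SelectionIndexResults"]


class SelectionIndex:
    """A selection-index model for one method and one weighting scheme.

    Parameters
    ----------
    panel : TraitPanel
        Phenotypic records (genotype means), the X of I = X b.
    P, G : (m, m) arrays
        Phenotypic and genotypic covariance matrices. The base index needs
        neither to compute b, but both to be evaluated.
    method : {"optimum", "base", "pesek_baker"}
    weights : EconomicWeights, DesiredGains, array, or None
        Economic values a (optimum/base) or desired gains d (pesek_baker).
        Defaults to unit weights, or d = sqrt(diag(G)) for pesek_baker.
    target : trait name or 0-based index used for relative efficiency.
    """

    def __init__(self, panel: TraitPanel, P=None, G=None, method="optimum",
                 weights=None, target: int | str = None, allow_pinv=False):
        self.panel = panel
        self.method = method
        self.P = None if P is None else np.asarray(P, float)
        self.G = None if G is None else np.asarray(G, float)
        self.allow_pinv = allow_pinv
        m = panel.n_traits
        if method == "pesek_baker":
            if weights is None:
                if self.G is None:
                    raise ValueError("pesek_baker needs G to derive d = sqrt(diag(G))")
                weights = desired_gains(self.G, trait_names=panel.trait_names)
            elif not isinstance(weights, DesiredGains):
                weights = DesiredGains(weights, panel.trait_names)
        else:
            if weights is None:
                weights = unit_weights(m, panel.trait_names)
            elif not isinstance(weights, EconomicWeights):
                weights = EconomicWeights(weights, trait_names=panel.trait_names)
        self.weights = weights
        self.target = panel.trait_index(target) if target is not None else m - 1

    @classmethod
    def from_trial(cls, trial: RCBDTrial, basis: str = "plot", **kwargs
                   ) -> "SelectionIndex":
        """Estimate P and G from a balanced RCBD trial, score genotype means."""
        vc = estimate_components(trial, basis=basis)
        panel = genotype_means(trial)
        return cls(panel, P=vc.P, G=vc.G, **kwargs)

    def fit(self, intensity: float = 0.10, k: float | None = None
            ) -> "SelectionIndexResults":
        """Compute coefficients, score genotypes and evaluate the index."""
        names = self.panel.trait_names
        if self.method == "optimum":
            model = _ix.optimum_coefficients(self.P, self.G, self.weights, names)
        elif self.method == "base":
            model = _ix.base_coefficients(self.weights, names)
        elif self.method == "pesek_baker":
            model = _ix.pesek_baker_coefficients(self.G, self.weights, names,
                                                 allow_pinv=self.allow_pinv)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        scores = _ix.score_genotypes(self.panel, model)
        criteria = None
        if self.P is not None and self.G is not None:
            criteria = evaluate_index(model, self.P, self.G, self.weights,
                                      target=self.target, p=intensity, k=k,
                                      scores=scores)
        k_val = k if k is not None else selection_differential(intensity)
        return SelectionIndexResults(self, model, scores, criteria,
                                     float(intensity), float(k_val))


@dataclass
class SelectionIndexResults:
    """Fitted coefficients, scores, ranks and criteria for one index."""

    model_spec: SelectionIndex
    coefficients: _ix.SelectionIndexModel
    scores: _ix.IndexScores
    criteria: EvaluationCriteria | None
    intensity: float
    k: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients.b,
                         index=self.model_spec.panel.trait_names, name="b")

    def select(self, intensity: float | None = None) -> list[str]:
        return _ix.rank_and_select(self.scores,
                                   intensity if intensity is not None
                                   else self.intensity)

    def ranking(self) -> pd.DataFrame:
        df = pd.DataFrame({"genotype": self.scores.genotype_ids,
                           "score": self.scores.I, "rank": self.scores.ranks})
        return df.sort_values("rank").reset_index(drop=True)

    def summary(self) -> str:
        spec = self.model_spec
        lines = [
            "Selection Index Results",
            "=" * 58,
            f"Method:            {self.coefficients.method}",
            f"Weighting scheme:  {getattr(spec.weights, 'scheme', 'desired_gains')}",
            f"Genotypes, traits: {spec.panel.n_genotypes}, {spec.panel.n_traits}",
            f"Selection:         p = {self.intensity:.4g}  (k = {self.k:.4f})",
            "-" * 58,
            "Index coefficients b:",
            self.params.round(4).to_string(),
        ]
        if self.criteria is not None:
            c = self.criteria
            lines += [
                "-" * 58,
                "Evaluation criteria:",
                f"  accuracy R_HI        = {c.R_HI:.4f}",
                f"  total gain delta_H   = {c.delta_H:.4f}",
                f"  rel. efficiency RE   = {c.RE:.4f}"
                f"  (target trait: {spec.panel.trait_names[spec.target]})",
                f"  CV of index (%)      = {c.CV_I:.4f}",
                "  per-trait gains delta:",
                pd.Series(c.delta, index=spec.panel.trait_names).round(4)
                  .to_string(),
            ]
        lines += [
            "-" * 58,
            f"Selected at p={self.intensity:.2g}: "
            + ", ".join(self.select()),
        ]
        return "\n".join(lines)
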