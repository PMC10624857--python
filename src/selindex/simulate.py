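"""Simulated multi-trait RCBD trials with known covariance ground truth.

The generator draws, in a fixed documented order, (1) genotype effects
g_i ~ MVN(0, G_true), (2) per-trait replicate effects r_j ~ N(0, rep_sd^2),
(3) plot errors e_ij ~ MVN(0, E_true), and emits plot values

    y_ij = mu + g_i + r_j + e_ij

so every downstream estimate (P, G, h2, index coefficients, gains) can be
checked against the truth that produced the data. Replicate effects default
to zero: block effects cancel from genotype means and never enter the
evaluation criteria, but a nonzero value exercises the replicate stratum of
the ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import TraitPanel
from .varcomp import RCBDTrial

__all__ = ["SimulationSpec", "simulate_rcbd_trial", "worked_fixture"]


def _check_spd(M, name):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    lo = float(np.linalg.eigvalsh(M)[0])
    if lo <= 0:
        raise ValueError(
            f"{name} is not positive definite: smallest eigenvalue {lo:.3g}"
        )
    return M


@dataclass
class SimulationSpec:
    """Ground-truth parameters for one simulated RCBD trial."""

    G_true: np.ndarray
    E_true: np.ndarray
    mu: np.ndarray = None
    n_genotypes: int = 100
    n_reps: int = 3
    rep_effect_sd: float = 0.0
    seed: int = 0
    trait_names: list[str] = field(default=None)

    def __post_init__(self):
        self.G_true = _check_spd(self.G_true, "G_true")
        self.E_true = _check_spd(self.E_true, "E_true")
        m = self.G_true.shape[0]
        if self.E_true.shape[0] != m:
            raise ValueError("G_true and E_true disagree on trait count")
        self.mu = (np.zeros(m) if self.mu is None
                   else np.asarray(self.mu, dtype=float).ravel())
        if self.mu.size != m:
            raise ValueError("mu length does not match trait count")
        if self.n_genotypes < 2 or self.n_reps < 2:
            raise ValueError("need n_genotypes >= 2 and n_reps >= 2")
        if self.rep_effect_sd < 0:
            raise ValueError("rep_effect_sd must be nonnegative")
        if self.trait_names is None:
            self.trait_names = [f"trait_{j + 1}" for j in range(m)]

    @property
    def m(self) -> int:
        return self.G_true.shape[0]

    def expected_P(self, basis: str = "plot") -> np.ndarray:
        """Population phenotypic covariance implied by the spec."""
        if basis == "plot":
            return self.G_true + self.E_true
        if basis == "mean":
            return self.G_true + self.E_true / self.n_reps
        raise ValueError(f"basis must be 'plot' or 'mean', got {basis!r}")


def simulate_rcbd_trial(spec: SimulationSpec) -> tuple[RCBDTrial, dict]:
    """Draw one balanced trial; returns (trial, ground-truth record).

    The truth record carries the realized genotype effects, replicate
    effects and the spec itself, so tests can compare estimates both with
    the population parameters and with their realized finite-sample values.
    """
    rng = np.random.default_rng(spec.seed)
    n, r, m = spec.n_genotypes, spec.n_reps, spec.m
    # draw order is part of the reproducibility contract: g, then r, then e
    g = rng.multivariate_normal(np.zeros(m), spec.G_true, size=n,
                                method="cholesky")
    rep = (rng.normal(0.0, spec.rep_effect_sd, size=(r, m))
           if spec.rep_effect_sd > 0 else np.zeros((r, m)))
    e = rng.multivariate_normal(np.zeros(m), spec.E_true, size=(n, r),
                                method="cholesky")
    y = spec.mu + g[:, None, :] + rep[None, :, :] + e      # (n, r, m)

    genotype_id = np.repeat([f"G{i + 1:03d}" for i in range(n)], r)
    replicate_id = np.tile([f"R{j + 1}" for j in range(r)], n)
    trial = RCBDTrial(genotype_id, replicate_id, y.reshape(n * r, m),
                      list(spec.trait_names))
    truth = {
        "spec": spec,
        "genotype_effects": g,
        "replicate_effects": rep,
        "expected_means": spec.mu + g + rep.mean(axis=0),
    }
    return trial, truth


def worked_fixture() -> tuple[TraitPanel, np.ndarray, np.ndarray, np.ndarray]:
    """Small two-trait example with hand-checkable downstream values.

    Returns (panel, P, G, a) where P = [[4,1],[1,2]], G = [[2,.5],[.5,1]],
    a = (1,1), and the 6-genotype panel X is constructed so its sample
    covariance equals P exactly. Handy identities: optimum b = (0.5, 0.5),
    base b = (1, 1), Pesek-Baker b = (0.52241, 0.73880) for d = sqrt(diag G).
    """
    P = np.array([[4.0, 1.0], [1.0, 2.0]])
    G = np.array([[2.0, 0.5], [0.5, 1.0]])
    a = np.array([1.0, 1.0])
    # fixed base scores, exactly whitened then recoloured so cov(X) == P
    base = np.array([
        [1.2, -0.3],
        [-0.7, 0.9],
        [0.4, 1.6],
        [-1.5, -0.8],
        [0.9, -1.1],
        [-0.3, -0.3],
    ])
    Z = base - base.mean(axis=0)
    C = np.cov(Z, rowvar=False)
    Z_white = Z @ np.linalg.inv(np.linalg.cholesky(C).T)
    mu = np.array([20.0, 10.0])
    X = mu + Z_white @ np.linalg.cholesky(P).T
    panel = TraitPanel(X, [f"g{i + 1}" for i in range(6)], ["t1", "t2"])
    return panel, P, G, a
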