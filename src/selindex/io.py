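"""CSV input/output and the end-to-end pipeline.

File layout mirrors common breeding-trial practice: a trait matrix X
(optional ``genotype`` id column + one column per trait), square P and G
covariance CSVs with trait names as header row and index column, and an
optional weights CSV with one row per trait and one column per scheme.
Reports are written as a directory of CSVs (diff-able, language-neutral)
with 4-decimal rounding in the human-readable criteria table and full
precision in machine-readable sidecars.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import selection_differential
from .index import SelectionIndex
from .indices import index_score_correlation
from .panel import TraitPanel
from .varcomp import RCBDTrial, correlation_matrices, estimate_components, genotype_means
from .weights import (DEFAULT_SLE, DEFAULT_SLS, EconomicWeights,
                      correlation_weights, stepwise_beta_weights, unit_weights)

__all__ = [
    "RunConfig",
    "read_panel_csv",
    "read_matrix_csv",
    "read_weights_csv",
    "read_trial_csv",
    "write_matrix_csv",
    "run_pipeline",
]

logger = logging.getLogger("selindex")

SYMMETRY_TOL = 1e-6


@dataclasses.dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Exactly one input mode: either ``trial_path`` (plot-level CSV, P and G
    estimated here) or ``x_path`` + ``p_path`` + ``g_path`` (precomputed).
    ``target`` is a trait name or 1-based position (matching field habit of
    numbering traits from 1); ``intensity`` and ``k`` are mutually exclusive
    ways to fix the selection differential.
    """

    trial_path: str | None = None
    x_path: str | None = None
    p_path: str | None = None
    g_path: str | None = None
    weights_path: str | None = None
    target: int | str = None
    intensity: float = 0.10
    k: float | None = None
    methods: tuple[str, ...] = ("optimum", "base", "pesek_baker")
    schemes: tuple[str, ...] = ("unit",)
    basis: str = "plot"
    clamp_negative: bool = False
    allow_pinv: bool = False
    sle: float = DEFAULT_SLE
    sls: float = DEFAULT_SLS
    outdir: str = "selindex_out"

    def __post_init__(self):
        trial_mode = self.trial_path is not None
        matrix_mode = self.x_path is not None
        if trial_mode == matrix_mode:
            raise ValueError(
                "exactly one input mode: give either trial_path or "
                "x_path (+ p_path, g_path)"
            )
        if matrix_mode and (self.p_path is None or self.g_path is None):
            raise ValueError("matrix mode needs x_path, p_path and g_path")
        if not 0 < self.intensity <= 1:
            raise ValueError(f"intensity must lie in (0, 1], got {self.intensity}")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        return pd.read_csv(path)
    except ValueError as err:
        raise ValueError(f"could not parse {path}: {err}") from err


def read_panel_csv(path) -> TraitPanel:
    """Read a trait matrix X; a ``genotype`` column supplies ids if present."""
    df = _read_csv(path)
    non_numeric = [c for c in df.columns if c != "genotype"
                   and not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric trait column(s) {non_numeric}")
    return TraitPanel.from_dataframe(df)


def read_matrix_csv(path, name: str = "matrix") -> tuple[np.ndarray, list[str]]:
    """Read a square covariance CSV (trait-name header + index column).

    Symmetrized when the asymmetry is within 1e-6 (warned); beyond that it
    is an error naming the worst cell.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: {name} must be square, got {df.shape}")
    try:
        M = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric cell in {name}: {err}") from err
    asym = np.abs(M - M.T)
    worst = float(asym.max()) if M.size else 0.0
    if worst > SYMMETRY_TOL * max(1.0, float(np.abs(M).max())):
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: {name} asymmetric beyond tolerance at "
            f"[{df.index[i]!r}, {df.columns[j]!r}]: "
            f"{M[i, j]!r} vs {M[j, i]!r}"
        )
    if worst > 0:
        warnings.warn(f"{path}: {name} symmetrized (max asymmetry {worst:.2e})",
                      stacklevel=2)
        M = (M + M.T) / 2.0
    return M, [str(c) for c in df.columns]


def read_weights_csv(path) -> pd.DataFrame:
    """Weights CSV: one row per trait (index column), one column per scheme."""
    df = pd.read_csv(path, index_col=0)
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"{path}: non-numeric weight column(s) {bad}")
    return df


def read_trial_csv(path) -> RCBDTrial:
    """Plot-level trial CSV: genotype, replicate, then one column per trait."""
    return RCBDTrial.from_dataframe(_read_csv(path))


def write_matrix_csv(M: np.ndarray, trait_names: list[str], path) -> None:
    pd.DataFrame(M, index=trait_names, columns=trait_names).to_csv(path)


def _check_alignment(names_x, names_m, src_x, src_m):
    if names_x and names_m and list(names_x) != list(names_m):
        raise ValueError(
            f"trait mismatch between {src_x} ({list(names_x)}) and "
            f"{src_m} ({list(names_m)})"
        )


def _resolve_weights(scheme: str, config: RunConfig, panel: TraitPanel,
                     target: int, weight_table: pd.DataFrame | None
                     ) -> EconomicWeights:
    if scheme == "unit":
        return unit_weights(panel.n_traits, panel.trait_names)
    if scheme == "correlation":
        return correlation_weights(panel, target, source="total")
    if scheme in ("beta", "stepwise_beta"):
        return stepwise_beta_weights(panel, target, sle=config.sle, sls=config.sls)
    if weight_table is not None and scheme in weight_table.columns:
        return EconomicWeights(weight_table[scheme].to_numpy(), "user",
                               list(weight_table.index.astype(str)))
    raise ValueError(
        f"unknown weight scheme {scheme!r} (built-ins: unit, correlation, beta; "
        f"file schemes: {list(weight_table.columns) if weight_table is not None else []})"
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run every requested (method x scheme) pairing and write the reports.

    Writes to ``config.outdir``: coefficients.csv, per-pairing score/rank
    CSVs, selection.csv, criteria.csv (4-decimal, one row per pairing),
    index_correlations.csv and run_log.json. Returns the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.trial_path is not None:
        trial = read_trial_csv(config.trial_path)
        vc = estimate_components(trial, basis=config.basis,
                                 clamp_negative=config.clamp_negative)
        panel = genotype_means(trial)
        P, G = vc.P, vc.G
        write_matrix_csv(P, panel.trait_names, outdir / "P_estimated.csv")
        write_matrix_csv(G, panel.trait_names, outdir / "G_estimated.csv")
        vc.summary().to_csv(outdir / "variance_components.csv")
        cp = correlation_matrices(vc)
        write_matrix_csv(cp.r_g, panel.trait_names, outdir / "genetic_correlations.csv")
        write_matrix_csv(cp.r_p, panel.trait_names, outdir / "phenotypic_correlations.csv")
    else:
        panel = read_panel_csv(config.x_path)
        P, p_names = read_matrix_csv(config.p_path, "P")
        G, g_names = read_matrix_csv(config.g_path, "G")
        _check_alignment(panel.trait_names, p_names, config.x_path, config.p_path)
        _check_alignment(p_names, g_names, config.p_path, config.g_path)
        if P.shape[0] != panel.n_traits or G.shape[0] != panel.n_traits:
            raise ValueError(
                f"dimension mismatch: X ({config.x_path}) has {panel.n_traits} "
                f"traits but P ({config.p_path}) is {P.shape} and G "
                f"({config.g_path}) is {G.shape}"
            )

    weight_table = (read_weights_csv(config.weights_path)
                    if config.weights_path else None)
    if config.target is None:
        target = panel.n_traits - 1
    elif isinstance(config.target, str) and config.target in panel.trait_names:
        target = panel.trait_index(config.target)
    else:
        target = int(config.target) - 1          # user-facing positions are 1-based
        if not 0 <= target < panel.n_traits:
            raise ValueError(f"target position {config.target} outside 1..{panel.n_traits}")

    k = config.k if config.k is not None else selection_differential(config.intensity)
    log = {
        "input_mode": "trial" if config.trial_path else "matrices",
        "basis": config.basis,
        "target_trait": panel.trait_names[target],
        "intensity": config.intensity,
        "k": k,
        "stepwise_sle": config.sle,
        "stepwise_sls": config.sls,
        "methods": list(config.methods),
        "schemes": list(config.schemes),
    }

    coef_cols, criteria_rows, score_sets, labels, selections = {}, [], [], [], []
    for scheme in config.schemes:
        a = _resolve_weights(scheme, config, panel, target, weight_table)
        for method in config.methods:
            w = None if method == "pesek_baker" else a
            sim = SelectionIndex(panel, P=P, G=G, method=method, weights=w,
                                 target=target, allow_pinv=config.allow_pinv)
            res = sim.fit(intensity=config.intensity, k=config.k)
            label = f"{method}.{scheme}" if method != "pesek_baker" else "pesek_baker.desired_gains"
            if label in coef_cols:      # pesek_baker is scheme-independent
                continue
            coef_cols[label] = res.params
            criteria_rows.append(res.criteria.as_series(4).rename(label))
            res.ranking().to_csv(outdir / f"scores_{label}.csv", index=False)
            score_sets.append(res.scores)
            labels.append(label)
            selections.append({"index": label,
                               "selected": ";".join(res.select())})
            logger.info("fitted %s: R_HI=%.4f dH=%.4f", label,
                        res.criteria.R_HI, res.criteria.delta_H)

    pd.DataFrame(coef_cols, index=panel.trait_names).to_csv(outdir / "coefficients.csv")
    pd.DataFrame(criteria_rows).to_csv(outdir / "criteria.csv")
    pd.DataFrame(selections).to_csv(outdir / "selection.csv", index=False)
    R = index_score_correlation(score_sets)
    pd.DataFrame(R, index=labels, columns=labels).to_csv(outdir / "index_correlations.csv")
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return outdir
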