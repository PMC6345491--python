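"""WAIC computation and the global-to-reduced covariate selection rule.

Model selection follows a two-stage protocol: fit a global model with
every candidate covariate, then refit a reduced model that keeps only the
covariates whose coefficients show posterior evidence of an effect — at
least one coefficient with a 50% credible interval excluding zero.
Categorical covariates are kept or dropped as whole dummy blocks, since
removing individual levels would silently change the reference coding.
Global and reduced models are then ranked by WAIC.

WAIC here uses the variance penalty (pWAIC2):

    lppd   = sum_i log( mean_s exp(log L_is) )
    p_waic = sum_i var_s(log L_is)        (sample variance, S - 1)
    WAIC   = -2 (lppd - p_waic)

with log L_is the integrated (latent state marginalized) site likelihood
of site-unit i at draw s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_data import ModelSpec
from .mcmc_inference import FitResult

__all__ = ["WAICResult", "waic", "reduce_model", "compare", "format_comparison"]


@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray
    n_sites: int


def waic(pointwise: np.ndarray) -> WAICResult:
    """WAIC from a (draws x site-units) matrix of pointwise log-likelihoods."""
    pointwise = np.asarray(pointwise, dtype=float)
    if pointwise.ndim != 2:
        raise ValueError("pointwise log-likelihood must be a 2-D matrix")
    n_draws, n_sites = pointwise.shape
    if n_draws < 2:
        raise ValueError("WAIC needs at least two draws (variance undefined)")
    lppd_i = logsumexp(pointwise, axis=0) - np.log(n_draws)
    p_i = pointwise.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WAICResult(
        lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic),
        pointwise_lppd=lppd_i, pointwise_p=p_i, n_sites=n_sites,
    )


def _kept_covariates(summary: pd.DataFrame, blocks: dict[str, list[int]],
                     prefix: str, names: list[str]) -> list[str]:
    kept = []
    for cov, cols in blocks.items():
        for idx in cols:
            row = summary.loc[f"{prefix}:{names[idx]}"]
            if row["lo50"] > 0 or row["hi50"] < 0:
                kept.append(cov)
                break
    return kept


def reduce_model(global_fit: FitResult,
                 global_spec: ModelSpec | None = None) -> ModelSpec:
    """Drop every covariate whose 50% credible intervals all straddle zero.

    A covariate survives if any of its coefficients (a categorical
    covariate owns one per non-reference level) has a 50% interval
    excluding 0. Intercepts are always retained. Applied independently to
    the occupancy and detection covariate lists; idempotent given the
    same fit.
    """
    spec = global_spec or global_fit.spec
    design = global_fit.design
    summary = global_fit.summary
    for col in ("lo50", "hi50"):
        if col not in summary.columns:
            raise ValueError("fit summary lacks 50% credible intervals")
    occ = _kept_covariates(summary, design.x_blocks, "occ", design.x_columns)
    det = _kept_covariates(summary, design.w_blocks, "det", design.w_columns)
    occ = [c for c in spec.occupancy_covariates if c in occ]
    det = [c for c in spec.detection_covariates if c in det]
    return ModelSpec(occupancy_covariates=occ, detection_covariates=det,
                     species=spec.species)


def compare(fits: list[tuple[str, WAICResult, int]]) -> pd.DataFrame:
    """Rank models by WAIC; ties broken toward fewer parameters K.

    All models must have been fit to the same site-units.
    """
    if not fits:
        raise ValueError("no models to compare")
    n_sites = {w.n_sites for _, w, _ in fits}
    if len(n_sites) != 1:
        raise ValueError(
            f"models were fit to different site-unit sets: {sorted(n_sites)}"
        )
    rows = [{"model": name, "K": k, "lppd": w.lppd, "p_waic": w.p_waic,
             "WAIC": w.waic} for name, w, k in fits]
    df = pd.DataFrame(rows).sort_values(["WAIC", "K"], kind="stable")
    df["dWAIC"] = df["WAIC"] - df["WAIC"].iloc[0]
    df["best"] = False
    df.iloc[0, df.columns.get_loc("best")] = True
    return df.reset_index(drop=True)


def format_comparison(table: pd.DataFrame,
                      specs: dict[str, ModelSpec] | None = None) -> str:
    """Human-readable comparison table (model, covariates, K, WAIC, dWAIC)."""
    lines = [f"{'Model':<16}{'K':>4}{'WAIC':>10}{'dWAIC':>8}"]
    for _, row in table.iterrows():
        lines.append(f"{row['model']:<16}{row['K']:>4}"
                     f"{row['WAIC']:>10.1f}{row['dWAIC']:>8.2f}")
        if specs and row["model"] in specs:
            s = specs[row["model"]]
            lines.append(f"    occupancy: {', '.join(s.occupancy_covariates) or '(intercept only)'}")
            lines.append(f"    detection: {', '.join(s.detection_covariates) or '(intercept only)'}")
    return "\n".join(lines)
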