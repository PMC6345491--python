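"""Apparent species richness and its Poisson log-linear model.

Apparent richness is the count of distinct species detected at a wetland
in one winter, uncorrected for detection probability; the wetland-year,
not the point count, is the replication unit. Richness is modeled as
Poisson with log mean linear in wetland type (ACEP vs reference), wetland
size (standardized) and survey year. The fit is by iteratively reweighted
least squares (IRLS), the canonical Fisher scoring algorithm for the
log-link Poisson GLM, with Wald z tests from the asymptotic normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_data import RichnessTable, ValidationError

__all__ = ["GLMResult", "compute_apparent_richness", "poisson_irls",
           "fit_poisson_glm", "format_glm_report"]


@dataclass
class GLMResult:
    coefficients: pd.Series        # log scale
    std_errors: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    deviance: float
    fitted: np.ndarray
    n_iter: int
    encoding_record: dict

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.coefficients,
            "std_error": self.std_errors,
            "z": self.z_values,
            "p_value": self.p_values,
        })


def compute_apparent_richness(detections: pd.DataFrame) -> RichnessTable:
    """Distinct-species counts per wetland-year from a long presence table.

    ``detections`` needs columns ``wetland_id, year, species`` and, for the
    downstream model, ``type`` and ``size`` (constant within wetland).
    Duplicate (wetland, year, species) records count once. Wetlands present
    in the table but with no species records (species NaN) count zero.
    """
    req = {"wetland_id", "year", "species"}
    missing = req - set(detections.columns)
    if missing:
        raise ValidationError(f"presence table missing column(s) {sorted(missing)}")
    grp = detections.groupby(["wetland_id", "year"], sort=True)
    rich = grp["species"].nunique(dropna=True).rename("richness").reset_index()
    for extra in ("type", "size"):
        if extra in detections.columns:
            vals = grp[extra].first().reset_index(drop=True)
            rich[extra] = vals
        else:
            rich[extra] = np.nan
    rich["year"] = rich["year"].astype(str)
    table = RichnessTable(rich[["wetland_id", "year", "type", "size",
                                "richness"]].copy())
    return table


def poisson_irls(X: np.ndarray, y: np.ndarray, names: list[str],
                 tol: float = 1e-10, max_iter: int = 100) -> GLMResult:
    """Log-link Poisson regression by IRLS.

    Converges when the relative deviance change drops below ``tol``.
    Raises on rank-deficient designs (e.g. duplicated columns) and on
    non-convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValidationError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("design matrix is rank deficient")

    beta = np.zeros(k)
    beta[0] = np.log(max(y.mean(), 1e-8))  # start at the null model
    dev = np.inf
    trace = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(eta)
        # working response for the log link; weights = mu
        zz = eta + (y - mu) / mu
        WX = X * mu[:, None]
        beta_new, *_ = np.linalg.lstsq(np.sqrt(mu)[:, None] * X,
                                       np.sqrt(mu) * zz, rcond=None)
        beta = beta_new
        mu = np.exp(X @ beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        new_dev = 2.0 * float(dev_terms.sum())
        trace.append(new_dev)
        if np.isfinite(dev) and abs(dev - new_dev) <= tol * (abs(new_dev) + tol):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise RuntimeError(f"IRLS failed to converge; deviance trace: {trace}")

    mu = np.exp(X @ beta)
    info = X.T @ (X * mu[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    from scipy.stats import norm
    p = 2.0 * norm.sf(np.abs(z))
    idx = pd.Index(names)
    return GLMResult(
        coefficients=pd.Series(beta, index=idx),
        std_errors=pd.Series(se, index=idx),
        z_values=pd.Series(z, index=idx),
        p_values=pd.Series(p, index=idx),
        deviance=dev, fitted=mu, n_iter=it, encoding_record={},
    )


def fit_poisson_glm(rt: RichnessTable) -> GLMResult:
    """Fit richness ~ wetland type + standardized size + year."""
    df = rt.data
    if df[["type", "size", "year"]].isna().any().any():
        raise ValidationError("richness table has missing covariates")
    size = df["size"].to_numpy(dtype=float)
    mean, sd = float(size.mean()), float(size.std(ddof=1))
    if sd == 0:
        raise ValidationError("wetland size has zero variance")
    size_z = (size - mean) / sd
    type_ref = (df["type"].astype(str) == "reference").to_numpy(dtype=float)
    years = sorted(df["year"].astype(str).unique())
    if len(years) > 2:
        raise ValidationError("expected at most two survey years")
    year2 = (df["year"].astype(str) == years[-1]).to_numpy(dtype=float) \
        if len(years) == 2 else None

    cols = [np.ones(len(df)), type_ref, size_z]
    names = ["(Intercept)", "type[reference]", "size"]
    if year2 is not None:
        cols.append(year2)
        names.append(f"year[{years[-1]}]")
    X = np.column_stack(cols)
    y = df["richness"].to_numpy(dtype=float)
    result = poisson_irls(X, y, names)
    result.encoding_record = {
        "size": {"kind": "continuous", "mean": mean, "sd": sd},
        "type": {"kind": "categorical", "reference": "ACEP"},
        "year": {"kind": "categorical", "reference": years[0]},
    }
    return result


def format_glm_report(result: GLMResult) -> str:
    """One-page text report of the richness model coefficients."""
    lines = ["Poisson GLM of apparent species richness",
             "(log link; size standardized; references: type=ACEP, first year)",
             ""]
    lines.append(f"{'term':<18}{'estimate':>10}{'SE':>8}{'z':>8}{'p':>10}")
    for term in result.coefficients.index:
        p = result.p_values[term]
        ptxt = "<0.01" if p < 0.01 else f"{p:.3f}"
        lines.append(
            f"{term:<18}{result.coefficients[term]:>10.3f}"
            f"{result.std_errors[term]:>8.3f}{result.z_values[term]:>8.2f}"
            f"{ptxt:>10}"
        )
    lines.append("")
    lines.append(f"residual deviance: {result.deviance:.2f} "
                 f"(IRLS iterations: {result.n_iter})")
    return "\n".join(lines)
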