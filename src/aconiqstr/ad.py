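"""Applicability domain of a QSTR model: Williams-plot quantities.

Leverage h_i is the i-th diagonal of the hat matrix H = X (X'X)^-1 X' built
from the model design (here an intercept column plus the PLS latent scores,
the standard choice when the raw descriptor matrix is rank-deficient).
Compounds with |standardized residual| > 3 sigma are outliers; compounds
with h above the critical leverage h* = 3p/n (p = number of model variables
plus one) are outside the domain in descriptor space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pls import PLSModel, QSTRDataset

SIGMA_CUTOFF = 3.0


def leverages(design: np.ndarray) -> np.ndarray:
    """Diagonal of the hat matrix H = X (X'X)^-1 X' of a full-rank design."""
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than columns (n={n}, p={p})")
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) < p:
        raise ValueError(
            "rank-deficient design; use the latent-score design [1 | T] instead of raw columns"
        )
    return np.einsum("ij,ji->i", X, np.linalg.solve(gram, X.T))


def critical_leverage(p: int, n: int) -> float:
    """h* = 3p/n with p = model variables + 1."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 * p / n


def standardized_residuals(residuals: np.ndarray) -> np.ndarray:
    """Residuals in units of their own standard deviation (ddof=1); an
    all-zero residual vector standardizes to zeros."""
    residuals = np.asarray(residuals, dtype=float)
    sd = residuals.std(ddof=1)
    if sd <= 1e-300:
        return np.zeros_like(residuals)
    return residuals / sd


def williams_report(model: PLSModel, dataset: QSTRDataset) -> pd.DataFrame:
    """Leverage / standardized-residual table with outlier and
    high-leverage flags for every training compound.

    The design matrix is [1 | latent scores]; p = n_components + 1.
    """
    T = model.scores
    n = T.shape[0]
    design = np.hstack([np.ones((n, 1)), T])
    h = leverages(design)
    p = model.n_components + 1
    h_star = critical_leverage(p, n)
    resid = dataset.y_train - model.predict(dataset.X_train)
    std_resid = standardized_residuals(resid)
    ids = [m for m, t in zip(dataset.block.molecule_ids, dataset.is_test) if not t]
    report = pd.DataFrame({
        "id": ids,
        "leverage": h,
        "std_residual": std_resid,
        "outlier": np.abs(std_resid) > SIGMA_CUTOFF,
        "high_leverage": h > h_star,
    }).set_index("id")
    report.attrs["h_star"] = h_star
    report.attrs["p"] = p
    return report


def summary(report: pd.DataFrame) -> dict:
    return {
        "h_star": float(report.attrs["h_star"]),
        "p": int(report.attrs["p"]),
        "n": int(len(report)),
        "n_outliers": int(report["outlier"].sum()),
        "n_high_leverage": int(report["high_leverage"].sum()),
        "outliers": list(report.index[report["outlier"]]),
        "high_leverage": list(report.index[report["high_leverage"]]),
        "all_within_3_sigma": bool((report["std_residual"].abs() <= SIGMA_CUTOFF).all()),
    }
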