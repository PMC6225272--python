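"""Partial least squares regression of toxicity on field descriptors.

A NIPALS PLS1 fit on centered (unscaled) data, with the validation
statistics customary in 3D-QSAR work: leave-one-out cross-validated q²,
fitted r², standard error of estimate SEE = sqrt(RSS/(n-c-1)), the F
statistic, predictive r² on a held-out test set, and the per-field fraction
contributions |coef|*sd used to apportion the model across field types.
The optimum number of latent components (ONC) is the q²-argmax of a
component scan; LOO is done by exact refitting (one model per left-out
compound), which is the transparent equivalent of covariance-shortcut LOO.

A model is conventionally called acceptable when q² > 0.5 and r² > 0.6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import FieldBlock

Q2_GOOD = 0.5
R2_GOOD = 0.6


@dataclass
class QSTRDataset:
    """Field block plus activities (pLD50) and a train/test split flag."""

    block: FieldBlock
    y: np.ndarray
    is_test: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.is_test = np.asarray(self.is_test, dtype=bool)
        n = self.block.matrix.shape[0]
        if self.y.shape != (n,) or self.is_test.shape != (n,):
            raise ValueError("y and is_test must have one entry per molecule")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite activity values")

    @property
    def X_train(self) -> np.ndarray:
        return self.block.matrix[~self.is_test]

    @property
    def y_train(self) -> np.ndarray:
        return self.y[~self.is_test]

    @property
    def n_train(self) -> int:
        return int((~self.is_test).sum())

    def train_subset(self, keep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.X_train[keep], self.y_train[keep]


def split_3to1(y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seeded 3:1 train/test split stratified by activity: sort by y, walk in
    blocks of four, and hold out one random member of each block."""
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    order = np.argsort(y)
    is_test = np.zeros(len(y), dtype=bool)
    for start in range(0, len(y), 4):
        chunk = order[start:start + 4]
        if len(chunk) == 4:
            is_test[rng.choice(chunk)] = True
    return is_test


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # (p, c) NIPALS weights
    loadings: np.ndarray   # (p, c) X loadings
    scores: np.ndarray     # (n, c) training latent scores
    y_loadings: np.ndarray  # (c,)
    coefficients: np.ndarray  # (p,)
    stats: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean + (np.asarray(X, dtype=float) - self.x_mean) @ self.coefficients

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Latent scores of new rows under the fitted decomposition."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        T = np.zeros((Xc.shape[0], self.n_components))
        for k in range(self.n_components):
            t = Xc @ self.weights[:, k]
            T[:, k] = t
            Xc = Xc - np.outer(t, self.loadings[:, k])
        return T

    @property
    def is_good(self) -> bool:
        return self.stats.get("q2", -np.inf) > Q2_GOOD and self.stats.get("r2", -np.inf) > R2_GOOD

    def to_json(self, path) -> None:
        payload = {
            "n_components": self.n_components,
            "stats": {k: (None if v is None else float(v)) if not isinstance(v, dict)
                      else {kk: float(vv) for kk, vv in v.items()}
                      for k, v in self.stats.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    X_work = Xc.copy()
    y_work = yc.copy()
    for k in range(n_components):
        w = X_work.T @ y_work
        norm = np.linalg.norm(w)
        if norm <= 1e-300:
            raise ValueError(
                f"degenerate X: no residual covariance at component {k + 1}"
            )
        w /= norm
        t = X_work @ w
        tt = t @ t
        if tt <= 1e-300:
            raise ValueError(f"degenerate score vector at component {k + 1}")
        pvec = X_work.T @ t / tt
        qk = y_work @ t / tt
        X_work = X_work - np.outer(t, pvec)
        y_work = y_work - qk * t
        W[:, k], P[:, k], T[:, k], q[k] = w, pvec, t, qk
    return W, P, T, q


def fit_pls(dataset: QSTRDataset, n_components: int) -> PLSModel:
    """Fit a PLS1 model on the training rows with ``n_components`` latent
    variables (NIPALS, centered, unscaled)."""
    X, y = dataset.X_train, dataset.y_train
    n = X.shape[0]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n <= n_components:
        raise ValueError(f"need n_train > n_components ({n} <= {n_components})")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    if np.allclose(Xc, 0.0):
        raise ValueError("degenerate X: zero variance after centering")
    W, P, T, q = _nipals(Xc, y - y_mean, n_components)
    coef = W @ np.linalg.solve(P.T @ W, q)
    model = PLSModel(n_components, x_mean, y_mean, W, P, T, q, coef)
    model.stats.update(model_stats(model, dataset))
    return model


def model_stats(model: PLSModel, dataset: QSTRDataset) -> dict:
    """Training-set r², SEE and F for a fitted model.

    SEE = sqrt(RSS/(n-c-1)); F = (r²/c) / ((1-r²)/(n-c-1)). A perfect fit
    reports SEE 0 and F +inf.
    """
    y = dataset.y_train
    n, c = len(y), model.n_components
    if n <= c + 1:
        raise ValueError("need n_train > n_components + 1 for SEE/F")
    resid = y - model.predict(dataset.X_train)
    rss = float(resid @ resid)
    ss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss
    see = float(np.sqrt(rss / (n - c - 1)))
    if 1.0 - r2 <= 1e-12:
        f_stat = float("inf")
    else:
        f_stat = (r2 / c) / ((1.0 - r2) / (n - c - 1))
    return {"r2": r2, "see": see, "f": f_stat, "n_train": n}


def loo_q2(dataset: QSTRDataset, n_components: int) -> float:
    """Leave-one-out cross-validated q² = 1 - PRESS/SS on the training set.

    Each training compound is predicted by a model refit without it, at the
    same component count; SS is the total sum of squares about the training
    mean. Implemented as n exact refits.
    """
    X, y = dataset.X_train, dataset.y_train
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 training compounds")
    if n_components >= n - 1:
        raise ValueError("n_components must be < n_train - 1 for LOO")
    press = 0.0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = QSTRDataset(
            FieldBlock(X[keep], list(dataset.block.column_meta),
                       [f"m{j}" for j in range(int(keep.sum()))]),
            y[keep], np.zeros(int(keep.sum()), dtype=bool))
        model = fit_pls(sub, n_components)
        pred = model.predict(X[i:i + 1])[0]
        press += (y[i] - pred) ** 2
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss


def select_components(dataset: QSTRDataset, max_components: int = 10,
                      tie_tol: float = 0.005) -> int:
    """Optimum number of components from a LOO q² scan over
    1..max_components (clipped to the feasible range).

    Ties break toward fewer components with a parsimony tolerance: the
    smallest count whose q² comes within ``tie_tol`` of the scan maximum is
    returned, so an extra latent variable must buy a material q² gain
    (default half a percent of explained variance) to be kept.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    upper = min(max_components, dataset.n_train - 2)
    q2s = [loo_q2(dataset, c) for c in range(1, upper + 1)]
    best = max(q2s)
    for c, q2 in enumerate(q2s, start=1):
        if q2 >= best - tie_tol:
            return c
    return upper


def predictive_r2(model: PLSModel, dataset: QSTRDataset) -> float:
    """r²pred = 1 - PRESS_test / sum_test (y - mean(y_train))²."""
    if not dataset.is_test.any():
        raise ValueError("empty test set")
    X_test = dataset.block.matrix[dataset.is_test]
    y_test = dataset.y[dataset.is_test]
    ybar = dataset.y_train.mean()
    denom = float(((y_test - ybar) ** 2).sum())
    press = float(((y_test - model.predict(X_test)) ** 2).sum())
    if denom <= 1e-300:
        return float("-inf")  # undefined: test activities equal the training mean
    return 1.0 - press / denom


def field_fractions(model: PLSModel, block: FieldBlock) -> dict[str, float]:
    """Per-field fraction contributions: sum over the field's columns of
    |coef|*sd, normalized over all columns."""
    sd = block.matrix.std(axis=0, ddof=0)
    contrib = np.abs(model.coefficients) * sd
    total = contrib.sum()
    fractions = {}
    for name in block.field_names:
        idx = block.columns_for(name)
        fractions[name] = float(contrib[idx].sum() / total) if total > 0 else 0.0
    return fractions


def contour_grid(model: PLSModel, block: FieldBlock, field_name: str,
                 lo_pct: float = 20.0, hi_pct: float = 80.0):
    """Per-grid-point sd*coef values for one field plus the disfavored and
    favored iso-levels at the lo/hi percentiles of the nonzero values."""
    idx = block.columns_for(field_name)
    sd = block.matrix[:, idx].std(axis=0, ddof=0)
    values = sd * model.coefficients[idx]
    grid_idx = np.array([block.column_meta[j][0] for j in idx])
    nonzero = values[values != 0.0]
    if nonzero.size == 0:
        return {"grid_index": grid_idx, "value": values, "lo_level": 0.0, "hi_level": 0.0}
    lo = float(np.percentile(nonzero, lo_pct))
    hi = float(np.percentile(nonzero, hi_pct))
    return {"grid_index": grid_idx, "value": values, "lo_level": lo, "hi_level": hi}


def evaluate(dataset: QSTRDataset, max_components: int = 10) -> PLSModel:
    """Component scan + final fit + full statistics, the one-call form used
    by the pipeline: ONC by LOO q², then r²/SEE/F, r²pred (if a test set is
    flagged) and field fractions."""
    onc = select_components(dataset, max_components)
    model = fit_pls(dataset, onc)
    model.stats["q2"] = loo_q2(dataset, onc)
    model.stats["onc"] = onc
    if dataset.is_test.any():
        model.stats["r2_pred"] = predictive_r2(model, dataset)
    model.stats["field_fractions"] = field_fractions(model, dataset.block)
    return model


def predictions_frame(model: PLSModel, dataset: QSTRDataset) -> pd.DataFrame:
    pred = model.predict(dataset.block.matrix)
    return pd.DataFrame({
        "id": dataset.block.molecule_ids,
        "pld50": dataset.y,
        "predicted": pred,
        "residual": dataset.y - pred,
        "is_test": dataset.is_test,
    }).set_index("id")
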