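"""Shrinkage Gaussian graphical model: partial correlations for p >> n.

The sample correlation matrix R is shrunk toward the identity target,
R* = lambda* I + (1 - lambda*) R, with the analytic shrinkage intensity

    lambda* = sum_{i!=j} Var_hat(r_ij) / sum_{i!=j} r_ij^2

(Schafer-Strimmer estimator; Var_hat(r_ij) from the empirical variance of
the per-sample products of standardized scores). R* is positive definite
for any lambda* > 0 even when features outnumber samples, so the partial
correlations follow from its inverse Omega:

    rho_ij = -omega_ij / sqrt(omega_ii * omega_jj).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ShrinkageFit:
    lambda_star: float
    n_samples: int
    n_features: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_star <= 1.0:
            raise ValueError("lambda_star must lie in [0, 1]")


@dataclass
class PartialCorrelationMatrix:
    """Symmetric feature x feature matrix of partial correlations, unit
    diagonal, entries in [-1, 1]."""

    rho: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.rho.to_numpy()
        if vals.shape[0] != vals.shape[1]:
            raise ValueError("rho must be square")
        if not np.allclose(vals, vals.T, atol=1e-8):
            raise ValueError("rho must be symmetric")
        if np.abs(vals).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("rho entries must lie in [-1, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.rho.columns)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal values (each unordered pair once)."""
        vals = self.rho.to_numpy()
        iu = np.triu_indices_from(vals, k=1)
        return vals[iu]

    def to_long_tsv(self, path: str | Path) -> None:
        ids = self.feature_ids
        vals = self.rho.to_numpy()
        i_idx, j_idx = np.triu_indices_from(vals, k=1)
        pd.DataFrame(
            {
                "feature_i": [ids[i] for i in i_idx],
                "feature_j": [ids[j] for j in j_idx],
                "rho": vals[i_idx, j_idx],
            }
        ).to_csv(path, sep="\t", index=False)

    def to_square_tsv(self, path: str | Path) -> None:
        self.rho.to_csv(path, sep="\t")


def standardize(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Column-standardize to zero mean and unit variance (ddof=1)."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 samples")
    sd = arr.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if len(constant):
        names = (
            [X.columns[i] for i in constant[:5]]
            if isinstance(X, pd.DataFrame)
            else constant[:5].tolist()
        )
        raise ValueError(f"constant features cannot be standardized: {names}")
    return (arr - arr.mean(axis=0)) / sd


def estimate_shrinkage_intensity(X: np.ndarray) -> ShrinkageFit:
    """Analytic shrinkage intensity from a standardized sample x feature
    matrix (identity correlation target)."""
    x = np.asarray(X, dtype=float)
    n, p = x.shape
    if p < 2:
        return ShrinkageFit(0.0, n, p)
    wbar = (x.T @ x) / n  # mean over samples of w_kij = x_ki * x_kj
    r = wbar * n / (n - 1)
    sq_sum = (x**2).T @ (x**2)  # sum_k w_kij^2
    var_r = n / (n - 1) ** 3 * (sq_sum - n * wbar**2)
    iu = np.triu_indices(p, k=1)
    denom = float((r[iu] ** 2).sum())
    numer = float(var_r[iu].sum())
    lam = 1.0 if denom == 0 else numer / denom
    return ShrinkageFit(float(np.clip(lam, 0.0, 1.0)), n, p)


def partial_correlations(
    X: pd.DataFrame | np.ndarray,
    lambda_override: float | None = None,
) -> tuple[PartialCorrelationMatrix, ShrinkageFit]:
    """Shrinkage partial-correlation matrix of a raw sample x feature matrix.

    Standardization happens internally, so rescaling any feature by a
    positive constant leaves the result unchanged. ``lambda_override``
    forces the shrinkage intensity (0 reproduces the unregularized
    inversion estimator when the correlation matrix is invertible; a
    pseudo-inverse is used otherwise).
    """
    ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    x = standardize(X)
    n, p = x.shape
    fit = estimate_shrinkage_intensity(x)
    lam = fit.lambda_star if lambda_override is None else float(lambda_override)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    fit = ShrinkageFit(lam, n, p)

    r_sample = (x.T @ x) / (n - 1)
    np.fill_diagonal(r_sample, 1.0)
    r_star = lam * np.eye(p) + (1.0 - lam) * r_sample
    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError:
        omega = np.linalg.pinv(r_star)
    if lam == 0.0 and p > n:
        omega = np.linalg.pinv(r_star)

    d = np.sqrt(np.abs(np.diag(omega)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = -omega / np.outer(d, d)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    if ids is None:
        ids = [f"V{i}" for i in range(p)]
    return PartialCorrelationMatrix(pd.DataFrame(rho, index=ids, columns=ids)), fit
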