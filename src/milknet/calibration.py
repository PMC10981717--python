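"""Empirical-Bayes edge calibration: two-group mixture over partial
correlations and local false discovery rates.

Observed off-diagonal partial correlations r are modeled as a mixture

    f(r) = eta0 * f0(r; kappa) + (1 - eta0) * fA(r),

where the null density is the sampling law of a vanishing partial
correlation with kappa effective degrees of freedom,

    f0(r; kappa) = Gamma(kappa/2) / (sqrt(pi) Gamma((kappa-1)/2))
                   * (1 - r^2)^((kappa-3)/2),

equivalently r^2 ~ Beta(1/2, (kappa-1)/2). kappa is fit empirically
(for p > n the nominal n - p + 1 is meaningless), eta0 by central-mass
matching, and the marginal f by kernel density estimation. The local fdr
of an edge is the posterior probability that it arose from the null:
lfdr(r) = eta0 * f0(r) / f(r); an edge is drawn when lfdr < 0.1,
i.e. when its "presence probability" 1 - lfdr exceeds 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.isotonic import IsotonicRegression

from .ggm import PartialCorrelationMatrix

KAPPA_FALLBACK = 1000.0
_GRID_SIZE = 2001
_EPS = 1e-12


@dataclass
class NullMixtureFit:
    """Fitted two-group mixture over off-diagonal partial correlations."""

    eta0: float
    kappa: float
    grid_r: np.ndarray
    grid_f: np.ndarray  # tabulated mixture density f_hat on grid_r

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta0 <= 1.0:
            raise ValueError("eta0 must lie in [0, 1]")
        if self.kappa <= 3.0:
            raise ValueError("kappa must exceed 3")

    def f0(self, r: np.ndarray) -> np.ndarray:
        return np.exp(null_logpdf(np.asarray(r, dtype=float), self.kappa))

    def fhat(self, r: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(r, dtype=float), self.grid_r, self.grid_f)


def null_logpdf(r: np.ndarray, kappa: float) -> np.ndarray:
    logc = (
        special.gammaln(kappa / 2.0)
        - 0.5 * np.log(np.pi)
        - special.gammaln((kappa - 1.0) / 2.0)
    )
    r2 = np.clip(np.asarray(r, dtype=float) ** 2, 0.0, 1.0 - 1e-15)
    return logc + (kappa - 3.0) / 2.0 * np.log1p(-r2)


def null_central_mass(b: float, kappa: float) -> float:
    """P(|r| <= b) under the null: r^2 ~ Beta(1/2, (kappa-1)/2)."""
    return float(special.betainc(0.5, (kappa - 1.0) / 2.0, min(b * b, 1.0)))


def _fit_kappa(rhos: np.ndarray, cutoff: float) -> float:
    """Truncated maximum likelihood on the central body |r| < cutoff."""
    central = rhos[np.abs(rhos) < cutoff]
    if len(central) < 10:
        return KAPPA_FALLBACK
    log1m = np.log1p(-np.clip(central**2, 0.0, 1.0 - 1e-15))
    s = float(log1m.sum())
    m = len(central)

    def nll(t: float) -> float:
        kappa = 3.0 + np.exp(t)
        logc = (
            special.gammaln(kappa / 2.0)
            - 0.5 * np.log(np.pi)
            - special.gammaln((kappa - 1.0) / 2.0)
        )
        mass = max(null_central_mass(cutoff, kappa), _EPS)
        return -(m * logc + (kappa - 3.0) / 2.0 * s - m * np.log(mass))

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(1e-2), np.log(1e7)), method="bounded"
    )
    return float(3.0 + np.exp(res.x))


def _mixture_density(rhos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE on [-1, 1] with boundary reflection, Silverman bandwidth."""
    grid = np.linspace(-1.0, 1.0, _GRID_SIZE)
    if np.std(rhos) < 1e-12:
        f = np.zeros(_GRID_SIZE)
        f[np.argmin(np.abs(grid - float(np.mean(rhos))))] = 1.0 / (grid[1] - grid[0])
        return grid, f
    kde = stats.gaussian_kde(rhos, bw_method="silverman")
    f = kde(grid) + kde(2.0 - grid) + kde(-2.0 - grid)
    f /= np.trapezoid(f, grid)
    return grid, np.maximum(f, _EPS)


def fit_null_mixture(rhos: np.ndarray) -> NullMixtureFit:
    """Fit (eta0, kappa, f_hat) from off-diagonal partial correlations.

    kappa: truncated MLE of the null density on the central body of the
    distribution (|r| below its 90th percentile). eta0: ratio of observed
    to null mass over the f0 central-quartile neighborhood of zero,
    clipped to [0, 1]. f_hat: reflected Gaussian KDE.
    """
    rhos = np.asarray(rhos, dtype=float).ravel()
    if len(rhos) < 100:
        warnings.warn(
            f"only {len(rhos)} partial correlations; mixture fit is unstable",
            stacklevel=2,
        )
    absr = np.abs(rhos)
    if len(rhos) == 0 or absr.max(initial=0.0) < 1e-12:
        grid = np.linspace(-1.0, 1.0, _GRID_SIZE)
        return NullMixtureFit(1.0, KAPPA_FALLBACK, grid, np.full(_GRID_SIZE, 0.5))

    cutoff = float(np.quantile(absr, 0.9))
    if cutoff <= 0:
        cutoff = float(absr.max())
    kappa = _fit_kappa(rhos, cutoff)

    # eta0 by central-mass matching: the f0 central quartile around zero
    delta2 = special.betaincinv(0.5, (kappa - 1.0) / 2.0, 0.25)
    delta = float(np.sqrt(delta2))
    observed_mass = float(np.mean(absr <= delta))
    eta0 = float(np.clip(observed_mass / 0.25, 0.0, 1.0))

    grid, f = _mixture_density(rhos)
    return NullMixtureFit(eta0, kappa, grid, f)


def local_fdr(rhos: np.ndarray, fit: NullMixtureFit) -> np.ndarray:
    """lfdr(r) = min(1, eta0 f0(r) / f_hat(r)), made non-increasing in |r|
    by isotonic post-processing."""
    rhos = np.asarray(rhos, dtype=float)
    raw = np.clip(fit.eta0 * fit.f0(rhos) / np.maximum(fit.fhat(rhos), _EPS), 0.0, 1.0)
    if len(rhos) < 2:
        return raw
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False, out_of_bounds="clip")
    return iso.fit_transform(np.abs(rhos), raw)


def significant_edges(
    pcm: PartialCorrelationMatrix,
    threshold: float = 0.1,
    fit: NullMixtureFit | None = None,
) -> pd.DataFrame:
    """EdgeList over all unordered feature pairs.

    Columns: feature_i, feature_j, rho, local_fdr, significant. An edge is
    significant iff its local fdr is strictly below ``threshold``
    (presence probability > 1 - threshold).
    """
    ids = pcm.feature_ids
    vals = pcm.rho.to_numpy()
    i_idx, j_idx = np.triu_indices_from(vals, k=1)
    rhos = vals[i_idx, j_idx]
    if fit is None:
        fit = fit_null_mixture(rhos)
    lfdr = local_fdr(rhos, fit)
    return pd.DataFrame(
        {
            "feature_i": [ids[i] for i in i_idx],
            "feature_j": [ids[j] for j in j_idx],
            "rho": rhos,
            "local_fdr": lfdr,
            "significant": lfdr < threshold,
        }
    )


def edge_density_percent(n_edges: int, n_nodes: int) -> float:
    """Network density as a percentage of all possible node pairs,
    rounded to one decimal."""
    if n_nodes < 2:
        return 0.0
    return round(100.0 * n_edges / (n_nodes * (n_nodes - 1) / 2.0), 1)


def network_summary(edges: pd.DataFrame, kinds: pd.Series) -> dict:
    """Edge/node counts, density, and same-kind edge percentage of the
    significant-edge network."""
    sig = edges[edges["significant"]]
    n_edges = int(len(sig))
    nodes = sorted(set(sig["feature_i"]) | set(sig["feature_j"]))
    n_nodes = len(nodes)
    if n_edges:
        same = (
            kinds.loc[sig["feature_i"]].to_numpy()
            == kinds.loc[sig["feature_j"]].to_numpy()
        )
        same_pct = round(100.0 * float(same.mean()), 1)
    else:
        same_pct = 0.0
    node_kinds = kinds.loc[nodes] if n_nodes else kinds.iloc[:0]
    return {
        "n_edges": n_edges,
        "n_nodes": n_nodes,
        "n_protein_nodes": int((node_kinds == "protein").sum()),
        "n_peptide_nodes": int((node_kinds == "peptide").sum()),
        "density_percent": edge_density_percent(n_edges, n_nodes),
        "same_kind_percent": same_pct,
    }


def write_edges_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.rename(columns={"feature_i": "source", "feature_j": "target"}).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    import networkx as nx

    g = nx.Graph()
    for row in edges[edges["significant"]].itertuples():
        g.add_edge(row.feature_i, row.feature_j, rho=float(row.rho), weight=abs(float(row.rho)))
    nx.write_graphml(g, str(path))
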