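"""Reading MaxQuant-dialect tables, prevalence filtering, outlier flagging,
and left-censored (MNAR) imputation.

The filtering rules implement the study design for ~300-sample milk
cohorts: drop contaminant/reverse entries, keep features identified in
strictly more than half of the samples, drop samples whose total peptide
signal is several orders of magnitude above the rest, then impute the
remaining left-censored missing values on the log2 scale.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PEPTIDE, PROTEIN, AbundanceTable

PROTEIN_GROUPS_DIALECT = "proteinGroups"
PEPTIDES_DIALECT = "peptides"

_REQUIRED = {
    PROTEIN_GROUPS_DIALECT: ["Majority protein IDs"],
    PEPTIDES_DIALECT: ["Sequence", "Proteins", "Start position", "End position"],
}
_PREFIX = {PROTEIN_GROUPS_DIALECT: "LFQ intensity ", PEPTIDES_DIALECT: "Intensity "}


def read_maxquant_table(
    path: str | Path,
    dialect: str,
    intensity_prefix: str | None = None,
) -> AbundanceTable:
    """Parse a proteinGroups- or peptides-like TSV into an AbundanceTable.

    MaxQuant writes zero where a feature was not quantified in a sample;
    those cells are recorded as missing. Contaminant/reverse rows follow
    the "+" flag convention and are kept (flagged in meta) for
    :func:`filter_features` to drop.
    """
    if dialect not in _REQUIRED:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"Reverse": str, "Potential contaminant": str})
    for col in _REQUIRED[dialect]:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    prefix = intensity_prefix or _PREFIX[dialect]
    intensity_cols = [c for c in df.columns if c.startswith(prefix)]
    if not intensity_cols:
        raise ValueError(f"zero samples detected: no columns start with {prefix!r}")
    sample_ids = [c[len(prefix):] for c in intensity_cols]

    if dialect == PROTEIN_GROUPS_DIALECT:
        feature_ids = df["Majority protein IDs"].astype(str).tolist()
        meta = pd.DataFrame(
            {
                "gene_name": df.get("Gene names", pd.Series(feature_ids)).astype(str).tolist(),
            },
            index=feature_ids,
        )
        kind = PROTEIN
    else:
        seqs = df["Sequence"].astype(str)
        prec = df["Proteins"].astype(str)
        feature_ids = [
            f"{p}|{int(s)}-{int(e)}"
            for p, s, e in zip(prec, df["Start position"], df["End position"])
        ]
        meta = pd.DataFrame(
            {
                "sequence": seqs.tolist(),
                "precursor_accession": prec.tolist(),
                "start": df["Start position"].astype(int).tolist(),
                "end": df["End position"].astype(int).tolist(),
                "gene_name": prec.tolist(),
            },
            index=feature_ids,
        )
        kind = PEPTIDE
    meta["is_contaminant"] = _parse_plus(df.get("Potential contaminant"))
    meta["is_reverse"] = _parse_plus(df.get("Reverse"))

    values = df[intensity_cols].to_numpy(dtype=float).T  # samples x features
    mask = values == 0.0
    intensities = pd.DataFrame(
        np.where(mask, np.nan, values), index=sample_ids, columns=feature_ids
    )
    return AbundanceTable(
        intensities=intensities,
        mask=pd.DataFrame(mask, index=sample_ids, columns=feature_ids),
        kind=pd.Series(kind, index=feature_ids),
        meta=meta,
    )


def _parse_plus(col: pd.Series | None) -> list[bool]:
    if col is None:
        return []
    return [str(v).strip() == "+" for v in col.fillna("")]


def filter_features(
    table: AbundanceTable, min_present_fraction: float = 0.5, strict: bool = True
) -> AbundanceTable:
    """Drop contaminant/reverse features, then apply the prevalence rule.

    A feature is retained when observed in strictly more than
    ``min_present_fraction`` of the samples (the ">150 of 300" rule,
    generalized). With ``strict=False`` the comparison is >=.
    """
    if table.n_features == 0:
        raise ValueError("empty table")
    keep = list(table.feature_ids)
    meta = table.meta
    for flag in ("is_contaminant", "is_reverse"):
        if flag in meta.columns:
            keep = [f for f in keep if not bool(meta.at[f, flag])]
    counts = table.presence_counts()
    cutoff = min_present_fraction * table.n_samples
    if strict:
        keep = [f for f in keep if counts[f] > cutoff]
    else:
        keep = [f for f in keep if counts[f] >= cutoff]
    if not keep:
        raise ValueError(
            "prevalence filter removed every feature; review min_present_fraction"
        )
    return table.select_features(keep)


def flag_outlier_samples(
    peptide_table: AbundanceTable, log10_margin: float = 2.0
) -> list[str]:
    """Samples whose log10 total peptide intensity exceeds the cohort median
    by at least ``log10_margin`` (operationalizing "several magnitudes")."""
    if peptide_table.n_samples < 3:
        raise ValueError("need at least 3 samples to flag outliers")
    if math.isinf(log10_margin):
        return []
    totals = peptide_table.intensities.fillna(0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        log_totals = np.log10(totals.to_numpy(dtype=float))
    median = np.median(log_totals)
    flagged = [
        s for s, lt in zip(peptide_table.sample_ids, log_totals) if lt - median >= log10_margin
    ]
    return flagged


def impute_mnar(
    table: AbundanceTable, seed: int, n_iterations: int = 10, n_predictors: int = 10
) -> AbundanceTable:
    """Impute left-censored missing values on the log2 scale.

    Initialization is quantile-regression based (QRILC-style): for each
    feature the observed values are treated as the upper ``1 - pi``
    quantiles of a censored normal (``pi`` = missing fraction), giving
    (mu, sigma) estimates from a regression of sorted observed values on
    the corresponding standard-normal quantiles; missing cells are drawn
    from that normal truncated above at the feature's observed minimum.

    A fixed number of Gibbs sweeps then refines each feature's missing
    cells: ridge regression of the feature (observed + current imputations)
    on its ``n_predictors`` most-correlated other features, redrawing the
    missing cells from the predictive normal truncated above at the
    observed minimum. Observed cells are never modified; identical seeds
    give identical output.
    """
    if table.is_complete():
        return table
    counts = table.presence_counts()
    empty = counts[counts == 0]
    if len(empty):
        raise ValueError(f"features with zero observed values: {list(empty.index[:5])}")

    rng = np.random.default_rng(seed)
    log2 = table.log2_matrix().to_numpy(dtype=float)  # samples x features, NaN missing
    mask = table.mask.to_numpy()
    n, p = log2.shape
    obs_min = np.nanmin(log2, axis=0)

    filled = log2.copy()
    for j in range(p):
        miss = mask[:, j]
        if not miss.any():
            continue
        mu, sigma = _qrilc_params(log2[~miss, j], miss.mean())
        filled[miss, j] = _draw_truncated(rng, mu, sigma, obs_min[j], miss.sum())

    missing_features = np.flatnonzero(mask.any(axis=0))
    for _ in range(n_iterations):
        corr = np.corrcoef(filled, rowvar=False) if p > 1 else np.ones((1, 1))
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        for j in missing_features:
            miss = mask[:, j]
            order = np.argsort(-np.abs(corr[:, j]))
            predictors = order[: min(n_predictors, p - 1)]
            if len(predictors) == 0:
                continue
            X = filled[:, predictors]
            y = filled[:, j]
            coef, intercept = _ridge_fit(X, y)
            pred = X @ coef + intercept
            resid_sd = float(np.std(y - pred, ddof=1)) if n > 1 else 0.0
            filled[miss, j] = _draw_truncated_vec(
                rng, pred[miss], max(resid_sd, 1e-8), obs_min[j]
            )

    out_vals = np.exp2(filled)
    intensities = pd.DataFrame(out_vals, index=table.sample_ids, columns=table.feature_ids)
    # observed cells preserved bit-exactly on the linear scale
    obs = ~table.mask
    intensities = intensities.where(~obs, table.intensities)
    return AbundanceTable(
        intensities=intensities,
        mask=pd.DataFrame(False, index=table.intensities.index, columns=table.intensities.columns),
        kind=table.kind.copy(),
        meta=table.meta.copy(),
    )


def _qrilc_params(observed: np.ndarray, missing_fraction: float) -> tuple[float, float]:
    """(mu, sigma) of the uncensored normal from censored observed values."""
    observed = np.sort(observed)
    m = len(observed)
    if m < 3:
        sd = float(np.std(observed, ddof=1)) if m > 1 else 1.0
        return float(observed.mean()), max(sd, 1e-6)
    # observed values occupy probability range (pi, 1)
    probs = missing_fraction + (1 - missing_fraction) * (np.arange(1, m + 1) - 0.5) / m
    z = stats.norm.ppf(probs)
    slope, intercept = np.polyfit(z, observed, 1)
    return float(intercept), max(float(slope), 1e-6)


def _draw_truncated(
    rng: np.random.Generator, mu: float, sigma: float, upper: float, size: int
) -> np.ndarray:
    return _draw_truncated_vec(rng, np.full(size, mu), sigma, upper)


def _draw_truncated_vec(
    rng: np.random.Generator, mu: np.ndarray, sigma: float, upper: float
) -> np.ndarray:
    b = (upper - mu) / sigma
    u = rng.uniform(0.0, 1.0, size=len(mu))
    # clip against quantile underflow when the prediction sits far above the cap
    q = np.clip(u * stats.norm.cdf(b), 1e-15, 1.0 - 1e-15)
    return np.minimum(mu + sigma * stats.norm.ppf(q), upper)


def _ridge_fit(X: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> tuple[np.ndarray, float]:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    k = X.shape[1]
    coef = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(k), Xc.T @ yc)
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return coef, intercept


def write_table_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Filtered/imputed table as TSV (features x samples, NaN for missing)."""
    table.intensities.T.to_csv(path, sep="\t")


def write_qc_report(
    path: str | Path,
    dropped_features: list[str],
    flagged_samples: list[str],
    counts: dict[str, int],
) -> None:
    payload = {
        "dropped_features": dropped_features,
        "flagged_samples": flagged_samples,
        "counts": counts,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
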