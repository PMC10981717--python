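"""Shared in-memory containers for abundance data and feature metadata.

The central object is :class:`AbundanceTable`: a samples x features intensity
matrix (linear scale, non-negative) together with a boolean missingness mask
and a per-feature kind tag (``"protein"`` or ``"peptide"``). Intensities at
masked cells are undefined and stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEIN = "protein"
PEPTIDE = "peptide"
_KINDS = {PROTEIN, PEPTIDE}


@dataclass
class AbundanceTable:
    """Samples x features intensity matrix with missingness mask.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id, columns = feature ids. Linear-scale
        non-negative values; NaN where missing.
    mask
        Boolean DataFrame, same shape/labels; True exactly where the
        intensity is undefined (missing).
    kind
        Per-feature tag, ``"protein"`` or ``"peptide"``.
    meta
        Optional per-feature metadata (indexed by feature id); columns such
        as ``gene_name``, ``is_contaminant``, ``is_reverse``, and for
        peptides ``precursor_accession``, ``sequence``, ``start``, ``end``
        (1-based inclusive, signal peptide included in the numbering).
    """

    intensities: pd.DataFrame
    mask: pd.DataFrame
    kind: pd.Series
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.intensities.columns.is_unique:
            dupes = self.intensities.columns[self.intensities.columns.duplicated()]
            raise ValueError(f"duplicate feature ids: {list(dupes[:5])}")
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask shape does not match intensities")
        self.mask = self.mask.astype(bool)
        vals = self.intensities.to_numpy(dtype=float)
        observed = ~self.mask.to_numpy(dtype=bool)
        if np.any(vals[observed] < 0):
            raise ValueError("negative intensities in observed cells")
        if np.any(np.isnan(vals[observed])):
            raise ValueError("NaN intensity in a cell not flagged missing")
        unknown = set(self.kind.unique()) - _KINDS
        if unknown:
            raise ValueError(f"unknown feature kinds: {sorted(unknown)}")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def presence_counts(self) -> pd.Series:
        """Number of samples in which each feature is observed."""
        return (~self.mask).sum(axis=0)

    def select_features(self, feature_ids) -> "AbundanceTable":
        feature_ids = list(feature_ids)
        meta = self.meta.loc[self.meta.index.intersection(feature_ids)] if len(self.meta) else self.meta
        return AbundanceTable(
            intensities=self.intensities[feature_ids].copy(),
            mask=self.mask[feature_ids].copy(),
            kind=self.kind[feature_ids].copy(),
            meta=meta.copy(),
        )

    def drop_samples(self, sample_ids) -> "AbundanceTable":
        keep = [s for s in self.sample_ids if s not in set(sample_ids)]
        return AbundanceTable(
            intensities=self.intensities.loc[keep].copy(),
            mask=self.mask.loc[keep].copy(),
            kind=self.kind.copy(),
            meta=self.meta.copy(),
        )

    def log2_matrix(self) -> pd.DataFrame:
        """log2 intensities with NaN at masked cells (downstream model scale)."""
        vals = self.intensities.where(~self.mask)
        return np.log2(vals)

    def is_complete(self) -> bool:
        return not bool(self.mask.to_numpy().any())


def combine(tables: list[AbundanceTable]) -> AbundanceTable:
    """Column-concatenate tables sharing the same samples (protein + peptide)."""
    base = tables[0]
    for t in tables[1:]:
        if list(t.sample_ids) != list(base.sample_ids):
            raise ValueError("tables do not share sample ids / order")
    return AbundanceTable(
        intensities=pd.concat([t.intensities for t in tables], axis=1),
        mask=pd.concat([t.mask for t in tables], axis=1),
        kind=pd.concat([t.kind for t in tables]),
        meta=pd.concat([t.meta for t in tables]) if any(len(t.meta) for t in tables) else pd.DataFrame(),
    )
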