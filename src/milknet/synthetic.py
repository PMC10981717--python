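"""Synthetic milk proteome/peptidome generator with known ground truth.

Emulates the statistical and biochemical structure the downstream analysis
assumes: log-normal protein abundance profiles with a planted sparse
partial-correlation (precision-matrix) block structure; peptides formed from
precursor proteins by endoproteolysis at K/R bonds plus single-residue
exoproteolytic trimming, with peptide abundance coupled to precursor
abundance; and left-censored (MNAR) missingness.

Every source of randomness flows from an explicit integer seed through a
named :class:`numpy.random.Generator`; no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PEPTIDE, PROTEIN, AbundanceTable

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# LFQ-like intensity scale: per-feature baseline log2-intensity range.
LOG2_BASELINE_RANGE = (20.0, 30.0)


@dataclass(frozen=True)
class PrecisionSpec:
    """Planted Gaussian graphical model: clusters as precision-matrix blocks.

    Features inside a block are pairwise partially correlated at
    ``within_block_pcor``; features in different blocks (and leftover
    features outside any block) are conditionally independent. A block of
    size ``k`` with constant partial correlation ``rho`` is positive
    definite only for ``rho < 1/(k-1)``.
    """

    n_features: int
    block_sizes: tuple[int, ...]
    within_block_pcor: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if not -1 < self.within_block_pcor < 1:
            raise ValueError("within_block_pcor must lie in (-1, 1)")
        if sum(self.block_sizes) > self.n_features:
            raise ValueError("blocks do not fit within n_features")


@dataclass(frozen=True)
class DigestSpec:
    """Endo- plus exoproteolytic digestion of precursor proteins.

    Endoproteolysis cuts the bond C-terminal of each residue in
    ``endo_rule`` (plasmin-like K/R specificity) independently with
    ``cleavage_prob``; each resulting fragment inside ``length_range`` is
    emitted, together with up to ``exo_steps`` single-residue trimmed
    variants per terminus (aminopeptidase/carboxypeptidase ladders) whose
    abundance decays by ``exo_decay`` per trimmed residue. Per-(peptide,
    sample) abundance = precursor abundance x ``peptide_yield`` x decay x
    log-normal noise with ``coupling_sigma`` (log2 units).
    """

    precursor_sequences: dict[str, str]
    endo_rule: frozenset[str] = frozenset({"K", "R"})
    cleavage_prob: float = 1.0
    exo_steps: int = 2
    length_range: tuple[int, int] = (8, 25)
    peptide_yield: float = 0.01
    exo_decay: float = 0.5
    coupling_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for acc, seq in self.precursor_sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for precursor {acc!r}")
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"invalid residues {sorted(bad)} in precursor {acc!r}"
                )
        if not 0 <= self.cleavage_prob <= 1:
            raise ValueError("cleavage_prob must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside generated tables.

    ``true_edges`` holds unordered feature-id pairs (the non-zero
    off-diagonal entries of the planted precision matrix);
    ``true_clusters`` maps feature id -> planted cluster id (0 = background);
    ``true_cleavage_sites`` holds (accession, bond position, P1 residue)
    triples, the bond following the 1-based residue index;
    ``censor_thresholds`` maps feature id -> intensity below which the
    feature was censored.
    """

    true_edges: set[tuple[str, str]] = field(default_factory=set)
    true_clusters: dict[str, int] = field(default_factory=dict)
    true_cleavage_sites: set[tuple[str, int, str]] = field(default_factory=set)
    censor_thresholds: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            true_edges=self.true_edges | other.true_edges,
            true_clusters={**self.true_clusters, **other.true_clusters},
            true_cleavage_sites=self.true_cleavage_sites | other.true_cleavage_sites,
            censor_thresholds={**self.censor_thresholds, **other.censor_thresholds},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_edges": sorted(map(list, self.true_edges)),
            "true_clusters": self.true_clusters,
            "true_cleavage_sites": sorted(
                [acc, pos, res] for acc, pos, res in self.true_cleavage_sites
            ),
            "censor_thresholds": self.censor_thresholds,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_edges={tuple(e) for e in payload["true_edges"]},
            true_clusters=payload["true_clusters"],
            true_cleavage_sites={
                (acc, int(pos), res) for acc, pos, res in payload["true_cleavage_sites"]
            },
            censor_thresholds=payload["censor_thresholds"],
        )


def build_precision_matrix(spec: PrecisionSpec) -> np.ndarray:
    """Precision matrix with unit diagonal and -pcor inside planted blocks.

    Raises with the offending block named if any block (or the whole
    matrix) fails positive definiteness.
    """
    rho = spec.within_block_pcor
    omega = np.eye(spec.n_features)
    pos = 0
    for b, size in enumerate(spec.block_sizes):
        sl = slice(pos, pos + size)
        block = np.full((size, size), -rho)
        np.fill_diagonal(block, 1.0)
        # smallest eigenvalue of I - rho(J - I) is 1 - rho*(k-1) for rho >= 0
        if np.linalg.eigvalsh(block).min() <= 1e-10:
            raise ValueError(
                f"block {b} (size {size}, pcor {rho}) yields a non-positive-"
                f"definite precision matrix; need |pcor| < 1/(size-1)"
            )
        omega[sl, sl] = block
        pos += size
    return omega


def _feature_names(n: int, prefix: str) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_abundances(
    spec: PrecisionSpec, feature_prefix: str = "PROT", kind: str = PROTEIN
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Draw log-normal abundance profiles with the planted GGM structure.

    Latent scores are multivariate Gaussian with the planted precision
    matrix; intensities are ``2**(mu_f + score)`` with per-feature baseline
    ``mu_f`` uniform over a realistic LFQ log2 range, so a log2 transform
    downstream recovers exact Gaussianity.
    """
    omega = build_precision_matrix(spec)
    sigma = np.linalg.inv(omega)
    rng = np.random.default_rng(spec.seed)
    scores = rng.multivariate_normal(
        np.zeros(spec.n_features), sigma, size=spec.n_samples, method="cholesky"
    )
    mu = rng.uniform(*LOG2_BASELINE_RANGE, size=spec.n_features)
    intensities = np.exp2(mu + scores)

    features = _feature_names(spec.n_features, feature_prefix)
    samples = _feature_names(spec.n_samples, "S")
    table = AbundanceTable(
        intensities=pd.DataFrame(intensities, index=samples, columns=features),
        mask=pd.DataFrame(False, index=samples, columns=features),
        kind=pd.Series(kind, index=features),
        meta=pd.DataFrame(
            {"gene_name": features, "is_contaminant": False, "is_reverse": False},
            index=features,
        ),
    )

    truth = SyntheticTruth()
    pos = 0
    clusters = {f: 0 for f in features}
    for b, size in enumerate(spec.block_sizes, start=1):
        block_feats = features[pos : pos + size]
        for f in block_feats:
            clusters[f] = b
        for i in range(size):
            for j in range(i + 1, size):
                truth.true_edges.add((block_feats[i], block_feats[j]))
        pos += size
    truth.true_clusters = clusters
    return table, truth


def _digest_one(
    seq: str, spec: DigestSpec, rng: np.random.Generator
) -> tuple[list[tuple[int, int, tuple[int, int] | None]], set[int]]:
    """Fragments (start, end, parent-coordinates) and the planted cut bonds.

    Coordinates are 1-based inclusive on the full precursor sequence. Base
    fragments (parent None) arise by endoproteolysis; each exo-trimmed
    variant records the peptide it was trimmed from, one residue at a
    time (N-chain and C-chain per base fragment). Only bonds flanking an
    emitted base fragment count as planted cleavage sites: a cut adjacent
    solely to length-filtered fragments leaves no observable terminus.
    """
    length = len(seq)
    eligible = [i for i in range(1, length) if seq[i - 1] in spec.endo_rule]
    cuts = [i for i in eligible if rng.random() < spec.cleavage_prob]
    boundaries = [0, *cuts, length]

    lo, hi = spec.length_range
    peptides: list[tuple[int, int, tuple[int, int] | None]] = []
    used_bonds: set[int] = set()
    for left, right in zip(boundaries[:-1], boundaries[1:]):
        start, end = left + 1, right  # 1-based inclusive fragment
        if not lo <= end - start + 1 <= hi:
            continue
        peptides.append((start, end, None))
        if start > 1:
            used_bonds.add(start - 1)
        if end < length:
            used_bonds.add(end)
        for t in range(1, spec.exo_steps + 1):  # N-terminal trim chain
            if end - (start + t) + 1 < lo:
                break
            peptides.append((start + t, end, (start + t - 1, end)))
        for t in range(1, spec.exo_steps + 1):  # C-terminal trim chain
            if (end - t) - start + 1 < lo:
                break
            peptides.append((start, end - t, (start, end - t + 1)))
    return peptides, used_bonds


def simulate_digest(
    spec: DigestSpec, precursor_abundances: pd.DataFrame
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Generate a peptide table by in-silico proteolysis of precursors.

    ``precursor_abundances`` is a samples x accession DataFrame of linear
    intensities (typically columns of a protein table). Abundance flows
    down the proteolysis cascade: a base fragment's per-sample intensity
    is precursor x ``peptide_yield`` x noise, and each single-residue
    trimmed variant's is its parent peptide's x ``exo_decay`` x noise —
    trimming acts on the peptide product, not on the precursor, so ladder
    neighbours are directly coupled, as exoproteolysis implies. Truth
    records the cascade (precursor-base and parent-child pairs) as
    ``true_edges`` and every cleavage bond used.
    """
    missing = set(spec.precursor_sequences) - set(precursor_abundances.columns)
    if missing:
        raise ValueError(f"no abundance profile for precursors {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    samples = list(precursor_abundances.index)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    truth = SyntheticTruth()
    tree_id = 0  # one planted cluster per base fragment's trim family (ladder)
    for acc in sorted(spec.precursor_sequences):
        seq = spec.precursor_sequences[acc]
        fragments, used_bonds = _digest_one(seq, spec, rng)
        truth.true_cleavage_sites |= {(acc, b, seq[b - 1]) for b in used_bonds}
        prec = precursor_abundances[acc].to_numpy(dtype=float)
        for start, end, parent in fragments:
            pid = f"{acc}|{start}-{end}"
            if pid in columns:
                continue
            noise = np.exp2(rng.normal(0.0, spec.coupling_sigma, size=len(samples)))
            if parent is None:
                columns[pid] = prec * spec.peptide_yield * noise
                truth.true_edges.add((acc, pid))
                tree_id += 1
                truth.true_clusters[pid] = tree_id
            else:
                parent_id = f"{acc}|{parent[0]}-{parent[1]}"
                columns[pid] = columns[parent_id] * spec.exo_decay * noise
                truth.true_edges.add((parent_id, pid))
                truth.true_clusters[pid] = truth.true_clusters[parent_id]
            meta_rows.append(
                {
                    "feature_id": pid,
                    "sequence": seq[start - 1 : end],
                    "precursor_accession": acc,
                    "start": start,
                    "end": end,
                    "gene_name": acc,
                    "is_contaminant": False,
                    "is_reverse": False,
                }
            )

    if columns:
        intensities = pd.DataFrame(columns, index=samples)
    else:
        intensities = pd.DataFrame(index=samples)
    meta = pd.DataFrame(meta_rows).set_index("feature_id") if meta_rows else pd.DataFrame()
    table = AbundanceTable(
        intensities=intensities,
        mask=pd.DataFrame(False, index=samples, columns=intensities.columns),
        kind=pd.Series(PEPTIDE, index=intensities.columns),
        meta=meta,
    )
    return table, truth


def apply_mnar_censoring(
    table: AbundanceTable,
    censor_quantile: float,
    seed: int,
    soft: bool = False,
    soft_scale: float = 0.25,
) -> AbundanceTable:
    """Left-censor each feature below its own intensity quantile.

    Hard censoring (default) deletes every intensity strictly below the
    per-feature ``censor_quantile`` quantile — the worst-case MNAR
    mechanism. With ``soft=True``, cells are deleted stochastically with a
    logistic probability in the log2 distance to the threshold
    (``soft_scale`` log2 units), softening the cut near the boundary.
    """
    if not 0 <= censor_quantile < 1:
        raise ValueError("censor_quantile must lie in [0, 1)")
    if censor_quantile == 0:
        return table
    rng = np.random.default_rng(seed)
    vals = table.intensities.to_numpy(dtype=float)
    mask = table.mask.to_numpy().copy()
    thresholds = np.nanquantile(
        np.where(mask, np.nan, vals), censor_quantile, axis=0
    )
    if soft:
        with np.errstate(divide="ignore"):
            dist = np.log2(vals) - np.log2(thresholds)[None, :]
        p_miss = 1.0 / (1.0 + np.exp(dist / soft_scale))
        new_missing = rng.random(vals.shape) < p_miss
    else:
        new_missing = vals < thresholds[None, :]
    mask |= new_missing & ~table.mask.to_numpy()
    out = AbundanceTable(
        intensities=table.intensities.where(
            ~pd.DataFrame(mask, index=table.intensities.index, columns=table.intensities.columns)
        ),
        mask=pd.DataFrame(mask, index=table.mask.index, columns=table.mask.columns),
        kind=table.kind.copy(),
        meta=table.meta.copy(),
    )
    return out


def censor_thresholds(table: AbundanceTable, censor_quantile: float) -> dict[str, float]:
    """Per-feature censoring thresholds for recording in SyntheticTruth."""
    vals = np.where(table.mask.to_numpy(), np.nan, table.intensities.to_numpy(dtype=float))
    th = np.nanquantile(vals, censor_quantile, axis=0)
    return dict(zip(table.feature_ids, th.tolist()))


# ---------------------------------------------------------------------------
# MaxQuant-dialect writers (round-trip partners of milknet.ingest readers)
# ---------------------------------------------------------------------------

def write_protein_groups(table: AbundanceTable, path: str | Path) -> None:
    """Write a proteinGroups-like TSV; missing cells become MaxQuant zeros."""
    meta = table.meta
    rows = pd.DataFrame(
        {
            "Majority protein IDs": table.feature_ids,
            "Gene names": [
                meta.at[f, "gene_name"] if "gene_name" in meta.columns else f
                for f in table.feature_ids
            ],
            "Reverse": _plus_flags(meta, table.feature_ids, "is_reverse"),
            "Potential contaminant": _plus_flags(meta, table.feature_ids, "is_contaminant"),
        }
    )
    filled = table.intensities.fillna(0.0).T
    filled.columns = [f"LFQ intensity {s}" for s in filled.columns]
    pd.concat([rows, filled.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False
    )


def write_peptides_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a peptides-like TSV with sequence/precursor coordinates."""
    meta = table.meta
    rows = pd.DataFrame(
        {
            "Sequence": [meta.at[f, "sequence"] for f in table.feature_ids],
            "Proteins": [meta.at[f, "precursor_accession"] for f in table.feature_ids],
            "Start position": [int(meta.at[f, "start"]) for f in table.feature_ids],
            "End position": [int(meta.at[f, "end"]) for f in table.feature_ids],
            "Reverse": _plus_flags(meta, table.feature_ids, "is_reverse"),
            "Potential contaminant": _plus_flags(meta, table.feature_ids, "is_contaminant"),
        }
    )
    filled = table.intensities.fillna(0.0).T
    filled.columns = [f"Intensity {s}" for s in filled.columns]
    pd.concat([rows, filled.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False
    )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()]
    seqio_write(records, str(path), "fasta")


def _plus_flags(meta: pd.DataFrame, features: list[str], column: str) -> list[str]:
    if column not in meta.columns:
        return ["" for _ in features]
    return ["+" if bool(meta.at[f, column]) else "" for f in features]


def random_protein_sequence(length: int, seed: int, kr_every: int = 12) -> str:
    """A synthetic amino-acid sequence with K/R residues roughly every
    ``kr_every`` positions, so a tryptic/plasmin-like digest yields
    fragments inside the standard 8-25 residue identification window."""
    rng = np.random.default_rng(seed)
    non_kr = sorted(AMINO_ACIDS - {"K", "R"})
    residues = [str(x) for x in rng.choice(non_kr, size=length)]
    pos = kr_every - 1
    while pos < length - 1:
        residues[pos] = str(rng.choice(["K", "R"]))
        pos += kr_every
    return "".join(residues)
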