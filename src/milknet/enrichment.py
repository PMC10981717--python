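"""GO overrepresentation of protein clusters (two-list mode).

For a cluster of n proteins drawn from a background of N identified
proteins, a term annotating B background proteins and b cluster proteins
gets the upper hypergeometric tail

    p = sum_{k >= b} C(B, k) C(N - B, n - k) / C(N, n),

Benjamini-Hochberg adjusted within each (cluster, GO-domain) pool.
Annotations are consumed as a flat gene -> term table (pre-propagated by
the provider; no DAG handling here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DOMAINS = ("BP", "MF", "CC")


@dataclass
class AnnotationSet:
    """Flat gene -> GO-term annotation with a term -> domain lookup."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_domain: dict[str, str] = field(default_factory=dict)

    def terms_for(self, genes) -> dict[str, set[str]]:
        """term -> annotated genes restricted to the given gene set."""
        out: dict[str, set[str]] = {}
        for g in genes:
            for t in self.gene_terms.get(g, ()):
                out.setdefault(t, set()).add(g)
        return out

    @classmethod
    def from_tsv(cls, gene_term_path: str | Path, term_domain_path: str | Path) -> "AnnotationSet":
        gt = pd.read_csv(gene_term_path, sep="\t", names=["gene", "term"], header=None)
        td = pd.read_csv(term_domain_path, sep="\t", names=["term", "domain"], header=None)
        ann = cls()
        for row in gt.itertuples():
            ann.gene_terms.setdefault(str(row.gene), set()).add(str(row.term))
        ann.term_domain = {str(r.term): str(r.domain) for r in td.itertuples()}
        return ann

    @classmethod
    def from_gaf(cls, path: str | Path) -> "AnnotationSet":
        """Minimal GAF 2.x subset reader (columns 3, 5, 9)."""
        aspect_map = {"P": "BP", "F": "MF", "C": "CC"}
        ann = cls()
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            gene, term, aspect = cols[2], cols[4], cols[8]
            ann.gene_terms.setdefault(gene, set()).add(term)
            ann.term_domain[term] = aspect_map.get(aspect, aspect)
        return ann


def hypergeom_overrepresentation(
    cluster_genes,
    background_genes,
    annotations: AnnotationSet,
) -> pd.DataFrame:
    """Per-term upper hypergeometric tail for one cluster.

    Returns a DataFrame with columns term, domain, b, n, B, N, p_value
    (terms with b = 0 omitted). Raises if the cluster is not a subset of
    the background.
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    stray = cluster - background
    if stray:
        raise ValueError(f"cluster genes absent from background: {sorted(stray)[:5]}")
    N, n = len(background), len(cluster)
    bg_terms = annotations.terms_for(background)
    cl_terms = annotations.terms_for(cluster)
    rows = []
    for term, genes_in_cluster in sorted(cl_terms.items()):
        b = len(genes_in_cluster)
        B = len(bg_terms[term])
        p = float(stats.hypergeom.sf(b - 1, N, B, n))
        rows.append(
            {
                "term": term,
                "domain": annotations.term_domain.get(term, "NA"),
                "b": b,
                "n": n,
                "B": B,
                "N": N,
                "p_value": min(max(p, np.nextafter(0, 1)), 1.0),
                "genes": ",".join(sorted(genes_in_cluster)),
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "domain", "b", "n", "B", "N", "p_value", "genes"]
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_cluster(
    cluster_id: int,
    cluster_genes,
    background_genes,
    annotations: AnnotationSet,
    pool: str = "domain",
) -> pd.DataFrame:
    """Overrepresentation records for one cluster, BH-adjusted.

    ``pool="domain"`` adjusts within each GO domain separately (mirroring
    per-domain reporting); ``pool="cluster"`` adjusts across all terms of
    the cluster at once.
    """
    records = hypergeom_overrepresentation(cluster_genes, background_genes, annotations)
    if records.empty:
        records["adjusted_p"] = pd.Series(dtype=float)
        records.insert(0, "cluster", pd.Series(dtype=int))
        return records
    records.insert(0, "cluster", cluster_id)
    if pool == "domain":
        records["adjusted_p"] = np.nan
        for dom, idx in records.groupby("domain").groups.items():
            records.loc[idx, "adjusted_p"] = bh_adjust(records.loc[idx, "p_value"])
    elif pool == "cluster":
        records["adjusted_p"] = bh_adjust(records["p_value"])
    else:
        raise ValueError(f"unknown adjustment pool {pool!r}")
    return records


def significant_enrichments(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Strictly adjusted_p < alpha."""
    if records.empty:
        return records
    return records[records["adjusted_p"] < alpha].reset_index(drop=True)


def write_enrichment_tsv(records: pd.DataFrame, path: str | Path) -> None:
    cols = ["cluster", "domain", "term", "adjusted_p", "genes"]
    out = records[[c for c in cols if c in records.columns]]
    out.to_csv(path, sep="\t", index=False)
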