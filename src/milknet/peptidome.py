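"""Peptidome-specific computations: peptide-to-precursor mapping, ladder
detection, exoproteolytic trimming steps, protease cleavage specificity,
and precursor contribution.

Coordinates are 1-based inclusive on the full precursor sequence, signal
peptide included in the numbering. A "ladder" is a connected component of
the interval-overlap graph of peptides from one precursor within one
cluster — the signature of single-residue aminopeptidase/carboxypeptidase
trimming around an initial endoproteolytic cut. Plasmin, the dominant milk
endoprotease, hydrolyzes bonds with K or R at P1 and any residue at P1'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable


@dataclass(frozen=True)
class PeptideLocation:
    precursor_accession: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    multi_hit: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad coordinates {self.start}-{self.end}")
        if self.sequence and len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "PeptideLocation") -> bool:
        return (
            self.precursor_accession == other.precursor_accession
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class LadderRecord:
    cluster_id: int | None
    precursor_accession: str
    range_start: int
    range_end: int
    n_peptides: int
    mean_length: float  # residues, 1 decimal
    members: list[PeptideLocation] = field(default_factory=list)


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    allowed_p1: frozenset[str]
    allowed_p1prime: frozenset[str] | None = None  # None = any residue

    def matches(self, p1: str, p1prime: str) -> bool:
        if p1 not in self.allowed_p1:
            return False
        return self.allowed_p1prime is None or p1prime in self.allowed_p1prime


PLASMIN = ProteaseRule("plasmin", frozenset({"K", "R"}))

_RANGE_RE = re.compile(r"(\d+)\s*[-–]\s*(\d+)")


def parse_range(text: str) -> tuple[int, int]:
    """Parse a "start-end" position string (hyphen or en-dash)."""
    m = _RANGE_RE.search(text)
    if not m:
        raise ValueError(f"cannot parse position range from {text!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if end < start:
        raise ValueError(f"end < start in range {text!r}")
    return start, end


def map_peptide(sequence: str, precursors: dict[str, str]) -> list[PeptideLocation]:
    """All exact-match placements of a peptide across precursor sequences.

    Placements are flagged ``multi_hit`` when the peptide occurs more than
    once (within or across precursors). Raises if the peptide matches
    nowhere.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    hits: list[tuple[str, int]] = []
    for acc in sorted(precursors):
        seq = precursors[acc]
        pos = seq.find(sequence)
        while pos != -1:
            hits.append((acc, pos))
            pos = seq.find(sequence, pos + 1)
    if not hits:
        raise ValueError(f"peptide {sequence!r} not found in any precursor")
    multi = len(hits) > 1
    return [
        PeptideLocation(acc, pos + 1, pos + len(sequence), sequence, multi_hit=multi)
        for acc, pos in hits
    ]


def detect_ladders(
    cluster_peptides: list[PeptideLocation],
    min_peptides: int = 5,
    cluster_id: int | None = None,
) -> list[LadderRecord]:
    """Connected components of the per-precursor interval-overlap graph.

    Two peptides overlap iff their position ranges intersect in at least
    one residue. Components with >= ``min_peptides`` members become
    ladders; several ladders per (cluster, precursor) are possible.
    """
    by_prec: dict[str, list[PeptideLocation]] = {}
    for p in cluster_peptides:
        by_prec.setdefault(p.precursor_accession, []).append(p)
    ladders = []
    for acc in sorted(by_prec):
        peptides = sorted(by_prec[acc], key=lambda p: (p.start, p.end))
        component: list[PeptideLocation] = []
        reach = -1
        for p in peptides + [None]:
            if p is not None and (not component or p.start <= reach):
                component.append(p)
                reach = max(reach, p.end)
                continue
            if len(component) >= min_peptides:
                lengths = [q.length for q in component]
                ladders.append(
                    LadderRecord(
                        cluster_id=cluster_id,
                        precursor_accession=acc,
                        range_start=min(q.start for q in component),
                        range_end=max(q.end for q in component),
                        n_peptides=len(component),
                        mean_length=round(float(np.mean(lengths)), 1),
                        members=component,
                    )
                )
            if p is not None:
                component, reach = [p], p.end
    return ladders


def trimming_steps(
    ladder_peptides: list[PeptideLocation],
) -> list[tuple[PeptideLocation, PeptideLocation, str]]:
    """Ordered pairs differing by one residue at exactly one terminus.

    (a, b, "N") means b is a with one N-terminal residue removed
    (start + 1, same end); (a, b, "C") the single C-terminal trim
    (same start, end - 1) — the elementary exoproteolysis events.
    """
    coords = {(p.precursor_accession, p.start, p.end): p for p in ladder_peptides}
    steps = []
    for (acc, start, end), p in sorted(coords.items()):
        n_child = coords.get((acc, start + 1, end))
        if n_child is not None and start + 1 <= end:
            steps.append((p, n_child, "N"))
        c_child = coords.get((acc, start, end - 1))
        if c_child is not None and start <= end - 1:
            steps.append((p, c_child, "C"))
    return steps


def cleavage_sites(
    peptides: list[PeptideLocation], precursor_sequences: dict[str, str]
) -> pd.DataFrame:
    """Unique cleavage sites implied by observed peptide termini.

    Each peptide implies a cleavage of the bond preceding its first
    residue (if any) and following its last (if any); protein N-/C-termini
    are not cleavage sites. Sites are deduplicated by (precursor, bond
    position); ``bond_position`` is the 1-based index of the P1 residue,
    the bond being P1-P1'.
    """
    seen: dict[tuple[str, int], tuple[str, str]] = {}
    for p in peptides:
        seq = precursor_sequences.get(p.precursor_accession)
        if seq is None:
            raise ValueError(f"no sequence for precursor {p.precursor_accession!r}")
        if p.end > len(seq):
            raise ValueError(
                f"peptide {p.start}-{p.end} outside precursor "
                f"{p.precursor_accession!r} (length {len(seq)})"
            )
        for bond in ((p.start - 1,) if p.start > 1 else ()) + (
            (p.end,) if p.end < len(seq) else ()
        ):
            seen.setdefault((p.precursor_accession, bond), (seq[bond - 1], seq[bond]))
    rows = [
        {"precursor_accession": acc, "bond_position": bond, "p1": p1, "p1prime": p1p}
        for (acc, bond), (p1, p1p) in sorted(seen.items())
    ]
    return pd.DataFrame(rows, columns=["precursor_accession", "bond_position", "p1", "p1prime"])


def cleavage_specificity(
    peptides: list[PeptideLocation],
    precursor_sequences: dict[str, str],
    rules: list[ProteaseRule] = (PLASMIN,),
    per_terminus: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Protease-specificity fractions over observed cleavage sites.

    Default counting is by unique (precursor, bond) site; with
    ``per_terminus=True`` every peptide terminus counts separately.
    Returns the site table (with per-rule match flags) and the percentage
    of sites matching each rule.
    """
    sites = cleavage_sites(peptides, precursor_sequences)
    if per_terminus:
        rows = []
        for p in peptides:
            seq = precursor_sequences[p.precursor_accession]
            if p.start > 1:
                rows.append(
                    {
                        "precursor_accession": p.precursor_accession,
                        "bond_position": p.start - 1,
                        "p1": seq[p.start - 2],
                        "p1prime": seq[p.start - 1],
                    }
                )
            if p.end < len(seq):
                rows.append(
                    {
                        "precursor_accession": p.precursor_accession,
                        "bond_position": p.end,
                        "p1": seq[p.end - 1],
                        "p1prime": seq[p.end],
                    }
                )
        sites = pd.DataFrame(
            rows, columns=["precursor_accession", "bond_position", "p1", "p1prime"]
        )
    fractions: dict[str, float] = {}
    for rule in rules:
        if sites.empty:
            sites[f"matches_{rule.name}"] = pd.Series(dtype=bool)
            fractions[rule.name] = float("nan")
            continue
        flags = [
            rule.matches(p1, p1p) for p1, p1p in zip(sites["p1"], sites["p1prime"])
        ]
        sites[f"matches_{rule.name}"] = flags
        fractions[rule.name] = round(100.0 * float(np.mean(flags)), 1)
    return sites, fractions


def precursor_contribution(peptide_table: AbundanceTable) -> pd.DataFrame:
    """Share of the peptidome attributable to each precursor protein.

    Count-based: peptides per precursor / total peptides. Abundance-based:
    summed mean observed intensity per precursor / total. Both as
    percentages summing to 100.
    """
    meta = peptide_table.meta
    if "precursor_accession" not in meta.columns:
        raise ValueError("peptide table lacks precursor_accession metadata")
    prec = meta.loc[peptide_table.feature_ids, "precursor_accession"]
    counts = prec.value_counts()
    mean_intensity = peptide_table.intensities.mean(axis=0, skipna=True)
    abundance = mean_intensity.groupby(prec).sum()
    out = pd.DataFrame(
        {
            "n_peptides": counts,
            "count_percent": 100.0 * counts / counts.sum(),
            "abundance_percent": 100.0 * abundance / abundance.sum(),
        }
    )
    out.index.name = "precursor_accession"
    return out.sort_values("count_percent", ascending=False)


def write_ladders_tsv(ladders: list[LadderRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cluster": l.cluster_id,
                "precursor_accession": l.precursor_accession,
                "range": f"{l.range_start}-{l.range_end}",
                "n_peptides": l.n_peptides,
                "mean_length": l.mean_length,
            }
            for l in ladders
        ]
    ).to_csv(path, sep="\t", index=False)
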