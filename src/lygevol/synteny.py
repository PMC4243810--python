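"""Genomic-neighborhood conservation and tandem-cluster detection.

Formalises gene-order comparisons around family members: the neighborhood of
a focal gene is the k nearest non-family genes on each side of it on its
scaffold; conservation between two neighborhoods is the Jaccard index of
their (case-insensitive) flanking-symbol sets; family genes on one scaffold
are chained into tandem clusters when consecutive inter-gene gaps do not
exceed ``max_gap``.

Coordinates are 1-based inclusive in files; the gap between two loci is
``next.start - prev.end - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "GeneLocus",
    "Neighborhood",
    "SyntenyError",
    "read_loci",
    "extract_neighborhood",
    "conservation_score",
    "tandem_clusters",
    "DEFAULT_K",
    "DEFAULT_MAX_GAP",
]

DEFAULT_K = 3
DEFAULT_MAX_GAP = 200_000

LOCI_COLUMNS = ["species", "scaffold", "start", "end", "strand", "symbol"]


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class GeneLocus:
    species: str
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    symbol: str

    def __post_init__(self):
        if self.start > self.end:
            raise SyntenyError(
                f"locus {self.symbol}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise SyntenyError(f"locus {self.symbol}: bad strand {self.strand!r}")


@dataclass
class Neighborhood:
    focal: GeneLocus
    upstream: list[GeneLocus]  # coordinate order, at most k
    downstream: list[GeneLocus]

    def symbols(self) -> set[str]:
        return {g.symbol.lower() for g in self.upstream + self.downstream}


def read_loci(path) -> pd.DataFrame:
    """Read a tab-separated loci table (species, scaffold, start, end,
    strand, symbol; 1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LOCI_COLUMNS if c not in df.columns]
    if missing:
        raise SyntenyError(f"loci table missing columns: {missing}")
    return df


def _loci_from_frame(df: pd.DataFrame) -> list[GeneLocus]:
    return [
        GeneLocus(
            str(r.species), str(r.scaffold), int(r.start), int(r.end),
            str(r.strand), str(r.symbol),
        )
        for r in df.itertuples()
    ]


def extract_neighborhood(
    loci: pd.DataFrame,
    focal_symbol: str,
    k: int = DEFAULT_K,
    family_symbols: Optional[Iterable[str]] = None,
) -> list[Neighborhood]:
    """Neighborhoods of every locus carrying ``focal_symbol``.

    The k nearest non-family genes on each side on the same scaffold, in
    coordinate order (fewer where the scaffold ends).  Family members —
    ``family_symbols`` plus the focal symbol itself — never count as
    neighbors.
    """
    if k < 1:
        raise SyntenyError("k must be >= 1")
    family = {s.lower() for s in (family_symbols or [])}
    family.add(focal_symbol.lower())
    records = _loci_from_frame(loci)
    focal = [g for g in records if g.symbol == focal_symbol]
    if not focal:
        raise SyntenyError(f"focal symbol {focal_symbol!r} not in loci table")
    out = []
    for f in focal:
        same = sorted(
            (
                g
                for g in records
                if g.species == f.species and g.scaffold == f.scaffold and g is not f
            ),
            key=lambda g: g.start,
        )
        neighbors = [g for g in same if g.symbol.lower() not in family]
        up = [g for g in neighbors if g.start < f.start][-k:]
        down = [g for g in neighbors if g.start > f.start][:k]
        out.append(Neighborhood(focal=f, upstream=up, downstream=down))
    return out


def conservation_score(n1: Neighborhood, n2: Neighborhood) -> tuple[float, list[str]]:
    """Jaccard index of the two neighborhoods' symbol sets (case-insensitive)
    plus the shared symbols; two empty neighborhoods score 1.0."""
    s1, s2 = n1.symbols(), n2.symbols()
    if not s1 and not s2:
        return 1.0, []
    shared = sorted(s1 & s2)
    return len(shared) / len(s1 | s2), shared


def tandem_clusters(
    loci: pd.DataFrame,
    family_symbols: Iterable[str],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[dict]:
    """Chain family genes on a scaffold into clusters.

    Consecutive family genes (coordinate order) belong to one cluster when
    the gap between them (``next.start - prev.end - 1``) is at most
    ``max_gap``.  Each cluster reports its members, genomic span, and whether
    all members share a strand.
    """
    if max_gap <= 0:
        raise SyntenyError("max_gap must be > 0")
    family = {s.lower() for s in family_symbols}
    records = [g for g in _loci_from_frame(loci) if g.symbol.lower() in family]
    clusters = []
    by_scaffold: dict[tuple[str, str], list[GeneLocus]] = {}
    for g in records:
        by_scaffold.setdefault((g.species, g.scaffold), []).append(g)
    for (species, scaffold), genes in sorted(by_scaffold.items()):
        genes.sort(key=lambda g: g.start)
        current = [genes[0]]
        for prev, nxt in zip(genes, genes[1:]):
            if nxt.start - prev.end - 1 <= max_gap:
                current.append(nxt)
            else:
                clusters.append(_cluster_record(species, scaffold, current))
                current = [nxt]
        clusters.append(_cluster_record(species, scaffold, current))
    return clusters


def _cluster_record(species: str, scaffold: str, genes: list[GeneLocus]) -> dict:
    return {
        "species": species,
        "scaffold": scaffold,
        "members": [g.symbol for g in genes],
        "size": len(genes),
        "span": genes[-1].end - genes[0].start + 1,
        "same_orientation": len({g.strand for g in genes}) == 1,
    }
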