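"""Read annotation cascade and per-library summaries.

Each read receives exactly one category, assigned in a fixed order:

1. ``abundant_ncRNA`` — exact substring of an rRNA/tRNA/snRNA sequence
   (stored strand only);
2. ``miRNA`` — exact full-length identity with a mature miRNA;
3. ``nonmapper`` — no perfect genome match (either strand);
4. ``siRNA`` — 21 nt perfect mapper;
5. ``piRNA`` — 23–29 nt perfect mapper;
6. ``unclassified`` — mappers of 18–20 or 22 nt, which the size rules leave
   unnamed.

The per-library summary counts each category plus the genome-unique piRNAs
attributable to each annotated cluster — the numbers a sequencing-counts
table reports per library and the input to cluster-anchored normalization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, GenomeIndex, map_perfect
from .reference import ReferenceBundle
from .simulate import SmallRNALibrary

__all__ = [
    "CATEGORIES",
    "AnnotatedRead",
    "AnnotationBreakdown",
    "classify_reads",
    "summarize",
    "size_histogram",
    "base_composition",
]

CATEGORIES = (
    "abundant_ncRNA",
    "miRNA",
    "siRNA",
    "piRNA",
    "unclassified",
    "nonmapper",
)
SIRNA_LENGTH = 21
PIRNA_RANGE = (23, 29)


@dataclass(frozen=True)
class AnnotatedRead:
    read_id: str
    sequence: str
    category: str
    genome_hits: tuple[AlignmentHit, ...] = ()

    @property
    def genome_hit_count(self) -> int:
        return len(self.genome_hits)

    @property
    def genome_unique(self) -> bool:
        return len(self.genome_hits) == 1

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationBreakdown:
    library_id: str
    total_reads: int
    category_counts: dict[str, int]
    cluster_unique_pirna: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) != self.total_reads:
            raise ValueError("category counts do not sum to total reads")
        pirna = self.category_counts.get("piRNA", 0)
        for cid, n in self.cluster_unique_pirna.items():
            if n > pirna:
                raise ValueError(f"cluster {cid} unique count exceeds piRNA count")

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total_reads)]
        rows += [(c, self.category_counts.get(c, 0)) for c in CATEGORIES]
        rows += [
            (f"{cid}_unique_piRNA", n)
            for cid, n in sorted(self.cluster_unique_pirna.items())
        ]
        return pd.DataFrame(rows, columns=["metric", "count"]).assign(
            library=self.library_id
        )[["library", "metric", "count"]]


def _categorise(
    seq: str,
    ncrna: Sequence[str],
    mirna: frozenset[str],
    genome: str | GenomeIndex,
) -> tuple[str, tuple[AlignmentHit, ...]]:
    if any(seq in s for s in ncrna):
        return "abundant_ncRNA", ()
    if seq in mirna:
        return "miRNA", ()
    hits = tuple(map_perfect(seq, genome))
    if not hits:
        return "nonmapper", ()
    n = len(seq)
    if n == SIRNA_LENGTH:
        return "siRNA", hits
    if PIRNA_RANGE[0] <= n <= PIRNA_RANGE[1]:
        return "piRNA", hits
    return "unclassified", hits


def classify_reads(
    library: SmallRNALibrary, bundle: ReferenceBundle
) -> list[AnnotatedRead]:
    """Run the annotation cascade over a library.

    Genome hits (perfect, both strands) are attached to every mapper so that
    downstream cluster/3'UTR attribution needs no re-mapping.  Identical
    sequences are classified once.
    """
    if not bundle.genome:
        raise ValueError("bundle genome is empty")
    ncrna = list(bundle.ncrna_set.values())
    mirna = frozenset(bundle.mirna_set.values())
    index = GenomeIndex(bundle.genome)
    cache: dict[str, tuple[str, tuple[AlignmentHit, ...]]] = {}
    out = []
    for rid, seq in library.reads:
        seq = seq.upper()
        got = cache.get(seq)
        if got is None:
            got = _categorise(seq, ncrna, mirna, index)
            cache[seq] = got
        out.append(AnnotatedRead(rid, seq, got[0], got[1]))
    return out


def summarize(
    annotated: Sequence[AnnotatedRead], bundle: ReferenceBundle, library_id: str = ""
) -> AnnotationBreakdown:
    """Category counts plus genome-unique piRNA counts per cluster.

    A piRNA counts towards a cluster when it is genome-unique and its single
    alignment lies entirely within the cluster interval.
    """
    counts = Counter(r.category for r in annotated)
    cluster_counts = {c.id: 0 for c in bundle.clusters}
    for r in annotated:
        if r.category != "piRNA" or not r.genome_unique:
            continue
        hit = r.genome_hits[0]
        for c in bundle.clusters:
            if c.interval.contains(hit.start, hit.end):
                cluster_counts[c.id] += 1
                break  # intervals do not overlap
    return AnnotationBreakdown(
        library_id=library_id,
        total_reads=len(annotated),
        category_counts={c: counts.get(c, 0) for c in CATEGORIES},
        cluster_unique_pirna=cluster_counts,
    )


def _select(
    annotated: Iterable[AnnotatedRead], categories: Iterable[str] | None
) -> list[AnnotatedRead]:
    if categories is None:
        return list(annotated)
    wanted = set(categories)
    unknown = wanted - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    return [r for r in annotated if r.category in wanted]


def size_histogram(
    annotated: Sequence[AnnotatedRead],
    categories: Iterable[str] | None = None,
    length_range: tuple[int, int] = (18, 29),
) -> pd.Series:
    """Read counts per length over ``length_range`` (inclusive)."""
    lo, hi = length_range
    selected = _select(annotated, categories)
    counts = Counter(r.length for r in selected)
    idx = range(lo, hi + 1)
    return pd.Series([counts.get(n, 0) for n in idx], index=pd.Index(idx, name="length"), name="reads")


def base_composition(
    annotated: Sequence[AnnotatedRead],
    categories: Iterable[str] | None = None,
    positions: int = 10,
) -> pd.DataFrame:
    """Per-position base frequencies over the first ``positions`` nt.

    Returns a ``positions x 4`` frequency matrix (rows 1-based positions,
    columns A/C/G/T; rows sum to 1).  Raises on an empty selection or when
    ``positions`` exceeds the shortest selected read.
    """
    selected = _select(annotated, categories)
    if not selected:
        raise ValueError("no reads selected for base composition")
    min_len = min(r.length for r in selected)
    if positions > min_len:
        raise ValueError(
            f"positions={positions} exceeds shortest selected read ({min_len} nt)"
        )
    mat = np.zeros((positions, 4), dtype=float)
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    for r in selected:
        for j in range(positions):
            mat[j, lut[r.sequence[j]]] += 1
    mat /= len(selected)
    return pd.DataFrame(
        mat, index=pd.Index(range(1, positions + 1), name="position"), columns=list("ACGT")
    )
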