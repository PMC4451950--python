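"""Ungapped short-read mapping.

Two semantics are needed by the pipeline:

* :func:`map_perfect` — every exact occurrence of a read (or its reverse
  complement) in a genome; a read is *genome-unique* iff it has exactly one
  such occurrence.  This is the semantics behind "mappers" and behind
  cluster / 3'UTR attribution.
* :func:`map_consensus` — every ungapped alignment of a read against a panel
  of transposable-element consensus sequences with a Hamming-distance budget
  (default 4 substitutions, no indels), on both strands.

Coordinates are 0-based on the reference forward strand.  The 5' end of an
antisense alignment is the rightmost aligned base on the forward strand, so
that 5'-end profiles of antisense piRNAs peak at their biological 5' ends.

:class:`ConsensusMapper` is a seeded (pigeonhole) batch implementation of the
consensus semantics used for whole-library quantification; it returns exactly
the hits of the per-read scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignmentHit",
    "revcomp",
    "GenomeIndex",
    "map_perfect",
    "map_consensus",
    "ConsensusMapper",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Reads shorter than this are rejected by map_perfect: on a toy genome a
#: very short query produces spurious multi-mappers that mean nothing.
MIN_READ_LENGTH = 15


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (T is the stand-in for U)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One ungapped alignment of a read to a reference.

    ``start`` is the 0-based leftmost aligned position on the reference
    forward strand; ``five_prime`` is the reference coordinate of the read's
    5' end (``start`` on ``+``, ``start + length - 1`` on ``-``).
    """

    reference_id: str
    start: int
    strand: str
    mismatches: int
    length: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.start + self.length - 1

    @property
    def end(self) -> int:
        """0-based exclusive end on the forward strand."""
        return self.start + self.length


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


class GenomeIndex:
    """Exact-occurrence index over a genome: k-mer prefix seeding plus a
    full-length verification, equivalent to scanning with ``str.find``."""

    def __init__(self, genome: str, k: int = MIN_READ_LENGTH):
        if not genome:
            raise ValueError("empty genome")
        self.genome = genome.upper()
        self.k = k
        index: dict[str, list[int]] = {}
        g = self.genome
        for p in range(len(g) - k + 1):
            index.setdefault(g[p : p + k], []).append(p)
        self._index = index

    def find_all(self, query: str) -> list[int]:
        """All start positions of exact occurrences of ``query`` (forward)."""
        if len(query) < self.k:
            raise ValueError("query shorter than index k-mer")
        g = self.genome
        return [
            p
            for p in self._index.get(query[: self.k], ())
            if g.startswith(query, p)
        ]


def map_perfect(
    read: str,
    genome: str | GenomeIndex,
    reference_id: str = "genome",
    min_length: int = MIN_READ_LENGTH,
) -> list[AlignmentHit]:
    """All exact occurrences of ``read`` on either strand of ``genome``.

    ``genome`` may be a raw sequence or a prebuilt :class:`GenomeIndex`
    (identical results; the index amortises whole-library mapping).
    Raises ``ValueError`` for reads shorter than ``min_length``.
    """
    read = read.upper()
    if len(read) < min_length:
        raise ValueError(
            f"read of length {len(read)} is below the perfect-mapping guard "
            f"({min_length} nt)"
        )
    if isinstance(genome, str):
        if not genome:
            raise ValueError("empty genome")
        finder = lambda q: _find_all(genome, q)  # noqa: E731
    else:
        finder = genome.find_all
    hits: list[AlignmentHit] = []
    for strand, query in (("+", read), ("-", revcomp(read))):
        for start in finder(query):
            hits.append(
                AlignmentHit(reference_id, start, strand, 0, len(read))
            )
    hits.sort()
    return hits


_ENC = np.full(256, 200, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one(
    query: np.ndarray, ref: np.ndarray, max_mismatches: int
) -> tuple[np.ndarray, np.ndarray]:
    """Starts and mismatch counts of all ungapped alignments of ``query``."""
    L = query.size
    if ref.size < L:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(ref, L)
    mism = (windows != query).sum(axis=1)
    keep = np.nonzero(mism <= max_mismatches)[0]
    return keep, mism[keep]


def map_consensus(
    read: str,
    panel: Mapping[str, str],
    max_mismatches: int = 4,
) -> dict[str, list[AlignmentHit]]:
    """Map a read to every consensus in ``panel`` with a mismatch budget.

    Returns ``{family_id: [hits]}`` for families with at least one ungapped
    alignment (either strand) at Hamming distance <= ``max_mismatches``.
    A read may hit several families and several positions per family.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    read = read.upper()
    fwd = _encode(read)
    rev = _encode(revcomp(read))
    out: dict[str, list[AlignmentHit]] = {}
    for fam, seq in panel.items():
        ref = _encode(seq)
        hits: list[AlignmentHit] = []
        for strand, query in (("+", fwd), ("-", rev)):
            starts, mism = _scan_one(query, ref, max_mismatches)
            hits.extend(
                AlignmentHit(fam, int(s), strand, int(m), len(read))
                for s, m in zip(starts, mism)
            )
        if hits:
            hits.sort()
            out[fam] = hits
    return out


class ConsensusMapper:
    """Batch mismatch-tolerant mapper over a TE consensus panel.

    Seeds candidate positions with exact k-mers (pigeonhole: a read aligned
    with at most ``max_mismatches`` substitutions must match one of
    ``max_mismatches + 1`` disjoint segments exactly) and verifies candidates
    with a vectorised Hamming count.  Produces exactly the hits of
    :func:`map_consensus`.
    """

    def __init__(self, panel: Mapping[str, str], max_mismatches: int = 4):
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.panel = {fam: seq.upper() for fam, seq in panel.items()}
        self.max_mismatches = max_mismatches
        self._n_seg = max_mismatches + 1
        # concatenate family sequences, 255-sentinel separated, so one k-mer
        # index covers the whole panel
        parts: list[np.ndarray] = []
        self._fam_ids: list[str] = []
        self._fam_start: list[int] = []
        self._fam_end: list[int] = []
        off = 0
        for fam, seq in self.panel.items():
            arr = _encode(seq)
            self._fam_ids.append(fam)
            self._fam_start.append(off)
            self._fam_end.append(off + arr.size)
            parts.append(arr)
            parts.append(np.full(1, 255, dtype=np.uint8))
            off += arr.size + 1
        self._cat = (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        )
        self._starts_arr = np.asarray(self._fam_start, dtype=np.intp)
        self._ends_arr = np.asarray(self._fam_end, dtype=np.intp)
        self._index: dict[int, dict[bytes, np.ndarray]] = {}
        self._cache: dict[str, dict[str, list[AlignmentHit]]] = {}

    def _kmer_index(self, k: int) -> dict[bytes, np.ndarray]:
        idx = self._index.get(k)
        if idx is not None:
            return idx
        built: dict[bytes, list[int]] = {}
        cat = self._cat
        data = cat.tobytes()
        for s, e in zip(self._fam_start, self._fam_end):
            for p in range(s, e - k + 1):
                built.setdefault(data[p : p + k], []).append(p)
        idx = {km: np.asarray(v, dtype=np.intp) for km, v in built.items()}
        self._index[k] = idx
        return idx

    def _candidates(self, query: bytes, L: int) -> np.ndarray:
        k = max(1, min(L // self._n_seg, 8))
        idx = self._kmer_index(k)
        # floor-partition boundaries give n_seg disjoint k-mers: with at most
        # max_mismatches substitutions one of them must match exactly
        seg_offsets = [i * L // self._n_seg for i in range(self._n_seg)]
        pools = []
        for off in seg_offsets:
            off = min(off, L - k)
            hit = idx.get(query[off : off + k])
            if hit is not None:
                pools.append(hit - off)
        if not pools:
            return np.empty(0, dtype=np.intp)
        cand = np.unique(np.concatenate(pools))
        cand = cand[(cand >= 0) & (cand + L <= self._cat.size)]
        if cand.size == 0:
            return cand
        # alignment must lie entirely within one family
        fam = np.searchsorted(self._starts_arr, cand, side="right") - 1
        ok = (fam >= 0) & (cand + L <= self._ends_arr[fam])
        return cand[ok]

    def map_read(self, read: str) -> dict[str, list[AlignmentHit]]:
        read = read.upper()
        cached = self._cache.get(read)
        if cached is not None:
            return cached
        L = len(read)
        out: dict[str, list[AlignmentHit]] = {}
        if L == 0:
            return out
        for strand, seq in (("+", read), ("-", revcomp(read))):
            query = _encode(seq)
            cand = self._candidates(query.tobytes(), L)
            if cand.size == 0:
                continue
            windows = self._cat[cand[:, None] + np.arange(L)]
            mism = (windows != query).sum(axis=1)
            keep = mism <= self.max_mismatches
            fams = np.searchsorted(self._starts_arr, cand[keep], "right") - 1
            for pos, m, f in zip(cand[keep], mism[keep], fams):
                fam_id = self._fam_ids[f]
                out.setdefault(fam_id, []).append(
                    AlignmentHit(
                        fam_id, int(pos - self._fam_start[f]), strand, int(m), L
                    )
                )
        for hits in out.values():
            hits.sort()
        self._cache[read] = out
        return out

    def map_many(
        self, reads: Sequence[str]
    ) -> dict[str, dict[str, list[AlignmentHit]]]:
        """Map unique sequences once; returns ``{sequence: hits_by_family}``."""
        return {seq: self.map_read(seq) for seq in dict.fromkeys(reads)}
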