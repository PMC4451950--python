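"""Toy reference bundle for a follicle-cell-like small-RNA system.

The bundle holds one random chromosome carrying two piRNA clusters — a
germline normalizer cluster (42AB-like) and a somatic cluster built from
antisense fragments of soma-dominant TE consensi (flamenco-like) — plus
genic 3'UTR piRNA source intervals, a TE consensus panel, and ncRNA / mature
miRNA sets.  Intervals never overlap and every 23-mer inside a cluster
occurs exactly once in the genome (on either strand), so "genome-unique"
attribution is exact by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import revcomp

__all__ = [
    "Interval",
    "Cluster",
    "TEConsensus",
    "UTRSource",
    "TEFragment",
    "ReferenceBundle",
    "BuildParams",
    "build_reference",
]

GERMLINE_NORMALIZER = "germline_normalizer"
SOMATIC = "somatic"
SOMA_DOMINANT = "soma_dominant"
GERMLINE_DOMINANT = "germline_dominant"

_UNIQ_K = 23  # shortest piRNA length; uniqueness of cluster 23-mers


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval on the single toy chromosome."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Cluster:
    id: str
    interval: Interval
    role: str  # germline_normalizer | somatic
    strand: str  # strand of the piRNA precursor


@dataclass(frozen=True)
class TEConsensus:
    id: str
    sequence: str
    te_class: str  # soma_dominant | germline_dominant

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UTRSource:
    gene_id: str
    interval: Interval
    strand: str


@dataclass(frozen=True)
class TEFragment:
    """A consensus sub-sequence embedded (antisense) inside a cluster."""

    te_id: str
    cluster_id: str
    interval: Interval  # genomic coordinates of the embedded copy
    consensus_start: int
    consensus_end: int


@dataclass
class ReferenceBundle:
    chrom_id: str
    genome: str
    clusters: list[Cluster]
    te_panel: list[TEConsensus]
    utr_sources: list[UTRSource]
    ncrna_set: dict[str, str]
    mirna_set: dict[str, str]
    te_fragments: list[TEFragment] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def cluster(self, cluster_id: str) -> Cluster:
        for c in self.clusters:
            if c.id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def te(self, te_id: str) -> TEConsensus:
        for t in self.te_panel:
            if t.id == te_id:
                return t
        raise KeyError(te_id)

    def utr(self, gene_id: str) -> UTRSource:
        for u in self.utr_sources:
            if u.gene_id == gene_id:
                return u
        raise KeyError(gene_id)

    @property
    def normalizer_cluster(self) -> Cluster:
        for c in self.clusters:
            if c.role == GERMLINE_NORMALIZER:
                return c
        raise ValueError("bundle has no germline_normalizer cluster")

    @property
    def panel_sequences(self) -> dict[str, str]:
        return {t.id: t.sequence for t in self.te_panel}

    def fragments_of_class(self, te_class: str) -> list[TEFragment]:
        classes = {t.id: t.te_class for t in self.te_panel}
        return [f for f in self.te_fragments if classes[f.te_id] == te_class]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.genome)
        feats: list[tuple[str, Interval]] = [
            (c.id, c.interval) for c in self.clusters
        ] + [(u.gene_id, u.interval) for u in self.utr_sources]
        ids = (
            [i for i, _ in feats]
            + [t.id for t in self.te_panel]
            + list(self.ncrna_set)
            + list(self.mirna_set)
        )
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in bundle")
        for fid, iv in feats:
            if iv.end > n:
                raise ValueError(f"{fid} exceeds genome bounds")
        for i, (ai, a) in enumerate(feats):
            for bi, b in feats[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"intervals {ai} and {bi} overlap")
        for frag in self.te_fragments:
            cl = self.cluster(frag.cluster_id)
            if not cl.interval.contains(frag.interval.start, frag.interval.end):
                raise ValueError(f"fragment of {frag.te_id} outside its cluster")
        self._check_cluster_uniqueness()

    def _check_cluster_uniqueness(self) -> None:
        counts = _kmer_counts(self.genome, _UNIQ_K)
        rc = revcomp(self.genome)
        for km, c in _kmer_counts(rc, _UNIQ_K).items():
            counts[km] = counts.get(km, 0) + c
        for cl in self.clusters:
            seq = self.genome[cl.interval.start : cl.interval.end]
            for i in range(len(seq) - _UNIQ_K + 1):
                km = seq[i : i + _UNIQ_K]
                # the k-mer and its reverse complement are the same site
                if counts[km] + counts.get(revcomp(km), 0) > 2:
                    raise ValueError(
                        f"cluster {cl.id} 23-mer at offset {i} recurs in genome"
                    )

    # -- serialisation -----------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        """Write the bundle as FASTA + BED + YAML under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "genome.fasta", {self.chrom_id: self.genome})
        _write_fasta(out / "te_panel.fasta", self.panel_sequences)
        _write_fasta(out / "ncrna.fasta", self.ncrna_set)
        _write_fasta(out / "mirna.fasta", self.mirna_set)
        bed = pd.DataFrame(
            [
                (self.chrom_id, c.interval.start, c.interval.end, c.id, 0, c.strand)
                for c in self.clusters
            ]
            + [
                (self.chrom_id, u.interval.start, u.interval.end, u.gene_id, 0, u.strand)
                for u in self.utr_sources
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        bed.to_csv(out / "features.bed", sep="\t", header=False, index=False)
        meta = {
            "chrom_id": self.chrom_id,
            "cluster_roles": {c.id: c.role for c in self.clusters},
            "utr_genes": [u.gene_id for u in self.utr_sources],
            "te_classes": {t.id: t.te_class for t in self.te_panel},
            "te_fragments": [
                {
                    "te_id": f.te_id,
                    "cluster_id": f.cluster_id,
                    "start": f.interval.start,
                    "end": f.interval.end,
                    "consensus_start": f.consensus_start,
                    "consensus_end": f.consensus_end,
                }
                for f in self.te_fragments
            ],
        }
        with open(out / "bundle.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def read(cls, indir: str | Path) -> "ReferenceBundle":
        ind = Path(indir)
        with open(ind / "bundle.yaml") as fh:
            meta = yaml.safe_load(fh)
        genome = _read_fasta(ind / "genome.fasta")
        panel = _read_fasta(ind / "te_panel.fasta")
        bed = pd.read_csv(
            ind / "features.bed",
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        clusters, utrs = [], []
        roles = meta["cluster_roles"]
        for row in bed.itertuples(index=False):
            iv = Interval(int(row.start), int(row.end))
            if row.name in roles:
                clusters.append(Cluster(row.name, iv, roles[row.name], row.strand))
            else:
                utrs.append(UTRSource(row.name, iv, row.strand))
        frags = [
            TEFragment(
                f["te_id"],
                f["cluster_id"],
                Interval(f["start"], f["end"]),
                f["consensus_start"],
                f["consensus_end"],
            )
            for f in meta.get("te_fragments", [])
        ]
        return cls(
            chrom_id=meta["chrom_id"],
            genome=genome[meta["chrom_id"]],
            clusters=clusters,
            te_panel=[
                TEConsensus(tid, seq, meta["te_classes"][tid])
                for tid, seq in panel.items()
            ],
            utr_sources=utrs,
            ncrna_set=_read_fasta(ind / "ncrna.fasta"),
            mirna_set=_read_fasta(ind / "mirna.fasta"),
            te_fragments=frags,
        )


def _write_fasta(path: Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
    return counts


@dataclass
class BuildParams:
    """Sizes and counts for :func:`build_reference`.

    Defaults give a ~60 kb chromosome with a 6 kb germline normalizer
    cluster, an 8 kb somatic cluster, three soma-dominant and two
    germline-dominant TE consensi of 1.5 kb (one ~1 kb fragment of each
    embedded antisense in the matching cluster), three 1 kb 3'UTR sources,
    four ncRNA stand-ins and eight mature miRNAs.
    """

    genome_length: int = 60_000
    germline_cluster_length: int = 6_000
    somatic_cluster_length: int = 8_000
    n_soma_te: int = 3
    n_germline_te: int = 2
    te_length: int = 1_500
    fragment_length: int = 1_000
    n_utr: int = 3
    utr_length: int = 1_000
    n_ncrna: int = 4
    ncrna_length: int = 150
    n_mirna: int = 8
    te_divergence: float = 0.0  # per-base substitution rate of embedded copies
    max_attempts: int = 20

    def __post_init__(self) -> None:
        if self.te_length < self.fragment_length:
            raise ValueError("fragment_length exceeds te_length")
        if not 1_000 <= self.genome_length:
            raise ValueError("genome_length must be at least 1 kb")
        for name in (
            "germline_cluster_length",
            "somatic_cluster_length",
            "n_soma_te",
            "n_germline_te",
            "te_length",
            "fragment_length",
            "n_utr",
            "utr_length",
            "n_ncrna",
            "ncrna_length",
            "n_mirna",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.te_divergence < 0.1:
            raise ValueError("te_divergence must be in [0, 0.1)")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def build_reference(
    params: BuildParams | None = None, seed: int = 0, **overrides
) -> ReferenceBundle:
    """Build a self-consistent toy reference bundle.

    Deterministic for fixed ``(params, seed)``.  Raises ``ValueError`` when
    the requested features cannot be packed into the requested genome length
    or when a uniqueness-preserving layout cannot be found.
    """
    if params is None:
        params = BuildParams(**overrides)
    elif overrides:
        params = dataclasses.replace(params, **overrides)
    p = params
    footprint = (
        p.germline_cluster_length
        + p.somatic_cluster_length
        + p.n_utr * p.utr_length
    )
    n_feats = 2 + p.n_utr
    if footprint + n_feats + 1 > p.genome_length:
        raise ValueError(
            f"features total {footprint} bp and do not fit in a "
            f"{p.genome_length} bp genome"
        )

    for attempt in range(p.max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        bundle = _try_build(p, rng)
        if bundle is not None:
            return bundle
    raise ValueError(
        "could not build a bundle with genome-unique clusters; "
        "increase genome_length or max_attempts"
    )


def _try_build(p: BuildParams, rng: np.random.Generator) -> ReferenceBundle | None:
    soma_tes = [
        TEConsensus(f"soma_te_{i + 1}", _random_seq(rng, p.te_length), SOMA_DOMINANT)
        for i in range(p.n_soma_te)
    ]
    germ_tes = [
        TEConsensus(
            f"germ_te_{i + 1}", _random_seq(rng, p.te_length), GERMLINE_DOMINANT
        )
        for i in range(p.n_germline_te)
    ]

    def cluster_seq(
        length: int, tes: list[TEConsensus]
    ) -> tuple[str, list[tuple[str, int, int, int]]] | None:
        """Random backbone with one antisense fragment of each consensus."""
        need = len(tes) * p.fragment_length
        if need > length:
            return None
        seq = list(_random_seq(rng, length))
        # non-overlapping fragment placement via sorted gap sampling
        slack = length - need
        cuts = np.sort(rng.integers(0, slack + 1, size=len(tes)))
        placements = []
        for i, te in enumerate(tes):
            start = int(cuts[i]) + i * p.fragment_length
            c0 = int(rng.integers(0, te.length - p.fragment_length + 1))
            frag = te.sequence[c0 : c0 + p.fragment_length]
            frag = _mutate(rng, frag, p.te_divergence)
            seq[start : start + p.fragment_length] = revcomp(frag)
            placements.append((te.id, start, c0, c0 + p.fragment_length))
        return "".join(seq), placements

    germ = cluster_seq(p.germline_cluster_length, germ_tes)
    soma = cluster_seq(p.somatic_cluster_length, soma_tes)
    if germ is None or soma is None:
        raise ValueError("cluster too short for the requested TE fragments")
    germ_seq, germ_frags = germ
    soma_seq, soma_frags = soma

    # place clusters and UTR intervals left to right with random gaps
    blocks = [
        ("cluster_42ab_like", germ_seq, GERMLINE_NORMALIZER),
        ("cluster_flam_like", soma_seq, SOMATIC),
    ] + [(f"utr_gene_{i + 1}", _random_seq(rng, p.utr_length), "utr") for i in range(p.n_utr)]
    total_block = sum(len(s) for _, s, _ in blocks)
    slack = p.genome_length - total_block
    cuts = np.sort(rng.integers(1, slack, size=len(blocks))) if slack > len(blocks) else None
    if cuts is None:
        return None
    genome_parts: list[str] = []
    pos = 0
    placed: dict[str, Interval] = {}
    for i, (name, seq, _role) in enumerate(blocks):
        start = int(cuts[i]) + sum(len(s) for _, s, _ in blocks[:i])
        genome_parts.append(_random_seq(rng, start - pos))
        genome_parts.append(seq)
        placed[name] = Interval(start, start + len(seq))
        pos = start + len(seq)
    genome_parts.append(_random_seq(rng, p.genome_length - pos))
    genome = "".join(genome_parts)

    clusters = [
        Cluster("cluster_42ab_like", placed["cluster_42ab_like"], GERMLINE_NORMALIZER, "+"),
        Cluster("cluster_flam_like", placed["cluster_flam_like"], SOMATIC, "+"),
    ]
    utrs = [
        UTRSource(name, placed[name], "+" if i % 2 == 0 else "-")
        for i, (name, _s, role) in enumerate(blocks)
        if role == "utr"
    ]
    frags = []
    for cl_id, placements in (
        ("cluster_42ab_like", germ_frags),
        ("cluster_flam_like", soma_frags),
    ):
        base = placed[cl_id].start
        for te_id, start, c0, c1 in placements:
            frags.append(
                TEFragment(
                    te_id,
                    cl_id,
                    Interval(base + start, base + start + (c1 - c0)),
                    c0,
                    c1,
                )
            )

    mirnas = {
        f"mir_{i + 1}": _random_seq(rng, int(rng.integers(21, 24)))
        for i in range(p.n_mirna)
    }
    ncrnas = {
        f"ncrna_{i + 1}": _random_seq(rng, p.ncrna_length)
        for i in range(p.n_ncrna)
    }

    bundle = ReferenceBundle(
        chrom_id="chr_toy",
        genome=genome,
        clusters=clusters,
        te_panel=soma_tes + germ_tes,
        utr_sources=utrs,
        ncrna_set=ncrnas,
        mirna_set=mirnas,
        te_fragments=frags,
    )
    try:
        bundle.validate()
    except ValueError:
        return None  # uniqueness clash: rejection-sample a new layout
    return bundle
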