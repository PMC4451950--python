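"""Scenario-driven simulation of small-RNA libraries (18–29 nt).

A :class:`ScenarioConfig` assigns each read source class an abundance weight
and a multiplicative depletion factor; a library of ``n_reads`` reads is
drawn with class probabilities proportional to ``weight x depletion``, which
emulates sequencing a perturbed sample to a fixed depth (depleting one class
inflates the share of the others — exactly the situation the cluster-anchored
normalization is designed to correct).

Source classes
--------------
germline_cluster_piRNA   reads from the 42AB-like normalizer cluster
somatic_cluster_piRNA    reads from the flamenco-like somatic cluster
soma_TE_piRNA            reads from soma-dominant TE fragments (antisense to TE)
germline_TE_piRNA        reads from germline-dominant TE fragments
utr_piRNA                reads from genic 3'UTR intervals
miRNA                    exact mature miRNA sequences
ncRNA_fragment           18–29 nt fragments of rRNA/tRNA/snRNA stand-ins

piRNA-class reads are 23–29 nt with a configurable 1U bias (position-1 T),
implemented by choosing 5'-end positions whose genomic base is T with
probability ``u1_bias`` — reads stay perfect genome mappers.  TE-class reads
optionally carry 1–4 substitutions versus their origin with probability
``mismatch_rate``.  Truth labels (class, origin, strand, substitution count)
are kept in a sidecar table that the analysis pipeline never reads.
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
from .reference import (
    GERMLINE_DOMINANT,
    GERMLINE_NORMALIZER,
    SOMA_DOMINANT,
    SOMATIC,
    Interval,
    ReferenceBundle,
)

__all__ = [
    "SOURCE_CLASSES",
    "PIRNA_CLASSES",
    "ScenarioConfig",
    "SmallRNALibrary",
    "builtin_scenario",
    "simulate_library",
]

SOURCE_CLASSES = (
    "germline_cluster_piRNA",
    "somatic_cluster_piRNA",
    "soma_TE_piRNA",
    "germline_TE_piRNA",
    "utr_piRNA",
    "miRNA",
    "ncRNA_fragment",
)
PIRNA_CLASSES = frozenset(
    {
        "germline_cluster_piRNA",
        "somatic_cluster_piRNA",
        "soma_TE_piRNA",
        "germline_TE_piRNA",
        "utr_piRNA",
    }
)
#: somatic classes depleted together in the miRNA-pathway-loss scenario
SOMATIC_CLASSES = ("somatic_cluster_piRNA", "soma_TE_piRNA")

MIN_READ, MAX_READ = 18, 29
PIRNA_MIN, PIRNA_MAX = 23, 29

# unimodal piRNA length profile peaking at 25–26 nt
_PIRNA_LENGTHS = {23: 0.08, 24: 0.16, 25: 0.26, 26: 0.24, 27: 0.14, 28: 0.08, 29: 0.04}
_MIRNA_LENGTHS = {21: 0.25, 22: 0.55, 23: 0.20}
_NCRNA_LENGTHS = {n: 1 / 12 for n in range(MIN_READ, MAX_READ + 1)}

_DEFAULT_LENGTH_MODEL: dict[str, dict[int, float]] = {
    **{c: dict(_PIRNA_LENGTHS) for c in PIRNA_CLASSES},
    "miRNA": dict(_MIRNA_LENGTHS),
    "ncRNA_fragment": dict(_NCRNA_LENGTHS),
}

#: default follicle-cell-like class mix (weights sum to 1)
_DEFAULT_WEIGHTS = {
    "germline_cluster_piRNA": 0.20,
    "somatic_cluster_piRNA": 0.25,
    "soma_TE_piRNA": 0.20,
    "germline_TE_piRNA": 0.10,
    "utr_piRNA": 0.10,
    "miRNA": 0.10,
    "ncRNA_fragment": 0.05,
}


@dataclass
class ScenarioConfig:
    """Per-class abundances, depletions and read-shape parameters."""

    name: str = "control"
    source_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    depletion: dict[str, float] = field(default_factory=dict)
    length_model: dict[str, dict[int, float]] = field(
        default_factory=lambda: {c: dict(d) for c, d in _DEFAULT_LENGTH_MODEL.items()}
    )
    u1_bias: float = 0.85
    mismatch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        unknown = set(self.source_weights) - set(SOURCE_CLASSES)
        if unknown:
            raise ValueError(f"unknown source classes: {sorted(unknown)}")
        if any(w < 0 for w in self.source_weights.values()):
            raise ValueError("source weights must be non-negative")
        if sum(self.source_weights.values()) <= 0:
            raise ValueError("source weights must sum to a positive value")
        unknown = set(self.depletion) - set(SOURCE_CLASSES)
        if unknown:
            raise ValueError(f"unknown depletion classes: {sorted(unknown)}")
        if any(d <= 0 for d in self.depletion.values()):
            raise ValueError("depletion factors must be > 0")
        if not 0.0 <= self.u1_bias <= 1.0:
            raise ValueError("u1_bias must lie in [0, 1]")
        if not 0.0 <= self.mismatch_rate <= 1.0:
            raise ValueError("mismatch_rate must lie in [0, 1]")
        for cls, dist in self.length_model.items():
            if cls not in SOURCE_CLASSES:
                raise ValueError(f"length model for unknown class {cls}")
            if not dist or any(p < 0 for p in dist.values()) or sum(dist.values()) <= 0:
                raise ValueError(f"invalid length distribution for {cls}")
            lo, hi = (PIRNA_MIN, PIRNA_MAX) if cls in PIRNA_CLASSES else (MIN_READ, MAX_READ)
            if any(not lo <= n <= hi for n in dist):
                raise ValueError(
                    f"{cls} lengths must lie in [{lo}, {hi}]"
                )

    def effective_probs(self) -> dict[str, float]:
        raw = {
            c: self.source_weights.get(c, 0.0) * self.depletion.get(c, 1.0)
            for c in SOURCE_CLASSES
        }
        total = sum(raw.values())
        return {c: v / total for c, v in raw.items()}

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if "length_model" in data:
            data["length_model"] = {
                c: {int(k): float(v) for k, v in d.items()}
                for c, d in data["length_model"].items()
            }
        return cls(**data)


def builtin_scenario(name: str, seed: int = 0) -> ScenarioConfig:
    """Named perturbation scenarios.

    ``wt-drosha`` / ``control``
        the unperturbed follicle-cell-like mix.
    ``tn-drosha``
        miRNA-pathway loss: somatic-cluster, soma-TE and miRNA classes
        depleted fourfold; germline and 3'UTR classes untouched.
    ``yb``
        loss of the somatic piRNA biogenesis machinery: all somatic piRNA
        classes including 3'UTR piRNAs depleted tenfold.
    ``piwi-kd``
        piwi knockdown: strong depletion of every somatic piRNA class.
    """
    key = name.lower().replace("_", "-")
    if key in ("control", "wt-drosha"):
        return ScenarioConfig(name=key, seed=seed)
    if key == "tn-drosha":
        return ScenarioConfig(
            name=key,
            depletion={
                "somatic_cluster_piRNA": 0.25,
                "soma_TE_piRNA": 0.25,
                "miRNA": 0.25,
            },
            seed=seed,
        )
    if key == "yb":
        return ScenarioConfig(
            name=key,
            depletion={
                "somatic_cluster_piRNA": 0.1,
                "soma_TE_piRNA": 0.1,
                "utr_piRNA": 0.1,
            },
            seed=seed,
        )
    if key == "piwi-kd":
        return ScenarioConfig(
            name=key,
            depletion={
                "somatic_cluster_piRNA": 0.2,
                "soma_TE_piRNA": 0.2,
                "utr_piRNA": 0.2,
            },
            seed=seed,
        )
    raise KeyError(f"unknown scenario {name!r}")


@dataclass
class SmallRNALibrary:
    library_id: str
    reads: list[tuple[str, str]]  # (read id, sequence)
    truth: pd.DataFrame | None = None  # sidecar labels, testing only

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids are not unique")
        for rid, seq in self.reads:
            if not MIN_READ <= len(seq) <= MAX_READ:
                raise ValueError(
                    f"read {rid} length {len(seq)} outside [{MIN_READ}, {MAX_READ}]"
                )

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.reads]

    def write_fastq(self, path: str | Path) -> None:
        records = []
        for rid, seq in self.reads:
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)  # 'I'
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")

    def write_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=r, description="") for r, s in self.reads],
            str(path),
            "fasta",
        )

    def write_truth(self, path: str | Path) -> None:
        if self.truth is None:
            raise ValueError("library carries no truth labels")
        self.truth.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fastx(cls, path: str | Path, library_id: str | None = None) -> "SmallRNALibrary":
        path = Path(path)
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta") else "fastq"
        reads = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)
        ]
        return cls(library_id or path.stem, reads)


class _IntervalSampler:
    """Draw piRNA 5' ends from an interval with an exact 1U fraction.

    Candidate 5' positions keep the whole 23–29 nt read inside the interval;
    with probability ``u1`` a position whose genomic 5' base is T is chosen,
    otherwise a non-T position, so the expected position-1 T fraction equals
    ``u1`` exactly.
    """

    def __init__(self, genome: str, interval: Interval, strand: str):
        self.strand = strand
        s, e = interval.start, interval.end
        if e - s < PIRNA_MAX:
            raise ValueError("interval shorter than the longest piRNA")
        if strand == "+":
            pos = np.arange(s, e - PIRNA_MAX + 1)
            is_t = np.frombuffer(
                genome[s : e - PIRNA_MAX + 1].encode(), dtype=np.uint8
            ) == ord("T")
        else:
            pos = np.arange(s + PIRNA_MAX - 1, e)
            # 5' base of a minus-strand read is the complement of the
            # forward base at its rightmost position
            is_t = np.frombuffer(
                genome[s + PIRNA_MAX - 1 : e].encode(), dtype=np.uint8
            ) == ord("A")
        self.t_pos = pos[is_t]
        self.other_pos = pos[~is_t]

    def draw(self, rng: np.random.Generator, want_t: bool) -> int:
        pool = self.t_pos if want_t else self.other_pos
        if pool.size == 0:
            pool = self.other_pos if want_t else self.t_pos
        return int(pool[rng.integers(0, pool.size)])


def _extract(genome: str, five_prime: int, length: int, strand: str) -> str:
    if strand == "+":
        return genome[five_prime : five_prime + length]
    return revcomp(genome[five_prime - length + 1 : five_prime + 1])


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(arr.size, size=min(n_subs, arr.size), replace=False)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in pos:
        arr[i] = rng.choice(bases[bases != arr[i]])
    return arr.tobytes().decode("ascii")


def simulate_library(
    bundle: ReferenceBundle,
    scenario: ScenarioConfig,
    n_reads: int,
    library_id: str | None = None,
) -> SmallRNALibrary:
    """Draw a labelled library of ``n_reads`` reads under a scenario.

    Deterministic for fixed ``(bundle, scenario, n_reads)``; the random
    stream is seeded from ``scenario.seed``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    scenario.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 911]))
    lib_id = library_id or f"{scenario.name}_s{scenario.seed}"

    probs = scenario.effective_probs()
    classes = list(SOURCE_CLASSES)
    pvec = np.array([probs[c] for c in classes])
    draw = rng.choice(len(classes), size=n_reads, p=pvec)

    # per-class source pools
    germ_cl = [c for c in bundle.clusters if c.role == GERMLINE_NORMALIZER]
    soma_cl = [c for c in bundle.clusters if c.role == SOMATIC]
    pools: dict[str, list[tuple[str, _IntervalSampler]]] = {}

    def interval_pool(feats: list[tuple[str, Interval, str]]) -> list:
        return [
            (fid, _IntervalSampler(bundle.genome, iv, strand))
            for fid, iv, strand in feats
        ]

    pools["germline_cluster_piRNA"] = interval_pool(
        [(c.id, c.interval, c.strand) for c in germ_cl]
    )
    pools["somatic_cluster_piRNA"] = interval_pool(
        [(c.id, c.interval, c.strand) for c in soma_cl]
    )
    cl_strand = {c.id: c.strand for c in bundle.clusters}
    pools["soma_TE_piRNA"] = interval_pool(
        [
            (f.te_id, f.interval, cl_strand[f.cluster_id])
            for f in bundle.fragments_of_class(SOMA_DOMINANT)
            if f.interval.length >= PIRNA_MAX
        ]
    )
    pools["germline_TE_piRNA"] = interval_pool(
        [
            (f.te_id, f.interval, cl_strand[f.cluster_id])
            for f in bundle.fragments_of_class(GERMLINE_DOMINANT)
            if f.interval.length >= PIRNA_MAX
        ]
    )
    pools["utr_piRNA"] = interval_pool(
        [(u.gene_id, u.interval, u.strand) for u in bundle.utr_sources]
    )
    for cls_name in PIRNA_CLASSES:
        if draw.size and not pools[cls_name] and pvec[classes.index(cls_name)] > 0:
            raise ValueError(f"bundle provides no sources for class {cls_name}")
    mirna_ids = sorted(bundle.mirna_set)
    ncrna_ids = sorted(bundle.ncrna_set)

    len_dists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls_name, dist in scenario.length_model.items():
        lens = np.array(sorted(dist))
        p = np.array([dist[int(n)] for n in lens], dtype=float)
        len_dists[cls_name] = (lens, p / p.sum())

    # pre-draw per-read vectors (one RNG pass per class keeps the loop cheap)
    lengths_all = np.zeros(n_reads, dtype=np.int64)
    for ci, cls_name in enumerate(classes):
        idx = np.nonzero(draw == ci)[0]
        if idx.size == 0 or cls_name == "miRNA":
            continue
        lens, p = len_dists[cls_name]
        lengths_all[idx] = lens[rng.choice(lens.size, size=idx.size, p=p)]
    want_t_all = rng.random(n_reads) < scenario.u1_bias
    sub_flag = rng.random(n_reads) < scenario.mismatch_rate

    rows = []
    reads: list[tuple[str, str]] = []
    for i, ci in enumerate(draw):
        cls_name = classes[ci]
        rid = f"r{i:07d}"
        if cls_name == "miRNA":
            mid = mirna_ids[rng.integers(0, len(mirna_ids))]
            seq = bundle.mirna_set[mid]
            rows.append((rid, cls_name, mid, -1, ".", len(seq), 0))
        elif cls_name == "ncRNA_fragment":
            nid = ncrna_ids[rng.integers(0, len(ncrna_ids))]
            src = bundle.ncrna_set[nid]
            L = min(int(lengths_all[i]), len(src))
            start = int(rng.integers(0, len(src) - L + 1))
            seq = src[start : start + L]
            rows.append((rid, cls_name, nid, start, "+", L, 0))
        else:
            pool = pools[cls_name]
            fid, sampler = pool[rng.integers(0, len(pool))]
            L = int(lengths_all[i])
            fp = sampler.draw(rng, bool(want_t_all[i]))
            seq = _extract(bundle.genome, fp, L, sampler.strand)
            n_subs = 0
            if cls_name in ("soma_TE_piRNA", "germline_TE_piRNA") and sub_flag[i]:
                n_subs = int(rng.integers(1, 5))
                seq = _substitute(rng, seq, n_subs)
            rows.append((rid, cls_name, fid, fp, sampler.strand, L, n_subs))
        reads.append((rid, seq))

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "source_class",
            "feature_id",
            "five_prime",
            "strand",
            "length",
            "n_substitutions",
        ],
    )
    return SmallRNALibrary(lib_id, reads, truth)
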