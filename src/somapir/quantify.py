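"""Cluster-anchored normalization, per-feature counting and 5'-end profiles.

Libraries are made comparable by scaling each to one million genome-unique
piRNAs from the germline normalizer cluster (a locus unaffected by the
somatic perturbations under study), so somatic depletion shows up as a real
drop rather than being hidden by fixed sequencing depth.  On the scaled
counts the module computes per-TE-family abundance (mismatch-tolerant
consensus mapping), per-interval abundance for clusters and 3'UTR sources
(genome-unique perfect mappers only), 5'-end-collapsed coverage profiles,
pairwise scatter comparisons with Pearson r, condition/control fold changes,
and RNA-IP enrichment (per-million genome-unique scaling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import ConsensusMapper
from .annotate import AnnotatedRead, AnnotationBreakdown
from .reference import Cluster, Interval, ReferenceBundle, UTRSource

__all__ = [
    "CountTable",
    "ProfileTrack",
    "ComparisonResult",
    "normalization_factor",
    "te_counts",
    "interval_counts",
    "profile_feature",
    "compare_libraries",
    "fold_changes",
    "rip_enrichment",
]

NORMALIZER_TARGET = 1_000_000


@dataclass
class CountTable:
    """Per-feature sense/antisense raw counts with a library scale factor.

    ``data`` is indexed by feature id with columns ``feature_class``,
    ``sense``, ``antisense`` (raw read counts) and ``total_normalized``
    (= (sense + antisense) x scale_factor).
    """

    library_id: str
    scale_factor: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale factor must be positive")
        if (self.data[["sense", "antisense"]] < 0).any().any():
            raise ValueError("negative counts")
        expected = (self.data["sense"] + self.data["antisense"]) * self.scale_factor
        if not np.allclose(self.data["total_normalized"], expected):
            raise ValueError("total_normalized inconsistent with scale factor")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")


def _count_table(
    library_id: str,
    scale_factor: float,
    rows: dict[str, tuple[str, int, int]],
) -> CountTable:
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["feature_class", "sense", "antisense"]
    )
    df.index.name = "feature_id"
    df["total_normalized"] = (df["sense"] + df["antisense"]) * scale_factor
    return CountTable(library_id, scale_factor, df)


@dataclass
class ProfileTrack:
    """5'-end-collapsed coverage along one feature.

    ``sense``/``antisense`` are non-negative vectors of length ``length``;
    position 0 is the feature's own 5' end (for minus-strand genomic
    features the axis follows the feature, not the chromosome).  Exported
    tables are 1-based and negate the antisense track, mirroring the usual
    up/down rendering.
    """

    feature_id: str
    length: int
    sense: np.ndarray
    antisense: np.ndarray
    policy: str  # genome_unique_only | all_hits
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sense.shape != (self.length,) or self.antisense.shape != (self.length,):
            raise ValueError("profile vectors must match feature length")
        if (self.sense < 0).any() or (self.antisense < 0).any():
            raise ValueError("profile vectors must be non-negative")

    @property
    def normalized(self) -> bool:
        return self.scale_factor != 1.0

    @property
    def total_mass(self) -> float:
        return float(self.sense.sum() + self.antisense.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "sense": self.sense,
                "antisense": -self.antisense,
            }
        )


def normalization_factor(
    breakdown: AnnotationBreakdown, normalizer: str
) -> float:
    """Scale factor bringing the normalizer cluster to one million
    genome-unique piRNAs.

    Raises ``ValueError`` when the library has no genome-unique piRNA in the
    normalizer cluster (such a library cannot be normalized).
    """
    try:
        count = breakdown.cluster_unique_pirna[normalizer]
    except KeyError:
        raise KeyError(f"no cluster {normalizer!r} in breakdown") from None
    if count <= 0:
        raise ValueError(
            f"library {breakdown.library_id!r} has no genome-unique piRNA in "
            f"normalizer cluster {normalizer!r}; cannot normalize"
        )
    return NORMALIZER_TARGET / count


def te_counts(
    annotated: Sequence[AnnotatedRead],
    panel: Mapping[str, str],
    panel_classes: Mapping[str, str] | None = None,
    max_mismatches: int = 4,
    scale_factor: float = 1.0,
    library_id: str = "",
    mapper: ConsensusMapper | None = None,
) -> CountTable:
    """Per-TE-family piRNA counts under mismatch-tolerant consensus mapping.

    Every piRNA-category read contributes one count to each family it hits
    (once per family, regardless of how many positions it matches), assigned
    to the strand of its best (fewest-mismatch) hit in that family.
    """
    if not panel:
        raise ValueError("empty TE panel")
    if mapper is None:
        mapper = ConsensusMapper(panel, max_mismatches)
    pirna = [r for r in annotated if r.category == "piRNA"]
    hit_sets = mapper.map_many([r.sequence for r in pirna])
    rows = {
        fam: [panel_classes.get(fam, "TE") if panel_classes else "TE", 0, 0]
        for fam in panel
    }
    for r in pirna:
        for fam, hits in hit_sets[r.sequence].items():
            best = min(hits, key=lambda h: (h.mismatches, h.strand != "+"))
            rows[fam][1 if best.strand == "+" else 2] += 1
    return _count_table(
        library_id, scale_factor, {f: tuple(v) for f, v in rows.items()}
    )


def _interval_features(
    bundle: ReferenceBundle,
) -> list[tuple[str, str, Interval, str]]:
    feats = [
        (c.id, f"cluster_{c.role}", c.interval, c.strand) for c in bundle.clusters
    ]
    feats += [(u.gene_id, "utr", u.interval, u.strand) for u in bundle.utr_sources]
    return feats


def interval_counts(
    annotated: Sequence[AnnotatedRead],
    bundle: ReferenceBundle,
    scale_factor: float = 1.0,
    library_id: str = "",
) -> CountTable:
    """Genome-unique piRNA counts per cluster / 3'UTR interval.

    Sense means the read's alignment strand equals the feature strand.
    """
    feats = _interval_features(bundle)
    rows = {fid: [fclass, 0, 0] for fid, fclass, _iv, _s in feats}
    for r in annotated:
        if r.category != "piRNA" or not r.genome_unique:
            continue
        hit = r.genome_hits[0]
        for fid, _fclass, iv, strand in feats:
            if iv.contains(hit.start, hit.end):
                rows[fid][1 if hit.strand == strand else 2] += 1
                break
    return _count_table(
        library_id, scale_factor, {f: tuple(v) for f, v in rows.items()}
    )


def profile_feature(
    annotated: Sequence[AnnotatedRead],
    feature: str,
    bundle: ReferenceBundle,
    scale_factor: float = 1.0,
    max_mismatches: int = 4,
    mapper: ConsensusMapper | None = None,
) -> ProfileTrack:
    """5'-end density along a TE consensus, cluster or 3'UTR.

    TE consensi are profiled with every mismatch-tolerant hit (positional
    multiplicity retained); clusters and 3'UTRs with genome-unique perfect
    mappers only, per the two uniqueness policies the counting uses.  Each
    qualifying hit adds ``scale_factor`` at the read's 5'-end coordinate in
    the strand-appropriate vector.
    """
    panel = bundle.panel_sequences
    if feature in panel:
        length = len(panel[feature])
        sense = np.zeros(length)
        anti = np.zeros(length)
        if mapper is None:
            mapper = ConsensusMapper({feature: panel[feature]}, max_mismatches)
        pirna = [r for r in annotated if r.category == "piRNA"]
        hit_sets = mapper.map_many([r.sequence for r in pirna])
        for r in pirna:
            for hit in hit_sets[r.sequence].get(feature, []):
                vec = sense if hit.strand == "+" else anti
                vec[hit.five_prime] += scale_factor
        return ProfileTrack(feature, length, sense, anti, "all_hits", scale_factor)

    for fid, _fclass, iv, strand in _interval_features(bundle):
        if fid != feature:
            continue
        length = iv.length
        sense = np.zeros(length)
        anti = np.zeros(length)
        for r in annotated:
            if r.category != "piRNA" or not r.genome_unique:
                continue
            hit = r.genome_hits[0]
            if not iv.contains(hit.start, hit.end):
                continue
            # coordinate along the feature's own orientation
            local = (
                hit.five_prime - iv.start
                if strand == "+"
                else iv.end - 1 - hit.five_prime
            )
            vec = sense if hit.strand == strand else anti
            vec[local] += scale_factor
        return ProfileTrack(
            feature, length, sense, anti, "genome_unique_only", scale_factor
        )
    raise KeyError(f"unknown feature {feature!r}")


@dataclass
class ComparisonResult:
    data: pd.DataFrame  # feature_id-indexed columns a, b (normalized totals)
    pearson_r: float
    r_defined: bool
    library_a: str = ""
    library_b: str = ""


def _check_same_panel(a: CountTable, b: CountTable) -> None:
    if list(a.features) != list(b.features):
        raise ValueError("count tables cover different feature panels")


def compare_libraries(
    a: CountTable, b: CountTable, log_scale: bool = False
) -> ComparisonResult:
    """Paired normalized totals per feature plus Pearson r over all features.

    With ``log_scale`` the correlation is computed on log10(x + 1).  With
    fewer than two features or a zero-variance vector r is undefined and
    flagged (NaN).
    """
    _check_same_panel(a, b)
    df = pd.DataFrame(
        {
            "a": a.data["total_normalized"].to_numpy(),
            "b": b.data["total_normalized"].to_numpy(),
        },
        index=a.features,
    )
    x, y = df["a"].to_numpy(float), df["b"].to_numpy(float)
    if log_scale:
        x, y = np.log10(x + 1), np.log10(y + 1)
    if len(df) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return ComparisonResult(df, float("nan"), False, a.library_id, b.library_id)
    r = float(sps.pearsonr(x, y).statistic)
    return ComparisonResult(df, r, True, a.library_id, b.library_id)


def fold_changes(
    condition: CountTable, control: CountTable, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-feature (condition + pc) / (control + pc) on normalized totals."""
    _check_same_panel(condition, control)
    cond = condition.data["total_normalized"].to_numpy(float)
    ctrl = control.data["total_normalized"].to_numpy(float)
    return pd.DataFrame(
        {
            "feature_class": condition.data["feature_class"].to_numpy(),
            "condition": cond,
            "control": ctrl,
            "fold_change": (cond + pseudocount) / (ctrl + pseudocount),
        },
        index=condition.features,
    )


def rip_enrichment(
    ip_annotated: Sequence[AnnotatedRead],
    input_annotated: Sequence[AnnotatedRead],
    bundle: ReferenceBundle,
    pseudocount: float = 1.0,
    ip_id: str = "IP",
    input_id: str = "input",
) -> pd.DataFrame:
    """Per-feature IP/input enrichment for RNA-IP libraries.

    Each library is scaled to one million genome-unique reads (all
    categories), features are counted as genome-unique reads contained in
    each cluster / 3'UTR interval, and enrichment is the pseudocounted ratio
    of the scaled counts.  Raises when either library has no genome-unique
    read.
    """
    feats = _interval_features(bundle)

    def scaled_counts(annotated: Sequence[AnnotatedRead], label: str) -> np.ndarray:
        unique = [r for r in annotated if r.genome_unique]
        if not unique:
            raise ValueError(f"{label} library has no genome-unique read")
        scale = NORMALIZER_TARGET / len(unique)
        counts = np.zeros(len(feats))
        for r in unique:
            hit = r.genome_hits[0]
            for i, (_fid, _fc, iv, _s) in enumerate(feats):
                if iv.contains(hit.start, hit.end):
                    counts[i] += 1
                    break
        return counts * scale

    ip = scaled_counts(ip_annotated, ip_id)
    inp = scaled_counts(input_annotated, input_id)
    return pd.DataFrame(
        {
            "feature_class": [fc for _fid, fc, _iv, _s in feats],
            "ip_scaled": ip,
            "input_scaled": inp,
            "enrichment": (ip + pseudocount) / (inp + pseudocount),
        },
        index=pd.Index([fid for fid, _fc, _iv, _s in feats], name="feature_id"),
    )
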