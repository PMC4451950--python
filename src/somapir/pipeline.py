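"""End-to-end workflow: simulate (or load) libraries, annotate, normalize,
count, profile, compare, and test — writing one tidy TSV per product.

A :class:`RunConfig` drives the run.  Everything randomised is derived from
the config seed, outputs carry no timestamps, and tables are written with
fixed column order, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import quantify as qt
from .align import ConsensusMapper
from .reference import BuildParams, ReferenceBundle, build_reference
from .simulate import (
    ScenarioConfig,
    SmallRNALibrary,
    builtin_scenario,
    simulate_library,
)
from .stats import bh_adjust, compare_two_samples

logger = logging.getLogger("somapir")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and the offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: str = "results"
    reference_dir: str | None = None  # load a bundle; None -> build one
    scenarios: list[str] = field(default_factory=lambda: ["wt-drosha", "tn-drosha"])
    library_paths: dict[str, str] = field(default_factory=dict)  # id -> FASTQ/FASTA
    comparisons: list[list[str]] = field(default_factory=list)  # [condition, control]
    n_reads: int = 200_000
    seed: int = 0
    max_mismatches: int = 4
    pirna_range: list[int] = field(default_factory=lambda: [23, 29])
    sirna_length: int = 21
    normalizer_cluster: str | None = None  # default: the germline normalizer
    fold_change_pseudocount: float = 1.0
    profile_pseudocount: float = 0.0
    gate_alpha: float = 0.05
    profile_features: list[str] = field(default_factory=list)  # default: all

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if list(self.pirna_range) != [23, 29]:
            raise ValueError("pirna_range is fixed at [23, 29] in this pipeline")
        if self.sirna_length != 21:
            raise ValueError("sirna_length is fixed at 21 in this pipeline")
        if not 0 < self.gate_alpha < 1:
            raise ValueError("gate_alpha must lie in (0, 1)")
        if self.fold_change_pseudocount < 0 or self.profile_pseudocount < 0:
            raise ValueError("pseudocounts must be non-negative")
        for pair in self.comparisons:
            if len(pair) != 2:
                raise ValueError("each comparison must be [condition, control]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(stage: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # surface the failing stage
                raise PipelineError(stage, str(exc)) from exc

        return inner

    return wrap


@_stage("reference")
def _get_reference(cfg: RunConfig) -> ReferenceBundle:
    if cfg.reference_dir is not None:
        logger.info("loading reference bundle from %s", cfg.reference_dir)
        return ReferenceBundle.read(cfg.reference_dir)
    logger.info("building default reference bundle (seed=%d)", cfg.seed)
    return build_reference(BuildParams(), seed=cfg.seed)


@_stage("libraries")
def _get_libraries(cfg: RunConfig, bundle: ReferenceBundle) -> list[SmallRNALibrary]:
    libs: list[SmallRNALibrary] = []
    for lib_id, path in sorted(cfg.library_paths.items()):
        logger.info("loading library %s from %s", lib_id, path)
        libs.append(SmallRNALibrary.from_fastx(path, lib_id))
    for i, name in enumerate(cfg.scenarios):
        scenario = builtin_scenario(name, seed=cfg.seed + i)
        logger.info("simulating %d reads for scenario %s", cfg.n_reads, name)
        libs.append(simulate_library(bundle, scenario, cfg.n_reads, library_id=name))
    if not libs:
        raise ValueError("no libraries: provide library_paths or scenarios")
    return libs


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the whole chain and return the result directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = _get_reference(cfg)
    normalizer = cfg.normalizer_cluster or bundle.normalizer_cluster.id
    libraries = _get_libraries(cfg, bundle)
    panel = bundle.panel_sequences
    panel_classes = {t.id: t.te_class for t in bundle.te_panel}
    mapper = ConsensusMapper(panel, cfg.max_mismatches)

    te_tables: dict[str, qt.CountTable] = {}
    iv_tables: dict[str, qt.CountTable] = {}
    breakdown_frames = []
    for lib in libraries:
        lid = lib.library_id
        annotated = _stage("annotate")(ann.classify_reads)(lib, bundle)
        breakdown = _stage("annotate")(ann.summarize)(annotated, bundle, lid)
        breakdown_frames.append(breakdown.to_frame())
        scale = _stage("normalize")(qt.normalization_factor)(breakdown, normalizer)
        logger.info("library %s: scale factor %.6g", lid, scale)
        te_tables[lid] = _stage("te_counts")(qt.te_counts)(
            annotated, panel, panel_classes, cfg.max_mismatches, scale, lid, mapper
        )
        iv_tables[lid] = _stage("interval_counts")(qt.interval_counts)(
            annotated, bundle, scale, lid
        )
        lib_dir = out / "libraries" / lid
        lib_dir.mkdir(parents=True, exist_ok=True)
        te_tables[lid].to_tsv(lib_dir / "te_counts.tsv")
        iv_tables[lid].to_tsv(lib_dir / "interval_counts.tsv")
        feats = cfg.profile_features or (
            list(panel) + [c.id for c in bundle.clusters] + [u.gene_id for u in bundle.utr_sources]
        )
        for feat in feats:
            track = _stage("profile")(qt.profile_feature)(
                annotated, feat, bundle, scale, cfg.max_mismatches,
                mapper if feat in panel else None,
            )
            track.to_frame().to_csv(
                lib_dir / f"profile_{feat}.tsv", sep="\t", index=False
            )
        hist = ann.size_histogram(annotated)
        hist.to_csv(lib_dir / "length_histogram.tsv", sep="\t")
        comp = ann.base_composition(annotated, ["piRNA"], positions=10)
        comp.to_csv(lib_dir / "base_composition.tsv", sep="\t")

    pd.concat(breakdown_frames, ignore_index=True).to_csv(
        out / "annotation_breakdown.tsv", sep="\t", index=False
    )

    comparisons = cfg.comparisons or (
        [[libraries[i].library_id, libraries[0].library_id] for i in range(1, len(libraries))]
    )
    for cond_id, ctrl_id in comparisons:
        if cond_id not in te_tables or ctrl_id not in te_tables:
            raise PipelineError("compare", f"unknown library in comparison {cond_id} vs {ctrl_id}")
        cdir = out / "comparisons" / f"{cond_id}_vs_{ctrl_id}"
        cdir.mkdir(parents=True, exist_ok=True)
        res = _stage("compare")(qt.compare_libraries)(te_tables[cond_id], te_tables[ctrl_id])
        res.data.assign(pearson_r=res.pearson_r).to_csv(
            cdir / "te_scatter.tsv", sep="\t", index_label="feature_id"
        )
        fc_te = _stage("compare")(qt.fold_changes)(
            te_tables[cond_id], te_tables[ctrl_id], cfg.fold_change_pseudocount
        )
        fc_te.to_csv(cdir / "te_fold_changes.tsv", sep="\t", index_label="feature_id")
        fc_iv = _stage("compare")(qt.fold_changes)(
            iv_tables[cond_id], iv_tables[ctrl_id], cfg.fold_change_pseudocount
        )
        fc_iv.to_csv(cdir / "interval_fold_changes.tsv", sep="\t", index_label="feature_id")

        # per-feature-class comparison of normalized counts
        rows = []
        fc_all = pd.concat([fc_te, fc_iv])
        for fclass, sub in fc_all.groupby("feature_class", sort=True):
            if len(sub) < 2:
                continue
            result = compare_two_samples(
                sub["condition"], sub["control"], cfg.gate_alpha
            )
            rows.append(
                (
                    fclass,
                    len(sub),
                    result.test_used,
                    result.statistic,
                    result.p_value,
                )
            )
        tests = pd.DataFrame(
            rows, columns=["feature_class", "n_features", "test_used", "statistic", "p_value"]
        )
        if len(tests):
            tests["p_adjusted"] = bh_adjust(tests["p_value"].to_numpy())
        tests.to_csv(cdir / "tests.tsv", sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "normalizer_cluster": normalizer,
        "libraries": [lib.library_id for lib in libraries],
        "comparisons": comparisons,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
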