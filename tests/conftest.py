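"""Shared fixtures: a small reference bundle and simulated libraries.

Oracle helpers (pure-Python brute-force mappers) live here so that several
test modules can check the optimised aligners against the same naive scan.
"""

from __future__ import annotations

import numpy as np
import pytest

from somapir.align import AlignmentHit, revcomp
from somapir.annotate import classify_reads, summarize
from somapir.reference import BuildParams, build_reference
from somapir.simulate import ScenarioConfig, builtin_scenario, simulate_library

SMALL_PARAMS = BuildParams(
    genome_length=24_000,
    germline_cluster_length=2_500,
    somatic_cluster_length=3_000,
    n_soma_te=2,
    n_germline_te=1,
    te_length=600,
    fragment_length=450,
    n_utr=2,
    utr_length=400,
    n_ncrna=3,
    ncrna_length=120,
    n_mirna=5,
)


@pytest.fixture(scope="session")
def bundle():
    return build_reference(SMALL_PARAMS, seed=7)


@pytest.fixture(scope="session")
def control_library(bundle):
    return simulate_library(
        bundle, builtin_scenario("control", seed=41), 12_000, library_id="ctrl"
    )


@pytest.fixture(scope="session")
def annotated_control(bundle, control_library):
    return classify_reads(control_library, bundle)


@pytest.fixture(scope="session")
def breakdown_control(bundle, annotated_control):
    return summarize(annotated_control, bundle, "ctrl")


# ---------------------------------------------------------------------------
# naive oracles
# ---------------------------------------------------------------------------


def brute_map_perfect(read: str, genome: str, reference_id: str = "genome"):
    """Position-by-position exact scan on both strands."""
    read = read.upper()
    hits = []
    for strand, query in (("+", read), ("-", revcomp(read))):
        for start in range(len(genome) - len(read) + 1):
            if genome[start : start + len(read)] == query:
                hits.append(AlignmentHit(reference_id, start, strand, 0, len(read)))
    return sorted(hits)


def brute_map_consensus(read: str, panel: dict[str, str], max_mismatches: int = 4):
    """Exhaustive Hamming scan of every offset, both strands, per family."""
    read = read.upper()
    out: dict[str, list[AlignmentHit]] = {}
    for fam, seq in panel.items():
        hits = []
        for strand, query in (("+", read), ("-", revcomp(read))):
            for start in range(len(seq) - len(read) + 1):
                mism = sum(
                    1 for x, y in zip(seq[start : start + len(read)], query) if x != y
                )
                if mism <= max_mismatches:
                    hits.append(AlignmentHit(fam, start, strand, mism, len(read)))
        if hits:
            out[fam] = sorted(hits)
    return out


def random_reads(bundle, n: int, seed: int) -> list[str]:
    """Seeded read mix: genome/TE-derived (with substitutions) and random."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    reads = []
    sources = [t.sequence for t in bundle.te_panel] + [bundle.genome]
    for _ in range(n):
        L = int(rng.integers(18, 30))
        kind = rng.random()
        if kind < 0.2:
            seq = "".join(bases[rng.integers(0, 4, L)])
        else:
            src = sources[rng.integers(0, len(sources))]
            s = int(rng.integers(0, len(src) - L))
            arr = list(src[s : s + L])
            for _ in range(int(rng.integers(0, 6))):
                arr[int(rng.integers(0, L))] = str(bases[rng.integers(0, 4)])
            seq = "".join(arr)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(seq)
    return reads
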