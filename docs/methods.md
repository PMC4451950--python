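# Methods

## The analysis model

`somapir` quantifies class-specific changes in piRNA populations between
small-RNA libraries from *Drosophila* ovarian somatic (follicle) cells.
The object of inference is a per-feature normalized count: for a feature
*f* (a TE family, a piRNA cluster, or a genic 3'UTR) in library *ℓ*,

    N_f(ℓ) = scale(ℓ) · (# qualifying reads of ℓ attributed to f),

with `scale(ℓ) = 10⁶ / U₄₂AB(ℓ)`, where `U₄₂AB(ℓ)` is the number of
piRNA-category reads of *ℓ* mapping genome-uniquely inside the germline
normalizer cluster. The anchor is a locus unaffected by somatic
perturbations, so a genuine somatic depletion appears as a drop in `N_f`
rather than being absorbed by the fixed sequencing depth. After scaling,
the normalizer's own unique piRNA mass is 10⁶ in every library by
construction; this identity is asserted in the tests and recomputed by the
acceptance script.

Attribution rules differ by feature type and are deliberately asymmetric:

* **TE families** — ungapped alignment of the read (both strands) to the
  family consensus with a Hamming budget of 4 substitutions; a read counts
  once per family regardless of how many positions it matches, assigned to
  the strand of its fewest-mismatch hit. Positional multiplicity is kept
  only in profiles.
* **Clusters and 3'UTRs** — genome-unique perfect mappers whose single
  alignment lies entirely within the interval; sense means alignment
  strand equals feature strand.

5'-end profiles collapse each qualifying alignment to its 5' coordinate
(for antisense alignments, the rightmost aligned base on the forward
strand, so antisense peaks sit at biological piRNA 5' ends) and add the
library scale factor there. Interval profiles follow the feature's own
orientation, so position 1 is the feature's 5' end on its coding strand.

### Annotation cascade

Each read gets exactly one category, in fixed order: exact substring of an
abundant ncRNA (stored strand only) → exact full-length identity with a
mature miRNA → perfect genome mapping (no hit: nonmapper) → size class
(21 nt siRNA; 23–29 nt piRNA; mappers of 18–20/22 nt stay `unclassified`).
Exact matching is used for the ncRNA and miRNA stages because it is the
reproducible reading of "matching"/"identity"; there is no isomiR
tolerance. T stands in for U throughout.

### Mapping machinery

Perfect genome mapping uses a 15-mer prefix index with full-length
verification; 15 nt is also the guard below which queries are rejected
(shorter queries produce meaningless multi-mappers on a toy genome).
Consensus mapping has two equivalent routes: a per-read sliding-window
Hamming scan (reference semantics) and a pigeonhole-seeded batch mapper
(a read within 4 substitutions must contain one of 5 disjoint exact
k-mers) used for whole-library quantification. The test suite holds both
routes equal to a pure-Python position-by-position scan on 500 seeded
reads. Alignments are substitution-only; indels are out of scope because
piRNA-to-consensus comparison in this setting is defined by a mismatch
budget alone.

## The synthetic-data generator

The generator builds a single-chromosome toy reference (default 60 kb,
i.i.d. base composition 0.25 each) carrying:

* a 6 kb **germline normalizer cluster** (42AB-like, `+` strand) with one
  ~1 kb antisense fragment of each germline-dominant TE consensus;
* an 8 kb **somatic cluster** (flamenco-like, `+` strand) with one ~1 kb
  antisense fragment of each soma-dominant TE consensus;
* three 1 kb genic **3'UTR intervals** (tj/jim-like, alternating strand);
* a panel of five random **TE consensi** (3 soma-dominant, 2
  germline-dominant, 1.5 kb each), four **ncRNA** stand-ins and eight
  **mature miRNAs** (21–23 nt).

Fragments are embedded as exact antisense copies (a `te_divergence` knob
exists, default 0), and a rejection-sampling check guarantees that every
cluster 23-mer occurs exactly once in the genome on either strand — so
"genome-unique" is exact, not probabilistic, for cluster reads. Intervals
never overlap.

Libraries are drawn read-by-read from seven source classes
(germline/somatic cluster piRNA, soma/germline TE piRNA, 3'UTR piRNA,
miRNA, ncRNA fragment) with probability ∝ weight × depletion, emulating
sequencing a perturbed sample to fixed depth: depleting one class inflates
the others' shares, which is exactly the distortion the cluster-anchored
normalization must undo. piRNA lengths follow a unimodal 23–29 nt profile
peaking at 25–26 nt; the 1U bias (default 0.85) is implemented by sampling
5'-end positions whose genomic base is T with the configured probability,
so simulated piRNAs remain perfect genome mappers and the position-1 T
fraction equals the parameter in expectation. TE-class reads are drawn
from the embedded genomic fragments; with probability `mismatch_rate`
(default 0) a read receives 1–4 substitutions. Because the toy fragments
are exact consensus copies, such substituted reads are genome nonmappers —
unlike real diverged TE insertions, whose reads map perfectly to the
genome while mismatching the consensus. This is the main respect in which
passing tests do not certify behaviour on real libraries; the ≤4-mismatch
machinery is therefore exercised directly by the alignment oracle tests
rather than through the default simulation. Other real-data features the
generator deliberately omits: sequencing errors, adapters, ping-pong
signatures (absent from this soma-only system), and multi-chromosome
genomes.

The default follicle-cell class mix (weights 0.20 germline cluster, 0.25
somatic cluster, 0.20 soma TE, 0.10 germline TE, 0.10 3'UTR, 0.10 miRNA,
0.05 ncRNA) is a choice, not a measured quantity — no per-class abundances
are available for this tissue at this granularity; it gives every
downstream statistic comfortable counts at 2×10⁵ reads. The named
scenarios encode the perturbations studied: `tn-drosha` depletes the
somatic cluster, soma-TE and miRNA classes fourfold (miRNA-pathway loss
spares germline and 3'UTR piRNAs); `yb` depletes all somatic classes
including 3'UTRs tenfold (loss of the somatic biogenesis machinery);
`piwi-kd` similarly at fivefold. Truth labels go to a sidecar table only;
the pipeline never reads them.

## Statistical procedure

`compare_two_samples` runs Shapiro–Wilk on each series; if both pass at
the gate alpha (0.05, recorded in every result), Levene's test chooses
between pooled Student's t and Welch's t; any normality failure — or a
series too short (< 3) or constant, where Shapiro–Wilk is undefined —
falls to Mann–Whitney with continuity correction (exact null when both
n ≤ 8 and no ties, midrank/normal approximation otherwise). Welch on
Levene failure is a completion choice: testing homogeneity implies acting
on it, and Welch is the conservative action. All tests are two-tailed.
Monte-Carlo calibration (1,000 null pairs, n = 10) keeps the realized
type-I error within binomial noise of 0.05 and power > 0.8 at a 2-SD
shift; both numbers are recomputed by the acceptance script.
`bh_adjust` is the standard step-up false-discovery-rate envelope
(delegated to scipy, checked against hand-computed examples).

## qPCR and ChIP formulas

ΔΔCt: replicate Cts are averaged arithmetically before exponentiation
(the standard treatment; nothing else is implied by the assay), then
`2^(−ΔΔCt)` with ΔCt = mean Ct(target) − mean Ct(reference) per condition.
The ChIP relative level is implemented exactly as the efficiency-corrected
ratio given in the README; note its orientation — a stronger target IP
signal (lower Ct) *decreases* the value, the reciprocal of the
Pfaffl-style convention. The printed form is kept as the default and a
`pfaffl_orientation` flag returns the reciprocal; the algebraic identity
`chip_relative_level(E=2) = 1 / ddct(IP↔condition)` is asserted in tests.
Efficiencies default to 2.0 when a Ct table omits them and must lie in
(1, 2]. Replicate uncertainty is propagated by recomputing the statistic
over the cartesian product of single-replicate choices and reporting
mean ± SD. Standard-curve efficiency estimation and melt-curve QC are out
of scope.

## Numerical and design choices

* Internal coordinates are 0-based half-open; exported profile tables are
  1-based inclusive to match figure axes. Antisense profile values are
  negated only on export.
* Pseudocounts: 0 in profiles (faithful densities), 1 in fold changes and
  RIP enrichment (finite ratios).
* Pearson r is computed on raw normalized counts by default with an
  optional log10(x+1) mode; r is flagged undefined (NaN) for < 2 features
  or zero variance.
* A library with zero genome-unique piRNAs in the normalizer cluster
  cannot be normalized and raises rather than returning infinity.
* Ties in te_counts strand assignment (a read hitting one family equally
  well on both strands) resolve to sense; with random consensi this is
  vanishingly rare.
* RNA-IP enrichment scales each library to 10⁶ genome-unique reads of any
  category (RIP libraries are not size-selected the way total small-RNA
  libraries are) before forming IP/input ratios.
* Determinism: every stochastic step derives from an integer seed through
  `numpy.random.default_rng` seed sequences; pipeline outputs contain no
  timestamps, so identical configs give byte-identical result trees.

## Problem sizes

Simulated studies use 2×10⁵ reads per library on the default 60 kb
reference — enough that injected somatic depletions of 2–8× are recovered
within 10% and 3'UTR fold changes stay within [0.9, 1.1], while a full
control-versus-perturbed analysis completes in well under a minute on one
CPU. Unit tests use a 24 kb bundle and 10⁴-scale libraries. The pipeline
also accepts external FASTQ/FASTA libraries plus a user-supplied reference
bundle of the same layout, which is the supported route for re-analysing
real deposited libraries at their native scale.

## Known limitations

Single-chromosome reference; exact-copy TE fragments (see above);
abundance weights are not calibrated against real follicle-cell libraries;
no adapter/quality handling (inputs are assumed pre-trimmed 18–29 nt
inserts); ncRNA subtraction is exact-substring and strand-sensitive, so
fragmented or antisense ncRNA contamination would not be caught; the
miRNA stage requires exact mature-sequence identity.
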