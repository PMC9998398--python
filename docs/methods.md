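# Methods

This note documents the statistical model, the defaults, the synthetic-data
generator and the numerical choices behind `diatmeth`.

## Coordinates, contexts, and methylation levels

Intervals are 0-based half-open throughout the library; cytosine reports
are 1-based per the Bismark-style dialect; bedGraph output is 0-based. All
conversions live in the readers/writers — internal code never shifts
coordinates.

Cytosine context is assigned from the reference sequence: for each C on the
plus strand (and each G, read as a C on the minus strand) the next one or
two bases on the cytosine's own 5'→3' strand decide CG, CHG or CHH
(H = A/C/T). N is treated as H, conservatively; a cytosine within 2 bp of a
contig end whose context cannot be decided defaults to CHH. Non-ACGTN
characters are an error, not a silent skip.

CG sites are kept **per strand**; the coverage filter and all level
computations operate on individual cytosines, not symmetric CpG dyads. A
dyad-pooling helper exists (`pool_symmetric_cg`) but is off the default
path, because the multi-sample coverage filter is defined on cytosines.

The weighted methylation level of a region is total methylated reads over
total reads of its retained in-context cytosines, both strands. This is a
coverage-weighted mean of per-site levels (an identity the test suite
asserts). Zero-coverage regions propagate NaN, never 0 — an "unmethylated"
call and a "no data" call must stay distinguishable in heatmaps and
matrices.

The coverage filter retains exactly the (chrom, pos, strand) triples with
coverage ≥ min_cov (default 5) **in every study sample**; a site failing in
one line is discarded everywhere so every per-bin comparison uses an
identical site universe.

## The DMR caller

Bins are a fixed 100-bp tiling of each chromosome, final partial bin
included at its true length. Per bin and sample, the retained CG counts are
pooled and equality of proportions is tested with the pooled-variance score
statistic; the p-value is two-sided normal. Thresholds (defaults): |Δ| ≥
0.20, p ≤ 0.01, ≥ 1 retained cytosine; hypoDMRs additionally need ≥ 2
reference cytosines with ≥ 1 methylated read. All thresholds are a single
parameter object echoed into every output header.

Numerical conventions:

* pooled p̂ ∈ {0, 1} (zero variance) → z = 0, p = 1: a bin where nothing is
  methylated anywhere, or everything is, carries no differential signal;
* either sample with zero reads in a bin → the bin is untestable and
  skipped silently (the skipped count is logged and reported);
* no continuity correction — the plain score-test definition; exactness at
  tiny counts is not claimed, and the 5X-in-all-lines filter keeps bin
  totals far from that regime (≈ 300 reads/bin at the default study
  conditions);
* raw p-values are thresholded without multiple-testing correction by
  default; a Benjamini–Hochberg option (`fdr=True`) exists but is off,
  keeping the caller's operating point at the documented nominal rate;
* adjacent significant bins are **not** merged: DMRs are fixed 100-bp
  regions, so region counts stay bin-denominated and comparable across
  runs. `merge_adjacent` is provided for callers who want joined spans;
* a bin passing Δ/p with reference > treatment but fewer than 2 methylated
  reference cytosines is dropped entirely (counted in
  `n_hypo_filtered`) — it is not re-labelled hyper.

The "methylated reference CpG" criterion is operationalized as a retained
CG-context cytosine with ≥ 1 methylated read (`min_m`, configurable):
read-support is the weakest faithful reading of "methylated", and any level
threshold would add a second, undocumented knob.

Consensus DMRs intersect two calls on identical bin coordinates and
direction; shared fractions are reported relative to each input set. The
shared fraction of an empty input set is NaN (0/0), not 0 or 1.

## Interval overlap

Overlap follows bedtools-default semantics: half-open, ≥ 1 bp shared,
strand ignored. Windowed overlap extends features by ± w bp, clipping at 0
and at the chromosome end (chromosome lengths are required for right
clipping). Window hit sets are monotone in w by construction. Histone-mark
membership is boolean per DMR per peak set; combination counts use
exclusive patterns (UpSet semantics) and therefore partition the DMR set.
TE-family summaries drop families with < 3 members in the summarized set
(configurable); TEs without a family label are pooled as "unknown" and
logged. The engine is backed by interval trees; the test suite pins it to
brute-force all-pairs oracles on random instances.

## Expression classification and linkage

Categories per mutant use strict inequalities: up (LFC > 1, FDR < 0.01),
down (LFC < −1, FDR < 0.01), stable (−1 < LFC < 1, FDR < 0.01), else not
significant; missing FDR means not significant. "Stable" deliberately means
*significant but small change*, distinct from "no evidence". The FDR
default is 0.01; because reasonable analyses also use 0.05 (and published
analyses are not always internally consistent), the threshold is one config
knob echoed in every report header rather than a constant.

LFC z-scores are mean-centered and divided by the **sample** standard
deviation (n−1) over the stated feature subset; features with z > 2 are
flagged. A constant subset yields NaN z-scores, not zeros.

Linkage reports, per expression category and window, the percentage of
features overlapping ≥ 1 common hypoDMR; consensus-upregulated features
missed at window 0 but hit at a larger window are reported as
regulatory-region attributions. The TE length comparison partitions
consensus-upregulated TE features by direct DMR overlap and applies the
Wilcoxon rank-sum test.

## Wilcoxon rank-sum

The statistic is the rank-sum of the first sample with midranks for ties.
For n₁+n₂ ≤ 12 without ties the two-sided p is exact by full enumeration of
all C(n, n₁) rank assignments, p = 2·min(P(W ≤ w), P(W ≥ w)) capped at 1;
otherwise a normal approximation with tie-corrected variance and a 0.5
continuity correction. The exact path matches scipy's exact Mann–Whitney
distribution to machine precision (asserted in tests); the implementation
enumerates independently rather than delegating, so scipy remains an
independent cross-check.

## The synthetic-data generator

The generator emulates the statistical structure of a diatom methylome
study, not its sequence content. Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 500 kb | desk-scale but large enough for ~650 island bins |
| GC content | 0.48 | diatom-like nuclear GC |
| TE islands | 20, lengths 2–5 kb | mosaic methylated islands; long, young TE proxies |
| decoy TEs | 20, lengths 0.2–0.5 kb | unmethylated elements so overlap statistics are non-trivial and length contrasts exist |
| island CG methylation | 0.80 | heavily methylated TE islands |
| background CG methylation | 0.02 | near-unmethylated genome body |
| non-CG methylation | 0.005 | scarce CHG/CHH signal |
| knockout depletion | ÷ 4.5 | the 4–5-fold global methylation loss regime |
| coverage | Poisson(30) per cytosine | 30X sequencing |
| planted upregulated fraction | 0.8 of methylated TE-genes | strong but incomplete TE derepression |
| decoy upregulated fraction | 0.5 | cell-line-specific, methylation-independent upregulation |
| planted LFC | N(3, 0.5) + N(0, 0.3) per-mutant noise | clearly classified at LFC > 1 with correlated direction across mutants |
| planted stable fraction | 0.2 of the rest | a nonempty "significant but unchanged" class |

The planted wild-type/knockout island difference is 0.8·(1 − 1/4.5) ≈ 0.62,
comfortably above the 0.20 DMR threshold, so island bins are recoverable by
design; the recovery tests then measure whether the caller actually
recovers them. Island methylation is applied to CG sites only (non-CG sites
keep the small constant level everywhere): non-CG methylation is scarce in
this genome type and the differential analysis is CG-context.

Randomness is one master seed with deterministic per-purpose child streams
(`SeedSequence` spawn keys derived from purpose labels), so any subset of
samples — including an added wild-type replicate for null calibration —
reproduces bit-identically and independently of generation order. Island
placement is rejection sampling with a 1000-retry cap and a 1 kb exclusion
buffer (decoys keep a 300 bp buffer from islands so no decoy can touch an
island bin). Zero-coverage cytosines are emitted as 0/0 rows, not dropped:
downstream filters must prove they handle them.

Expression tables are simulated directly at the summary level (LFC + FDR):
fitting and inverting a negative-binomial differential model is explicitly
out of scope, and the integration logic only consumes the summary columns.
Site-level sampling is pure binomial — no overdispersion; a beta-binomial
hook is deliberately not implemented. Consequently, passing recovery tests
demonstrates correctness of the analysis logic under the planted model,
**not** robustness to biological replicate variance, mapping artifacts,
bisulfite conversion error, or repeat-family multi-mapping, none of which
are modeled.

## Pipeline and determinism

The pipeline is a pure function of its input files, thresholds and seed;
`run-all` twice on the same fixture produces byte-identical report JSON
(asserted in tests). Every output file header carries the tool version, a
SHA-256 hash of the normalized config, and the active thresholds. Stage
subcommands consume the previous stage's files (DMR BEDs carry
levels/Δ/z/p in extra columns) so partial reruns are cheap. All problem
sizes above (1 Mb genome, ~480 k cytosines/sample, 10,000-bin null
calibrations) were chosen so the full validation suite runs in about a
minute on one CPU; they scale linearly for larger studies.

## Known limitations

* The score test is asymptotic; bins with a handful of reads (possible
  under permissive coverage filters) are tested with the same normal
  approximation.
* DMR boundaries are grid-quantized; a true DMR straddling a bin edge
  appears as two bins (or one plus a sub-threshold neighbor).
* Consensus requires exact bin identity, which is correct on a shared grid
  but strict if two calls ever came from different tilings (rejected with
  an error rather than resolved).
* The simulator plants uniform methylation within an island; real islands
  have internal structure, so per-bin level variance in real data will be
  higher than simulated.
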