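# Methods

`lignotx` re-implements, as a tested pipeline over synthetic data with planted
ground truth, the comparative-transcriptomics workflow used to contrast
*Trichoderma reesei* gene expression on a lignocellulosic substrate (wheat
straw), lactose and glucose: transcript-group classification, functional
category enrichment, hierarchical clustering, promoter motif-density analysis,
and qPCR / biomass assay statistics.

## Transcript-group model

The substrate of all transcriptome stages is a genes x samples table of log2
expression with (condition, replicate) sample labels. For a contrast of
conditions *a* vs *b*, the per-gene fold change is computed from the
difference of log2 condition means (a geometric-mean ratio on the linear
scale), and significance from a two-sample test on the log2 replicate values.
The default test is the pooled-variance Student t with no multiple-testing
correction, matching an analysis that reports raw p < 0.05 on few replicates;
Welch and a label-permutation test are available alternatives. When both
groups have zero variance the p-value is 1 if the means agree and 0 otherwise
(a documented convention, not an error, so that noise-free data classify
cleanly).

A gene is *up* on condition X when fold(X vs glucose) >= `fold_change_min`
(default 2) at p < `p_max` (default 0.05). The partition is:

- **A** — up on wheat straw only; **B** — up on lactose only;
- among genes up on both: **C** if the direct wheat-straw-vs-lactose contrast
  is itself >= `wl_fold_min` (default 2) at p < 0.05 in favour of wheat straw,
  **D** symmetric for lactose, **E** otherwise. "Comparably strong
  upregulation" has no published quantitative definition; re-using the primary
  2-fold/p<0.05 criterion on the direct contrast is this package's design
  choice and is exposed as a threshold.
- **CONSTITUTIVE** — all condition means above `expression_floor` (default
  1.0 log2 units; "expressed" has no published cutoff, so the floor is
  explicit and tunable) and every pairwise linear ratio of condition means
  inside the closed interval [1/1.4, 1.4]. The band is applied to condition
  means, not per-replicate values, and is inclusive at the boundary, with a
  1e-9 log2 tolerance so exact-boundary constructions survive floating-point
  rounding. Constitutive assignment precedes the A-E logic.
- **NONE** — everything else.

Invariants: the seven labels partition the gene universe; |C|+|D|+|E| equals
the count of genes up on both; tightening either threshold never grows the
induced set; outputs are invariant to row/column permutation.

## Category enrichment

Each (category, group) pair is tested with an independent Pearson chi-square
(1 df) on the 2x2 table (in group / not) x (in category / not) over the
universe of all annotated genes, uncorrected by default; Benjamini-Hochberg
adjustment and the Yates correction are opt-in. Genes with several category
codes count once per code. Tables with any expected cell below 1 are flagged
and carry a Fisher exact p as fallback. Results include the expected count,
the chi-square statistic and the percent of the category captured by the
group.

## Clustering and heat maps

Genes are clustered on their 3-vector of condition means (matching what the
heat maps display) with agglomerative clustering on Euclidean distances.
The linkage criterion of the original desktop tool is not published; average
linkage is the default here and complete/single are selectable. Rows are
sorted lexicographically by gene id before linkage so ties resolve
deterministically. Trees serialize to Newick with branch lengths derived
from merge-height differences (leaves sit at depth equal to the top merge
height). Heat maps are anchored at 0 (dark blue) to 16 (dark red) log2
units; display values are clipped to that range while the accompanying
row-order TSV retains the unclipped data, so figure content is testable
without pixel comparison.

## Promoter motif density

Promoter windows are the `L` bases (default 1000, i.e. -1000..-1) immediately
5' of the translation start, excluding the ATG; minus-strand genes take the
reverse complement of the bases following the start coordinate, and windows
truncated by contig edges are shortened and flagged. Coordinates are
1-based inclusive externally and 0-based half-open internally.

Scanning uses degenerate IUPAC patterns (default the XYR1 consensus GGCW4 =
`GGCWWWW`). Matching is greedy left-to-right with overlapping matches
prevented; with both strands scanned (the default for a double-strand binding
motif), a match on either strand occupies its coordinates for both strands,
and '+' wins position ties. An `N` in the sequence matches only an `N` in the
pattern. A naive sliding-window re-statement of these rules
(`lignotx.reference.naive_scan`) serves as the oracle in tests.

The genome-wide density — e.g. 20,692 consensus sites over a 33 Mbp genome,
one site per ~1,595 bp, reported as ~1,500 bp at the census's 500-bp
precision — defines the null for per-promoter counts: Poisson(lambda) with
lambda = L / expected spacing (0.627 sites per kb window). Which reference
distribution the original Anderson-Darling comparison used is not published;
this package operationalizes it as a Monte-Carlo two-sample test: `n_sim`
replicate count-sets build a pooled null reference, and the observed set plus
`n_sim` fresh null sets are each compared to that reference with the
two-sample Anderson-Darling statistic (Scholz-Stephens, midrank tie
convention, re-implemented in a histogram-batched form and cross-checked
against scipy's `anderson_ksamp`). Exchangeability of the observed and fresh
sets makes the Monte-Carlo p-value uniform under the null; ties only make it
conservative. The genome-wide census count is an input, never recomputed, so
the null matches whatever strand convention produced it.

## qPCR statistics

Amplification efficiency comes from an OLS fit of Ct on log10 input over a
dilution series: E = 10^(-1/slope), with non-negative slopes rejected as
failed assays. Relative expression uses the efficiency-corrected ratio

    R = E_t^(Ct_t,cal - Ct_t,sam) / E_r^(Ct_r,cal - Ct_r,sam)

on replicate-mean Cts, normalized on *tef1* and expressed against the
glucose 8-h calibrator. The standard error comes from the spread of ratios
over replicate combinations (exhaustive for small designs, seeded
subsampling otherwise). With E = 2 on both assays the ratio reduces exactly
to 2^ddCt, and swapping sample and calibrator inverts it.

Significance of R != 1 uses a fixed-reallocation randomization test:
per-replicate (target, normalizer) Ct pairs are pooled across the two groups
and reallocated at random `n_iter` times (default 2000), the log ratio is
recomputed, and the two-sided p is the fraction of reallocations at least as
extreme, with the +1/(n_iter+1) correction. Note the granularity limit of
permutation tests: with 3+3 replicates only C(6,3) = 20 distinct
reallocations exist and the two-sided p cannot fall below ~0.1, so power
statements use the full study design of two independent experiments x three
replicates (6+6 pooled, 924 splits). A Welch unequal-variance t-test (with
Welch-Satterthwaite df, degenerate-variance conventions as in the DE stage)
is the second route, applied to per-replicate dCt values.

Biomass on insoluble substrates is estimated from intracellular protein as
dry weight = max(0, protein - substrate control) / 0.35 g/g, the conversion
constant being configurable.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: three carbon sources,
two (configurable up to four; the recovery analyses use three, since a
t-test on n=2 has little power at these settings) replicates, log2 baseline
6.0, planted effect 2.0 log2 units (4-fold, comfortably above the 2-fold
cutoff), i.i.d. Gaussian replicate noise of sd 0.25 log2 units (the original
error model is unpublished; i.i.d. Gaussian on log intensities is the
standard assumption for such data and suffices for type-I/power testing),
and group proportions taken from the study's own 9,129-gene composition
(1619 A / 288 B / 344 C / 65 D / 804 E / 1100 constitutive / remainder not
induced). Constitutive genes get per-condition offsets uniform on (-j/2,
+j/2) with j = 0.2 log2 units, i.e. pairwise true differences within j,
well inside the +/-1.4 band; "not expressed" genes sit at half the
expression floor. Group labels are apportioned deterministically (largest
remainder), so different seeds share ground-truth structure and differ only
in noise.

Annotation labels are drawn independently of group at a base rate (default
0.02 per category), except for planted (group, category, odds-multiplier)
enrichments applied on the odds scale. Promoter backgrounds are drawn from a
configurable base composition (uniform by default) with every
motif-matching window on either strand rejected and resampled, after which
exactly the planted number of non-overlapping sites is inserted at recorded
positions and the construct is verified with the scanner itself, so scans
return exactly the planted counts. When no counts are specified they are
drawn Poisson at the genome density (one per 1,500 bp). Ct tables invert the
ratio model with Gaussian Ct noise (sd 0.15 cycles); with zero noise the
Pfaffl ratio recovers the planted ratios to machine precision.

The generator does not emulate probe-level microarray effects,
normalization artifacts, correlated noise between conditions, annotation
errors, or promoter sequence composition beyond base frequencies. Passing
tests therefore demonstrate correctness of the statistical machinery under
its stated assumptions, not robustness to the full messiness of array data.

## Problem sizes and numerical choices

The analysis scripts run at 2,000 genes x 9 samples; recovery checks use
1,000 genes; calibration checks use 500 null chi-square tests, 200
Anderson-Darling trials at 16 promoters x 199 simulations, and 200
randomization-power simulations at 1,999 iterations — sizes chosen to give
stable rates (binomial 99% bounds) while keeping the whole suite fast on a
laptop. Monte-Carlo comparisons use a 1e-12 slack on ">= observed" to avoid
losing exact ties to floating-point noise. Seeded `numpy` Generator streams
(one child stream per generator stage) make every stochastic output
reproducible byte-for-byte.

## Known limitations

- The classifier's C/D/E split criterion and the constitutive floor are this
  package's explicit parametrizations of verbally-defined published rules;
  alternative readings are reachable through `Thresholds` but not enumerated.
- The Anderson-Darling null is a window-count Poisson model; clustering of
  sites within promoters (e.g. tandem arrangements) violates it by design
  and is exactly what the test is meant to detect.
- The randomization test mirrors the fixed-reallocation scheme of the REST
  family of tools, whose exact internals are proprietary; results agree in
  the cases checkable by hand but are not bit-compatible with that software.
- Heat-map rendering is checked through its row-order TSV, not pixels.
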