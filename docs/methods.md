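# Methods

## The model

The pipeline analyzes log2-scale expression measured in replicate across
experimental conditions (genetic background × treatment). Replicates are
summarized per condition into a mean matrix **D** (genes × conditions) and
an uncertainty matrix **Σ** of replicate standard deviations (sample SD,
n−1 denominator). Σ is floored elementwise at 5% of |D| (configurable
`fraction`; entries where D = 0 are floored at ε = 10⁻⁶ expression units) so
that no element claims unrealistic precision and the weighted objective is
everywhere defined.

The factorization model is elementwise normal, D ~ N(AP, Σ), with
nonnegative amplitudes A (genes × k) and patterns P (k × conditions). The
point estimate minimizes the weighted residual

    chi² = Σ_ij ((D_ij − (AP)_ij) / Σ_ij)²

by alternating exact weighted nonnegative least squares: each sweep solves
every gene's amplitude row (fixed P) and every condition's pattern column
(fixed A) to optimality. The per-row solves enumerate all 2^k − 1 supports
(k ≤ 6 in practice), solve the normal equations on each support with a tiny
ridge (10⁻¹⁰ × trace) for conditioning, and keep the best feasible
candidate — this is exact NNLS, vectorized across genes. Because both block
updates are exact minimizers the objective is monotone non-increasing, which
the tests assert, and iterates reach the nonnegativity boundary (exact
zeros in A), which matters for identifiability (below). Convergence: stop
when the relative chi² change per sweep falls below 10⁻⁸ or the sweep
budget (`n_iter`, default 50,000) is exhausted.

### Identifiability and canonicalization

A nonnegative factorization of this design is not unique out of the box.
Every gene carries the constant baseline program, so any solution can move
an arbitrary multiple of the flat pattern into the structured patterns
(with A compensating), and when no gene is dominated by a single program the
admissible pattern cones form a continuum even for noiseless data. Two
design choices resolve this:

- **Anchor genes in the generator.** A fraction (`anchor_fraction`, default
  0.3) of each planted program's genes are "strongly inducible": their
  constitutive (baseline) amplitude is scaled by `anchor_scale` = 0.15, so
  their measurements are dominated by the program itself. Biologically these
  are low-basal, strongly induced genes — a standard feature of real
  expression programs — and mathematically they act as separability anchors
  that pin the pattern cone.
- **Structured initialization.** `factorize` initializes from an
  NNDSVD-style split of the leading singular vectors (the first component is
  nonnegative by Perron–Frobenius and seeds the baseline), perturbed by a
  seeded ±10% multiplicative jitter. Different seeds probe the basin without
  abandoning it.

After fitting, the offset ambiguity that remains (structured patterns
carrying a share of the flat baseline) is removed by a canonicalization that
preserves A·P exactly: the flattest pattern (smallest coefficient of
variation) is taken as the baseline and the maximal multiple of it that
keeps each other row nonnegative is subtracted, with the baseline's
amplitude column absorbing the difference. Pattern rows are then normalized
to sum to one, the scale moving into A. Any pattern row that ends up
identically zero is replaced by a uniform row with a zero amplitude column
(A·P unchanged); such empty patterns surface as unstable in the robustness
scan rather than crashing it.

### Uncertainty and z-scores

Posterior-like uncertainty comes from a parametric bootstrap: resample
D* ~ N(AP, Σ) and refit warm-started from the point estimate (`n_draws`,
default 50; `boot_sweeps` = 300 sweeps each). Warm starts keep pattern
identity across draws, so no relabeling is needed. The amplitude z-score is
mean over draws divided by the SD over draws (ddof = 1), with the SD floored
at 10⁻¹² — degenerate constant draws produce large finite z rather than
infinities, and all-zero draws give z = 0.

### Pattern matching and the flat-pattern convention

Patterns are compared by Pearson correlation of their rows, with a
Hungarian assignment maximizing total correlation. Pearson is undefined
against an exactly constant row and is pure noise against a near-flat one,
so rows whose coefficient of variation is ≤ 0.3 are treated as
constant-type: two constant-type rows agree at r = 1 (after sum-to-one
normalization they carry the same information), and a constant/structured
pair scores 0. The 0.3 operating point sits between the flat baseline
pattern as actually fitted (CV ≲ 0.2 at the study noise) and the weakest
structured planted pattern (CV ≥ 0.5); it is exposed as `flat_cv`. Without
the canonicalization above this classification would be meaningless —
un-sharpened structured patterns compress toward flatness.

### Choosing the pattern count

For each candidate k (default 2..6) the model is fit once and re-fit on
`n_runs` (default 3) parametric-bootstrap resamples; robustness(k) is the
worst matched-pattern correlation between the point estimate and any
resample fit. Patterns tracking real structure persist when the noise is
redrawn; patterns chasing one noise realization do not. The largest k with
robustness ≥ 0.9 is selected (no qualifying k → smallest candidate plus a
warning flag). A cross-run variant (comparing independently initialized
runs) was considered and rejected: with structured initialization even
spurious patterns reproduce across runs, and with random initialization
even the true k is unstable, so init-based robustness cannot discriminate.
The threshold of 0.9 reflects that bootstrap similarity of genuine patterns
sits near 1.0 while marginal ones hover near 0.8; scan refits use a
300-sweep budget (`scan_sweeps`), which the selection statistics tolerate.

## Preprocessing

**Probe collapse.** One probe per gene, maximizing
MAD(condition means) / median over conditions of the within-condition
replicate MAD. Raw MADs (no 1.4826 constant — it cancels). Zero
denominator with positive numerator scores +∞; 0/0 scores 0; exact ties
break to the lexicographically smallest probe id. For genes with no
condition-dependent signal the two probes are statistically
indistinguishable, so probe-recovery statements are made over genes that
carry planted signal.

**Gene filter.** Keep genes that belong to at least one TF target set and
whose largest pairwise difference of condition means (= max log2 fold
change) is ≥ 0.5. Both removal counts are reported. Order of operations is
stats → floor → filter; results for retained genes are identical in any
order.

## Enrichment statistics

- **Gene-set statistic**: mean member z-score in a pattern column, with a
  permutation null of `n_perm` = 10,000 random same-size sets and the
  add-one correction (1 + #{perm ≥ obs})/(1 + n_perm); comparisons use a
  10⁻¹⁰ relative tolerance so exact ties count as ≥. One-sided (greater) by
  default — the question is over-representation of high amplitudes.
- **TF association**: Pearson correlation of each gene's z-score row with
  the query gene's row across the k patterns (query excluded), then, for
  each TF annotating the query as a target, a one-sided Wilcoxon rank-sum of
  the remaining targets' correlations against all other genes, BH-adjusted
  across TFs. With k = 3 the correlations rest on three points; this is the
  procedure as specified and is flagged with a warning at k = 2 where it
  degenerates entirely.
- **Wilcoxon rank-sum**: exact p by enumeration of all C(n+m, n)
  assignments when n + m ≤ 12 and the pooled data carry no ties; otherwise
  the normal approximation with midranks, tie-corrected variance and
  continuity correction (scipy's asymptotic Mann-Whitney U).
- **Pearson test**: t-distributed p with df = n − 2, one- or two-sided.
- **FDR**: Benjamini–Hochberg step-up wherever multiple TFs are tested.

## The feedback signature

Treatment-induced changes are treated-minus-control means per background ×
drug contrast, on the log2 scale. The implicated TF's target genes are
clustered on their change profiles (agglomerative, average linkage) and cut
at two clusters; the cluster containing the reference gene is "up". The
default distance is **Euclidean**: the up/down division is carried by the
sign and magnitude of the changes, which correlation distance removes — in
the planted truth (and in the published membership structure) up- and
down-profiles are positively correlated in *shape* while opposite in
*level*, so correlation-distance clustering is near chance. Correlation
distance remains available via `metric` for shape-based questions, where
the clustering is invariant to adding a constant to all contrasts.

Signature evaluation ranks genes by the Pearson correlation of their change
profile with the reference gene's (the reference itself is excluded from
both the up set and the background, switchable) and tests the up set with a
one-sided Wilcoxon rank-sum. Pattern–survival association takes, per
background × drug, the pattern's treated-minus-control delta and correlates
it with relative survival. Marker stratification thresholds a marker gene
at the cohort-wide mean by default (median and explicit numeric thresholds
are supported); samples strictly below are "low".

## Alteration survey

A sample is altered in a gene on a mutation or a GISTIC score of ±2;
shallow gains/losses (±1) never count. Genes collapse onto network nodes by
boolean OR over family members (missing members are skipped with a
warning; an empty family is an error and a node with no present member is
dropped). Frequencies are percentages per node and tumor type; the
cross-type headline is the unweighted mean of per-type percentages, with
the pooled (sample-weighted) percentage reported alongside since the two
differ for unequal cohorts. Missing sample–gene entries are imputed as
unaltered and counted in the log.

## The synthetic cohort

`SimConfig` defaults define the study conditions: 500 genes, 3 TF sets of
40 targets, 4 backgrounds × 4 treatments × 3 replicates, 2 probes per gene,
i.i.d. Gaussian noise with SD 0.3 on the log2 scale (typical array
replicate noise after normalization). Three programs are planted:

1. **constant** — exactly uniform across conditions; every gene carries a
   baseline amplitude of ~112 (×1/16 per condition ≈ 7 log2 units).
2. **oncogenic** — 3× elevated in the resistant HRAS background and
   repressed by treatment in *every* background, most deeply where the
   driving pathway is most active (repression depth 0.3 → 0.65 from the
   most sensitive to the resistant line, scaled by a per-drug potency of
   0.9–1.1). Its repression magnitude therefore tracks relative survival.
   Loaded by the Elk1 target set and by the "down" members of the AP2A set
   (amplitude scale 20).
3. **feedback** — lowest in the resistant background, induced by treatment
   in proportion to each background's drug sensitivity (gain 2.0 × sens ×
   potency). Loaded by the "up" AP2A members, including the reference gene
   (amplitude scale 26, ≈0.5–2.5 log2-unit condition deltas).

The AP2A set splits 60/40 into up/down members; the reference gene is also
annotated to a decoy TF (SP1, whose true targets are constant-program
genes) so that the TF-association contest is non-trivial. Per program, 30%
of member genes are low-baseline anchors (see Identifiability). Each gene's
informative probe is chosen uniformly at random; the other probes sit at a
flat, condition-independent level in U(4, 8). Survival is planted as
1 − 9 × (feedback treatment delta) + N(0, 0.015), clipped to (0.01, 1], so
the feedback–survival anti-correlation is ≥ 0.9 in magnitude by
construction. Alteration simulation draws mutations and GISTIC ±2 events as
independent Bernoullis at stated marginal rates, with shallow scores filling
the remainder.

What the generator does *not* emulate: batch effects and normalization
artifacts (inputs are assumed normalized and batch-corrected), correlated
noise between replicates or genes, probe cross-hybridization, outlier
samples, and any dependence of survival on programs other than feedback.
Passing tests therefore demonstrate correctness of the pipeline's
statistics and its recovery behavior under the planted model, not
robustness to those real-data pathologies.

## Problem sizes and numerical choices

Tests and the acceptance script run the full design (500 genes × 48
samples; ~110 genes after filtering) with 10 master-seed replicates for
recovery and dimension-selection studies, 10,000 permutations for gene-set
statistics, and 1,000 replicates for null-calibration checks. The exact
Wilcoxon path is exercised exhaustively for all sample splits up to a
pooled size of 8 against an independent implementation. Degenerate inputs
are handled explicitly rather than by exception where a sensible value
exists: zero-variance rows yield missing correlations, constant draws yield
large finite z-scores, empty patterns become uniform rows with zero
amplitude, and single-replicate conditions are flagged and floored.

## Known limitations

- The optimizer enumerates amplitude supports per gene, exact but
  exponential in k; it is intended for the k ≤ 6 regime of this analysis.
- The bootstrap quantifies uncertainty around one point estimate; it does
  not explore distinct modes the way a full posterior sampler would.
- With k = 3, gene–gene correlations over patterns take few values, and
  set-level tests on them inherit that coarseness (a warning is emitted at
  k = 2).
- The flat-pattern convention (CV ≤ 0.3) is tuned to designs with one
  near-constant program; data with several genuinely weak programs would
  need a smaller `flat_cv`.
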