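# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Study design being modelled

Five groups of female *Polistes metricus* paper wasps — dominant foundress
(DF), subordinate foundress (SF), queen (Q), dominant worker (DW),
subordinate worker (SW) — with eight wasps per group. DF/SF pairs share a
founding-phase nest; Q/DW/SW trios share a worker-phase nest. Each wasp's
brain (or ovary) RNA is hybridised on two two-color microarrays with
opposite Cy3/Cy5 labels, and the 40 arrays form a single loop. The platform
carries duplicate spots per transcript. Alongside the arrays, absolute
cuticular-hydrocarbon (CHC) concentrations are measured per wasp and
compound, and cross-species comparisons ask whether the wasp's
differentially expressed genes overlap the significant gene lists of other
studies more (or less) than chance, over a shared ortholog background.

## Loop design

`make_loop_design` places sample *t* on array *t* (Cy3) and sample *t + 1*,
cyclically, on array *t* (Cy5): *n* samples need *n* arrays, every sample
appears exactly twice with opposite dyes, and the design graph is one
cycle. The generator's sample sheet orders wasps in **interleaved group
order** (DF1, SF1, Q1, DW1, SW1, DF2, ...), so every array pairs two
different groups. This matters: a loop that chains same-group neighbours
would carry almost no direct within-array information about group
contrasts; group estimates would then ride long chains of array effects,
and the realised false-discovery proportion of a single experiment becomes
erratic. Interleaving is the standard choice when a loop design must
estimate all pairwise group contrasts, and the simulation study in the test
suite confirms calibration under it. The ordering is a generator input:
`make_loop_design` accepts any sample order.

## Generative model for the arrays

On the log2 scale, for transcript *g*, spot replicate *j*, array *i* with
dye *k* carrying sample *s*:

    log2 signal = mu + gene_g + tau_{group(s)} + a_i + d_k + s_{gj} + eps

with gene_g ~ N(0, sd_gene²), a_i ~ N(0, sd_array²), d_k ~ N(0, sd_dye²),
s_gj ~ N(0, sd_spot²), eps ~ N(0, sd_resid²). A fraction `frac_de` of
transcripts carries a non-zero tau: by default one randomly chosen group is
shifted by ±`effect_size` (pattern `single_group`); pattern `phase` shifts
the worker-phase groups against the founding-phase groups, which is the
dominant axis the study observed. Raw foreground intensity is
`2^log2 + background`, with background drawn lognormally around
`background_level` (175 intensity units, the study's median background);
the additive background is what makes low-expressed transcripts drop below
the filter, as on real scanners. An intensity-dependent dye bias —
a quadratic polynomial in centered average log intensity A, split ± between
the channels — is planted with modest default coefficients (0.1, −0.05,
0.02) because two-color arrays always show such bias; it is what the loess
normalization exists to remove. A small fraction of spots (1%) is flagged
bad.

Defaults (8 wasps/group, 40 arrays, duplicate spots, 10% differential
expression at 1.0 log2, sd_resid 0.4, 1000 transcripts) are the package's
standing desk-scale study conditions: large enough for stable
FDR/sensitivity estimates, small enough that a 20-replicate simulation runs
in a few minutes on one CPU.

What the generator does **not** emulate: probe sequence and hybridisation
physics, print-tip or spatial artifacts, per-wasp biological random effects
beyond the group mean (the fitted model has no sample random term either,
so generator and model agree), and correlated differential expression
between transcripts. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real slides.

## Preprocessing

Fixed order: background filter → log2 → per-array loess (lowess)
normalization → missingness filter.

* **Background filter.** A channel value survives iff fg ≥ threshold
  (default 175; boundary kept). The two channels are filtered
  independently — a spot losing one channel keeps the other, because the
  downstream model tolerates unbalanced channels. `from_data=True`
  recomputes the threshold as the median of all background intensities.
  Flagged spots are dropped here.
* **Loess normalization.** Per array, M = log2(Cy5) − log2(Cy3) is
  regressed on A = ½(log2(Cy5) + log2(Cy3)) over spots with both channels
  (statsmodels lowess, span 0.4 by default); half the fitted trend is
  subtracted from Cy5 and added to Cy3, so within-array A values are
  preserved exactly. Because a local fit is not mean-unbiased, the leftover
  constant (the mean residual M) is folded into the correction — after
  normalization the per-array mean M over two-channel spots is zero to
  machine precision. Spots with a single surviving channel are corrected
  with the trend evaluated at their own log intensity, the best available
  proxy for A. Idempotence holds exactly at the fixed points (M ≡ 0,
  M ≡ constant); on noisy data a second pass refits local noise at the
  sd/√window scale, which is a property of loess itself, not of this
  implementation.
* **Missingness filter.** A transcript is present on an array if at least
  one unflagged value survives there; transcripts missing from strictly
  more than 25% of arrays are removed (a transcript missing exactly 25% is
  kept). Accounting is at transcript level over arrays.

## Per-transcript mixed-model ANOVA

For each retained transcript:

    value = group + spot + array + dye + error

group (5 levels) and spot (duplicate index) fixed; array and dye random
intercepts with own variance components, estimated by REML. Dye has two
levels, which makes its component statistically fragile; it is random by
default to mirror the published model, with `dye_as_random=False`
available.

The solver (`waspdom._mixed`) profiles out the residual variance and
optimises the log variance ratios by L-BFGS-B with the analytic REML score,
evaluating the likelihood through the Woodbury identity (one Cholesky of
the (levels × levels) capacitance matrix per evaluation instead of an
n × n factorization). A ratio driven to the lower search bound (e^−12) is
reported as a zero component — the model degenerates gracefully to the fit
without that term, and the fit then collapses to OLS. The implementation
was cross-checked against statsmodels MixedLM (variance components and
fixed effects agree to optimizer tolerance); MixedLM itself is an order of
magnitude too slow for the simulation studies.

**Noise-free responses** (exact linear structure) are detected by
projecting onto an orthonormal basis of the combined fixed + random column
space; the fit then absorbs the random factors as fixed effects, which
recovers estimable group contrasts exactly (the loop design is connected,
so all group contrasts are estimable) and flags the fit degenerate.

**Tests and df.** The group term is tested with a Wald F; the ten pairwise
contrasts with Wald t. Both use containment-style denominator degrees of
freedom, n − rank([X Z]). Under the generative model — array and dye the
only random terms, both crossed with group, no per-sample effect — the
residual stratum is the correct error stratum for group contrasts, and the
null simulations in the test suite confirm calibration (uniform omnibus p,
type-I error at nominal). A Satterthwaite approximation would add
derivative bookkeeping for no measurable gain under this design.

**Multiple testing.** Benjamini–Hochberg step-up q-values,
q(i) = min_{j≥i} m·p(j)/j capped at 1, implemented directly and verified
against both the literal definition and statsmodels. Families: the omnibus
tests over transcripts form one family; each pairwise contrast forms its
own family across transcripts. Significance is called at q < alpha with a
tissue-specific default (0.05 brain, 0.01 ovary — the stricter ovary cutoff
reflects its much larger signal). Unfit or degenerate transcripts are
excluded from the families and flagged.

## Derived gene sets and group summaries

"Dominance-associated" = union of the significant DF-vs-SF and DW-vs-SW
contrast sets (the two within-nest dominant/subordinate comparisons);
"caste-associated" = union of Q-vs-DW and Q-vs-SW. Unions require matching
tissue and cutoff provenance and merge contrast provenance. The group
distance matrix counts significant transcripts per pairwise contrast;
groups are clustered on it with average linkage (the published analysis
names hierarchical clustering without a linkage for this tree; average is
the neutral choice — the compound clustering below uses single linkage as
stated). PCA is computed on centered, unscaled log expression (samples as
observations); each axis's association with a metadata factor is the R² of
the axis scores on the factor indicators, and a factor's share of overall
variation is Σ variance-fraction × R² over axes.

## Cross-species overlap

Orthologs are one-way best BLAST hits: rows above the e-value cutoff
(1e−5 insects, 1e−3 mouse) are discarded; per query the minimum e-value
wins, ties broken by higher bit score, then lexicographically smaller
subject id. The shared universe is the set of focal transcripts on the
focal platform whose best-hit subject is on the other platform. The 2×2
table counts **focal transcripts** (several transcripts may map to one
other-species gene; the published cells are wasp-transcript counts, and an
optional gene-level collapse is deliberately not the default). Identifiers
outside the universe are dropped with a logged count.

`fisher_two_tailed` implements the minimum-likelihood two-sided rule: with
margins fixed, p is the sum of hypergeometric point probabilities not
exceeding the observed table's. Point masses are compared and summed in
exact integer arithmetic (binomial-coefficient numerators over the common
denominator, final division as a rational), so tie decisions are exact and
the result is correct to double-precision rounding at any table size used
here — no floating-point tie tolerance is needed. An exhaustive-enumeration
oracle over every 2×2 table with N ≤ 60 and a scipy cross-check back this
up in the test suite.

Of the ten published comparison rows, five are reproduced exactly at
printed precision from their printed cells under this rule (0.939, 0.343,
0.019, 0.022, 0.0184). Five are not reproducible from their printed counts
under *any* standard two-sided convention we tried (minimum-likelihood,
tail-doubling, mid-p variants, chi-square with and without continuity
correction): printed 0.322 computes to 0.304, printed 0.99 computes to 1.0
(the observed table is the modal table), printed 0.033 to 0.032, printed
0.692 to 0.752, and the printed "<0.001" row to 0.073. The package reports
the computed values; the discrepancies appear to be internal
inconsistencies between the published cells and p-values.

## CHC analysis

Concentrations are log10-transformed. Below-detection zeros are replaced by
half the compound's smallest positive value by default (`drop` and fixed
offsets available); the policy is recorded on the output. Per compound, a
mixed ANOVA with group fixed and colony random (same REML machinery) gives
the omnibus p; pairwise group comparisons are Bonferroni-adjusted within
the compound (family = the 10 pairs by default, configurable). LDA of whole
profiles uses scikit-learn (eigen solver); a singular within-group
covariance raises with advice to enable shrinkage (Ledoit–Wolf or a fixed
amount). Significantly different compounds are clustered by single linkage
on Euclidean distances between group-mean log10 vectors; `center=True`
subtracts each compound's row mean first, clustering abundance *patterns*
— the same transformation the fold-difference heatmap displays (group mean
log10 minus the compound's grand mean, rows centered at the 1:1 level).

The CHC generator plants, among the significant compounds, a correlated
block of "phase" compounds (low in foundresses, high in queens/workers, the
pattern the study's five long-chain compounds showed) and independent
random group-effect vectors for the rest, over a colony random effect
(foundress pairs and worker trios). Default effect and noise scales
(0.35 log10 effect, colony sd 0.15, residual sd 0.25) give a realistic
mixed-power regime; the clade-recovery demonstrations use an explicit
high-signal fixture (effect 0.6, reduced noise) because recovering a
planted block as an exact clade is a property of a clearly separated block,
not of every noise regime.

## Numerical and degenerate-input choices

* log base 2 for expression (cancels in contrasts and is the field's unit
  for fold change), log base 10 for CHC (the published display unit).
* REML search box for log variance ratios: [−12, 12]; boundary hits are
  zero components. Restart from the zero-variance corner on failure; a fit
  that still fails marks the transcript unfit (excluded, logged).
* Exact-linear detection threshold: residual sum of squares ≤ 1e−16 × ‖y‖².
* Constant compounds and transcripts with < 2 groups or < 2 values per
  group are flagged, not fitted.
* Fisher p is clipped to [0, 1]; a table with a zero margin has a single
  attainable configuration and p = 1.
* All randomness derives from one integer seed through named per-stage
  substreams (`numpy` SeedSequence spawning), so every artifact is
  bit-reproducible for a fixed configuration.

## Known limitations

* The mixed model carries no per-wasp biological random effect (matching
  the generative model and the published model description); on real data
  with biological replicate variance the containment df would be too
  liberal, and a per-sample term plus Satterthwaite df would be the first
  extension.
* The loess normalization corrects single-channel spots at their own
  intensity rather than a true A value.
* Ortholog mapping is one-way best hit by construction; no
  reciprocal-best-hit or tree-based orthology.
* The published PCA variance shares (23% season/social environment in
  brain, 41% ovary activation in ovary) and DE counts (499 brain,
  2302 ovary) depend on the deposited raw data and are out of desk-scale
  reach; the pipeline exposes the same quantities on synthetic data
  instead.
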