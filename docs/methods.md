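# Methods

## Clinical cohort model

A cohort is an ordered collection of patient records: Oncotype DX DCIS
score (integer 0–100), age, nuclear grade (1/2/3 or missing), follow-up,
treatment and recurrence status. Risk group is a deterministic function of
the score — low < 39, intermediate 39–54, high ≥ 55 — and is always
derived, never stored.

Two design choices around the example table:

- **Censored ages are used at their boundary code.** The table carries two
  boundary-coded ages ("<=30" → 30, ">=80" → 80). Coding them at the
  boundary is the only convention under which the cohort's printed mean
  and median ages reproduce, so summaries use the boundary value while the
  censor flag is preserved on the record for any downstream use.
- **Missing grade is excluded listwise** from the grade × risk-group
  contingency analysis (40 of 41 example records are graded).

The contingency test is a Pearson chi-square test of independence without
continuity correction; collapsing intermediate+high into one column is the
pre-specified secondary comparison. With the 3-group table the smallest
expected cell is 0.75, and the asymptotic p-value (0.0791) sits about
0.008 above a 10,000-shuffle permutation estimate — a known small-sample
limitation of the chi-square approximation. For the collapsed table
(smallest expected cell 2.25) the asymptotic and permutation p-values
agree well within Monte-Carlo error, and the suite asserts that agreement
there.

## Statistical primitives

`dcismir.stats` implements each primitive from its definition; only the
t, chi-square and normal tail functions come from scipy. All tests are
two-sided.

- Pearson r with the exact-null t transform (df = n − 2); Spearman rho as
  Pearson of mid-ranks (average ranks for ties). Constant inputs yield a
  flagged *not-testable* result instead of an exception so genome-wide
  screens never abort.
- Welch t with Satterthwaite degrees of freedom.
- Mann–Whitney U: exact two-sided p by enumerating all C(n_a+n_b, n_a)
  labelings when min(n) ≤ 8 and there are no ties (both tails counted, so
  the (1,2,3) vs (4,5,6) configuration gives p = 2/20 = 0.1); otherwise
  the normal approximation with continuity and tie correction. The
  threshold keeps enumeration instantaneous (≤ 12,870 labelings).
- Benjamini–Hochberg step-up, adjusted_(i) = min_{j≥i} (m/j) p_(j) capped
  at 1. The upstream analyses report "adjusted p-values" without naming a
  procedure; BH is the standard default of count-based differential
  expression tools and is used throughout (the choice is configurable at
  the call sites that take pre-computed p-values).

## Normalization and the correlation screens

Counts are normalized per sample to total counts (fractions summing to
one). Log expression is log2(fraction · scale + pseudocount), i.e.
log2(CPM + 1) with the defaults. Defining the pseudocount on the scaled
fraction rather than the raw count makes the transform — and hence every
screen estimate — *exactly* invariant to per-sample sequencing depth,
which the suite asserts by integer-rescaling library sizes.

The score screen computes per-miRNA Pearson r of log2 expression against
the numeric DX score; the age screen uses Spearman rho against age. Raw
p-values are BH-adjusted across all testable miRNAs; direction "down"
means expression falls as the covariate rises. Mean abundance (percent of
total reads) is reported per miRNA.

Batch adjustment (off by default) residualizes **both** the expression
rows and the covariate on batch indicator columns before correlating and
reduces the t degrees of freedom by the batch df — a partial correlation.
Residualizing expression alone would bias estimates toward zero whenever
batch and covariate are correlated, so the symmetric form is used.

Age-group binning follows the three-bin partition ≤ 55 / 56–70 / > 70
(the half-open variant that double-counts 55 is rejected). Panel selection
takes the union of the top-k score hits (default k = 10) and top-k age
hits (default k = 9) at BH-adjusted p < 0.05, recording provenance
(score / age / both); these defaults mirror the 10 + 9 signed hits the
screens are sized to detect, and a double hit takes its direction label
from the score screen.

## ΔΔCt quantification

Triplicates are averaged per (sample, miRNA); the QC flag is
"discordant" when replicate SD exceeds 0.5 cycles (a conventional
plate-QC threshold), "partial" with < 3 detected replicates, and
"undetected" rows (no detected replicate) are excluded downstream with a
logged warning — undetected is treated as missing, never imputed to a
maximum cycle. ΔCt subtracts the endogenous-control (RNU6B) mean Ct per
sample; a sample without a usable control is an error naming the sample.
ΔΔCt subtracts the *low-risk group mean* ΔCt per miRNA (the comparator for
all reported fold changes; a single-calibrator-sample variant would simply
shift all values by a constant). Fold change is 2^−ΔΔCt: amplification
efficiency is fixed at 2, so a 2-fold expression change is exactly −1
ΔΔCt. By construction the reference group's mean ΔΔCt is 0 and its
geometric-mean fold change is 1.

Group comparisons report both Welch t and Mann–Whitney p per miRNA; the
primary p (BH-adjusted across the panel) defaults to Mann–Whitney, the
more conservative choice for small, possibly non-normal ΔΔCt samples, and
is configurable.

NGS–qPCR concordance correlates log2 NGS expression with **−ΔCt** by
default, so platform agreement appears as a positive r (abundance and Ct
are physically inversely related). The raw-Ct orientation is available via
an option and simply flips the sign.

## Composite miRNA score

Panel expression rows are z-standardized with the sample SD (n − 1
denominator; the denominator convention is irrelevant to every downstream
correlation and rank statistic, which are scale-invariant). The score is
the plain signed sum Σ_m s_m z_{m,i} — no division by panel size — with
s_m = +1 for "up" and −1 for "down" members, generalizing the
downregulated-only formulation (where the score is the sum of negated
z-values) to mixed-direction panels while preserving its orientation:
the score rises with risk. On the ΔΔCt scale signs are flipped internally,
making ΔΔCt-scale and (−ΔΔCt) expression-scale scoring identical.

Consequences asserted as invariants: scores sum to zero across samples;
they are invariant to independent positive affine transforms of each
member's expression; flipping one member's direction changes the score
vector by exactly −2 s_m z_m. Group discrimination uses Welch t and
Mann–Whitney on the scores (low vs intermediate+high by default, pairwise
on request); within-group extremity ranks descend from the highest score,
ties broken by sample order.

## Synthetic cohort generator

The generator emulates the study design so that every stage is testable
without the (non-public) patient measurements. Defaults, chosen from that
design:

- **Cohort**: 32 samples (the sequenced-subset size), group weights
  26:10:5, scores uniform within 0–38 / 39–54 / 55–80, ages normal per
  group (means 64.8 / 63.7 / 56.4, SDs 12 / 13 / 10 years) rounded and
  truncated to 25–90, grades drawn from group-conditional frequencies
  matching the example table.
- **Counts**: log2 relative abundance a_j + β_j·score* + γ_j·age* +
  batch effect, where score*/age* are standardized with the *realized*
  sample mean/SD (so β is interpretable as log2 change per SD at any n),
  batch effects are N(0, 0.25²) log2 units per (batch, miRNA), and samples
  are multiplexed round-robin into 4 batches of ≤ 18 (extra batches open
  automatically for larger cohorts). Per-sample relative abundances are
  renormalized, library sizes are log-uniform on [5×10⁵, 2×10⁶], and
  counts are negative-binomial with variance μ + μ²/θ, θ = 10. The
  reference configuration plants 15 score-associated miRNAs at |β| = 0.8
  (10 up : 7 down sign ratio scaled to the planted count) with baselines
  log-uniform in 0.1–1% relative abundance — the window the screens' top
  hits occupy; background baselines are log-normal.
- **Ct tables**: Ct = 16 − log2(relative expression) + N(0, 0.3²) per
  replicate, three replicates, control gene at mean Ct 20 with the same
  replicate noise. At σ = 0 the ΔΔCt pipeline inverts the model exactly.

All draws come from a single seeded NumPy generator in the order
clinical → counts → Ct, so one seed fixes the whole cohort bit-for-bit.

What the generator does **not** emulate: FFPE degradation and length
biases, adapter/calibrator chemistry, zero inflation beyond NB sampling,
miRNA–miRNA covariance beyond compositional closure, and qPCR efficiency
drift. One consequence worth knowing: because planted miRNAs occupy a
noticeable share of the library, total-count normalization induces small
anti-correlated shifts in null miRNAs (compositional closure), so at the
reference configuration the empirical "FDR" versus planted truth runs
slightly above the nominal BH level even though the screen is correct —
under a global null (nothing planted) the empirical FDR is controlled at
the nominal level, and that is the property the suite asserts. Passing
tests therefore demonstrate correctness of the pipeline's arithmetic and
its operating characteristics under an NB compositional model, not
performance on real FFPE data.

## Numerical choices and degenerate inputs

- Correlations clamp r to [−1, 1] before the t transform; |r| = 1 yields
  p = 0 (a measure-zero event for continuous data).
- Identical constant groups in Welch's test return statistic 0, p = 1
  rather than 0/0.
- Chi-square requires strictly positive marginals (degenerate-table error
  otherwise); a statistic of exactly 0 reports p = 1.
- BH validates p ∈ [0, 1] and preserves input order; ties are handled by
  stable sorting.
- Zero-total count columns and missing qPCR controls raise errors naming
  the offending sample; constant expression rows and constant covariates
  propagate as not-testable flags.

## Problem sizes in the checks

The acceptance script and suite size their simulations to the study
design: 50 null replicates and 20 planted-effect seeds at 32 × 300, one
matched NGS/qPCR cohort per metric, and 200 replicates for the
15-vs-15 discrimination power estimate. The whole script completes in
seconds on one CPU.
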