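# Methods

This note documents the models, conventions and design choices behind
`zoometry`, in the spirit of a statistical-software methods appendix.

## Measurement schema and data handling

A record carries an opaque animal id, a biotype (NEGRO, CALLEJON,
ATIGRADO), a sex, an optional live weight (kg) and up to 17 named
linear measurements in cm. The interchange format is plain CSV with a
mandatory header, decimal points regardless of locale, and a fixed
column order (id, biotype, sex, weight, then the 17 codes in schema
order). Missing measurements are empty cells, never zero; records with
any missing measurement are excluded from index computation but retained
for per-trait summaries. Numbers are written with Python's shortest
round-trip representation so that write→read reproduces every field
exactly.

Validation separates hard failures (non-positive or non-finite values,
which the record constructor refuses outright) from soft plausibility
warnings: a value outside mean ± 5 SD of the built-in calibration for
its trait (SD derived from the calibrated CV%) is flagged but not
rejected, since the screening emulates the field practice of excluding
visibly defective animals without any published numeric rule. The ±5 SD
width and the calibration tables are configurable.

## Zoometric indices

Nine indices are pure measurement ratios × 100 and are therefore
invariant under uniform rescaling of the animal. The anamorphosis index
AI = TP²/HaW is degree-1 homogeneous and unit-sensitive. The classical
formula is often quoted as "TP²/HaW × 100 with lengths in cm", which
evaluates near 25,000 for adult cattle, while the values used in breed
characterization are near 2.5; those are reproduced by evaluating
TP²/HaW with lengths in metres, i.e. TP²/(100·HaW) in cm. The
metre-equivalent form is the default; the literal centimetre form is
kept behind `convention="literal_cm"` for comparison with sources that
print the large-magnitude variant. (Per-sex AI values around 1.4–2.0
reported in parts of the characterization literature cannot be
reconciled with the per-biotype values near 2.5 under any single unit
convention; the package does not attempt to reproduce them.)

Population index means are always computed as means of per-animal
indices, never as indices of group-mean measurements. The two differ by
a Jensen gap of order CV² (≈0.1–0.5% at the calibrated CVs), which is
small but systematic; tests verify the gap shrinks as CVs shrink.

Full precision is kept internally; reporting rounds half away from zero
to 2 decimals (decimal-based, so printed halves round up).

## Aptitude classification

Index interpretation follows the conventional dairy/beef reading: TI,
BI, AI, DTI, DCI form the dairy block, LBI, PI, TPI, LPI the beef
block, CEI is purely descriptive (dolichocephalic below 50) and never
votes. Quantified cutoffs exist for DTI (dairy < 10, beef > 11,
otherwise dual — both inequalities strict), TPI/LPI (beef > 33), the AI
dairy band [2.5, 3.0] (below the band reads beef-side: low thoracic
capacity per stature), and PI (brachypelvic < 100). TI, BI, LBI and DCI
have only comparative guidance in the literature, so their cutoffs
(elliptical thorax TI < 60, brevilineal BI < 85, compact LBI < 90,
dairy DCI > 45) are heuristics chosen to reproduce the conventional
qualitative reading of the calibration population's index profile; they
are flagged `heuristic` in every report and overridable via YAML.

The verdict is a majority vote over the nine aptitude-bearing indices.
An index votes with the side its label indicates; an index whose label
is inconclusive (DUAL) or descriptive (PI) votes with its block
membership. Unanimity yields DAIRY or BEEF outright; any split yields
DUAL with a tendency toward the majority; an exact tie (impossible with
nine voters under the default blocks, reachable under user-configured
blocks) yields plain DUAL. On the calibration population's pooled
profile this gives 5 dairy vs 4 beef — dual-purpose with a dairy
tendency — with the DTI value (10.24) sitting in the dual gap and
contributing its dairy-block vote.

## Descriptive statistics

Mean, SEM = s/√n and CV% = 100·s/mean use the n−1 sample standard
deviation. The pooled ("overall") row is computed on the concatenated
sample rather than by averaging group statistics, so pooled CV includes
between-group separation; group-size-weighted identity of the pooled
mean is tested exactly. Groups of size 1 report NaN SEM/CV with a
warning. Default summaries group by biotype (sexes pooled), with a
by-sex flag for per-sex index reports.

## Inference

ANOVA fits the fixed-effects factorial `y = biotype + sex +
biotype·sex + e` by OLS on dummy-coded designs (numpy lstsq); sums of
squares come from residual-sum comparisons of nested models. Type II is
the default for the unbalanced observational design: each main effect
is adjusted for the other, and the models testing main effects exclude
the interaction (marginality), which is tested last against the full
model. Type I (sequential) and Type III (sum-to-zero contrasts, each
term dropped from the full design) are available by flag; all three
coincide on balanced designs, and the decomposition is verified against
an independent reference implementation to 1e-8 on random datasets.
An empty biotype×sex cell makes the interaction inestimable and raises
a design error, with an explicit main-effects-only fallback. A constant
response reports zero sums of squares and NaN p-values with a warning.

Pairwise comparisons use Tukey's studentized range with the Kramer
standard error for unequal n, SE = √(MS_res/2·(1/nᵢ+1/nⱼ)), and
adjusted p from the studentized-range distribution with (k, df_res).
With k = 2 this reduces exactly to the pooled-variance two-sample test
(q = √2·|t|). Letters come from the insert-and-absorb compact letter
display: starting from one column holding all groups, each significant
pair splits every column containing both, and columns that are subsets
of others are absorbed; the invariant — two groups share a letter iff
their pair is not significant — is verified exhaustively for all
significance patterns with k ≤ 5. α = 0.05 throughout by default.

Pearson correlations are pairwise-complete with p-values from
t = r·√((n−2)/(1−r²)); no multiplicity correction by default, matching
per-pair significance reporting in the characterization literature,
with Bonferroni and Holm available by flag. Assumption screening
(Shapiro–Wilk per group, Brown–Forsythe across groups) is advisory
only: the pipeline logs outcomes and proceeds.

## Synthetic herd generator

The generator emulates the calibration population: 95 animals in six
biotype×sex cells (females 53/16/14, males 4/4/4), per-biotype trait
means, and one pooled CV% per trait applied within biotype — the only
dispersion published per trait. Within-biotype SD is therefore
CV%·(biotype mean)/100, which slightly overstates the pooled CV for
traits whose biotype means separate; at the calibrated values the
effect is below the acceptance tolerances. Sex multipliers default to
1.0 because per-sex measurement means are not published; the multiplier
exists for sensitivity studies.

Only a qualitative correlation pattern is public (verbal strength
classes), encoded as representative magnitudes: strong ≈ 0.7,
intermediate ≈ 0.5, strong negative ≈ −0.6, absent = 0, with head
width uncorrelated with everything. These are configuration, not
constants. The assembled pattern is not guaranteed positive definite,
so it is repaired with Higham's alternating-projections nearest
correlation algorithm (PSD projection by eigenvalue clipping with a
Dykstra correction, alternated with the unit-diagonal projection;
convergence tolerance 1e-12, eigenvalue floor 1e-8 followed by
diagonal renormalization). The repair is idempotent on PD inputs up to
solver tolerance and is cross-checked against an independent
implementation in the tests.

Draws are multivariate Gaussian per cell with covariance D·R·D,
D = diag(CV·mean/100); rows with any non-positive coordinate are
rejected and redrawn, a negligible truncation at CVs ≤ 11.32% (a
configuration warning fires above 1% rejection). A Gaussian with
rejection was preferred over a log-normal so that the configured means
and CVs remain the (near-exact) moments of the output. Fixed
(config, seed) reproduces the herd bit for bit.

What the generator does not emulate: measurement error structure,
age/parity covariates, sex dimorphism (by default), non-Gaussian tails,
and the exact (unpublished) correlation coefficients. Pipeline tests on
synthetic herds therefore validate the computational chain and its
calibration targets, not field-data behaviour.

## Problem sizes and numerical choices

Moment-recovery and end-to-end checks use herds of 20,000–60,000
animals, where sampling noise is an order of magnitude below the
tolerances being checked (0.2 cm on pooled means, 2% relative on index
means); calibration checks of the 95-animal default use 20 replicate
seeds. Tie-breaking: aptitude cutoffs are strict inequalities at both
DTI boundaries; TPI/LPI at exactly 33 read dairy-side. Degenerate
inputs (constant responses, zero-variance variables, singleton groups,
empty cells) are reported as NaN-with-warning or explicit errors rather
than silently propagated.

## Known limitations

- The heuristic TI/BI/LBI/DCI cutoffs are calibrated to one
  population's qualitative reading; other breeds may need overrides.
- The pairwise-comparison letter patterns of small unbalanced designs
  (n = 57/20/18) are borderline by construction: significance of the
  observed biotype contrasts in rump length flips with sample size, so
  letter displays should be read jointly with the adjusted p-values.
- Live weight is carried through records but not simulated and not
  included in the correlation screen by default.
- The factorial ANOVA assumes fixed effects and independent residuals;
  no mixed models, repeated measures or nonparametric fallbacks.
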