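# Methods

This note records the models behind each stage of `crosskill`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Synthetic screen model

A screen is parameterized by a `ScreenTruth`: per-compound shared effects
`c_j` (percent killing), per-(species, compound) offsets `s_{a,j} ~
N(shift_a, σ_s²)`, per-(line, compound) offsets `l_{i,j} ~ N(0, σ_l²)`, and
well-level noise σ_n. True killing of compound j in line i of species a is
`k_ij = c_j + s_{a,j} + l_{i,j}`. Offsets are drawn deterministically per
species/line name from the truth seed (CRC-keyed substreams), so the same
truth yields the same screen for any subset of lines.

Well luminescence encodes killing against a per-plate control level `L_p`
drawn log-normally around 10⁶ RLU (the assay's raw scale is arbitrary;
10⁶ is a typical plate-reader magnitude, CV 10%):
`lum = L_p (1 − k/100) + ε`, `ε ~ N(0, (σ_n/100) L_p)`, clipped at 0 with a
flag. With σ_n = 0 the normalization chain recovers `k` exactly — the
round-trip identity the test suite asserts to 1e−9. Plates are 384-well
(96 supported) with vehicle controls in the rightmost columns
(32 controls/plate by default — the screened library's true layout is not
public, so the control count is a declared default, not an inference) and
compounds stamped in consecutive-replicate order, paginated across plates.
2100 compounds in triplicate therefore occupy ⌈6300/352⌉ = 18 plates per
cell line. An optional multiplicative edge-effect droop exists for stress
tests and is off by default; no spatial correction is implemented
downstream (out of scope).

Default variance components (σ_s = 6, σ_l = 4, σ_n = 8 pp) give
realistically noisy but species-structured screens: triplicate means carry
σ_n/√3 ≈ 4.6 pp of noise, comparable to a well-run CellTiter-Glo screen.

### Driver planting

`generate_compound_library` plants driver targets as
`(target, n_drugs, n_sensitive)`. Sensitive drugs draw shared effects in
(65, 95)% and take **no** offsets; everything else (resistant driver drugs,
background compounds) is capped at an `inactive_ceiling` of 48% killing in
every line. The hard separation makes ground truth unambiguous: at zero
noise the target roll-up must return exactly the planted drivers, and at
the default noise the probability that a 40–48%-true compound crosses 50%
in *both* lines is small enough that false passing targets are rare. The
ceiling is a property of the library generator; manually built truths
(e.g. variance-component screens) default to no ceiling. The template
9/11 + 3/4 planting mirrors the proteasome/CRM1 selection pattern the
pipeline is designed to reproduce.

### Concordance planting

The squared Pearson correlation between two species' per-compound profiles
is `R² = [σ_c² / √((σ_c²+v_a)(σ_c²+v_b))]²` with
`v = σ_s² + (σ_l² + σ_n²/n_rep)/n_lines`. `shared_effect_sd(target_r2, ...)`
inverts this on the R² scale — the scale screens report — so a planted
0.54 is measured back as R² ≈ 0.54, not as the raw variance ratio (which
would square to ≈0.29). This is the one place where "shared fraction" is
deliberately defined through the statistic rather than the variance
decomposition; the helper documents the algebra.

### What the generator does not emulate

No plate spatial gradients by default, no compound carryover or edge
evaporation, no heteroscedastic luminescence (noise scales with the control
level, not the well mean), no correlated polypharmacology (multi-target
drugs are supported by the annotation but not planted by default), no PK/PD
or engraftment biology in the tumor generator, and exponential —
not Gompertzian — tumor growth. Passing tests therefore demonstrate that
the *analysis chain* is correct and calibrated under its stated model, not
that real screens are free of these artifacts.

## Normalization

Percent killing is `100 (control_center − treated)/control_center` with the
plate's own control **median** (robust to a dead control well; mean
available). Killing is normalized to vehicle-only controls — no day-0
baseline plate is modeled, so negative killing means growth stimulation
relative to DMSO and is retained (clipping available but off: thresholding
happens downstream on the raw scale). Replicates are averaged; a QC flag
records replicate luminescence CV > 20% or n = 1, and flagged entries are
kept but marked. Plates with fewer than two vehicle controls are excluded
with a warning rather than failing the run.

## Hit analysis

Hits use killing ≥ threshold (default 50); the roll-up deliberately uses
strict > 50 — both conventions are exposed because screening reports mix
"≥50%" (hit fractions) and ">50%" (target filters), and the two differ only
on exact-boundary values.

Analysis of Means flags compounds outside
`ȳ ± h · s_p · √((k−1)/(k n_i))`, with `s_p` the pooled within-group sd
(df = Σ(n_i−1)) and `h` the **Bonferroni** t quantile `t(1−α/(2k); df)`.
Exact ANOM constants (multivariate-t / Nelson tables) are slightly tighter;
the Bonferroni bound is conservative, closed-form, and testable against an
independent oracle, which the suite does over the full k∈{2..5} × n∈{2..4}
grid. Under the null, the family-wise flag rate is verified ≤ α at 2000
simulations. Unbalanced designs use the per-group n in the limit with a
warning (classical ANOM assumes balance). α defaults to 0.05 — the original
procedure's settings are not recorded anywhere, so this is a declared
assumption. In the pipeline the ANOM replicates for a compound are its
per-cell-line mean killings, i.e. "top drugs" means high mean killing
across the panel relative to the screen-wide grand mean.

## Concordance

Clustering: Euclidean distance on raw killing profiles with average
linkage (neither is dictated by anything in the source analyses; both are
recorded in the result and `correlation`/`complete` are exposed). Species
purity is the best species↔clade assignment accuracy at the k = 2 cut.
Flagged/missing entries are mean-imputed per compound with the count
reported. All-tied distance matrices are flagged `degenerate` (leaf order
then depends on input order). Concordance uses species-mean profiles when
a species has several lines, and the t-approximation p-value.

## Target roll-up

A drug counts toward every annotated target (no fractional weighting — a
deliberate choice: down-weighting promiscuous drugs would require potency
data the annotation lacks). The filter is `n_drugs_hit ≥ m` with m = 3,
killing > 50% required in **all** lines by default ("any" or a named list
available); monotonicity in threshold and m is property-tested. No
enrichment p-value is attached: the procedure is a count filter, and a
hypergeometric test would need a null model for target-size bias that the
annotation cannot support.

## Dose-response and synergy

4PL fits use `scipy.optimize.curve_fit` from a grid of starts (four IC50
decades × four Hill values, Hill sign free) with tight tolerances; the best
RSS wins. Fits are canonicalized to top ≥ bottom via the 4PL symmetry
`(top, bottom, h) ≡ (bottom, top, −h)`. IC50 is the inflection (relative
EC50); the absolute 50%-viability crossing is reported alongside when the
curve spans 50%. `ic50_in_range` flags extrapolated IC50s;
flat/degenerate responses return `converged=False` with best-effort
parameters rather than raising. Noiseless recovery is exact to 1e−6
relative; at 5% response noise the median IC50 error is within a quarter
of a 4-fold dilution step (both asserted in the suite).

Synergy is **Bliss independence** (excess over `Ea + Eb − Ea·Eb`), computed
from the measured zero-dose row/column of the checkerboard. Bliss needs
only the single-agent data a checkerboard already contains; Loewe/CI would
require full single-agent curves and is out of scope. The summary statistic
is the mean excess over interior cells; calibration (≈0 on additive grids,
planted +0.10 recovered within ±0.03) is asserted over 100 seeds.

Doubling times are `ln 2 / slope` of a log-linear fit; numerically-zero
slopes report ∞ with a `flat` flag and negative slopes keep their sign with
a `declining` flag instead of silently returning a positive time.

## In vivo

Caliper volume is `(L × W²)/2` with the smaller reading as W (auto-swap) —
the standard xenograft ellipsoid approximation. Study rules re-zero each
mouse at its first measurement ≥ 100 mm³, drop mice that never reach it,
and truncate at the first crossing of 1500 mm³ (crossing record kept) or
day 18 post-randomization, all recorded in an exclusion ledger; the
operation is idempotent. The ANOVA is a plain fixed-effects group × day
two-way ANOVA: balanced designs by direct sums of squares (identity to the
oracle asserted at 1e−9), unbalanced by Type-II SS via statsmodels, noted
in the output. Repeated measures within mouse are *not* modeled — the
analysis this reproduces used plain two-way ANOVA — and the output carries
that caveat. Because per-mouse re-zeroing can stagger day grids,
`shared_days` aligns the analysis to the intersection of measured days (no
interpolation). Type-I error at α = 0.05 is verified at 0.05 ± 0.01 over
2000 null simulations with additive measurement noise.

## Survival scan

Kaplan–Meier is the product-limit estimator; the log-rank statistic is
`(ΣO − ΣE)²/ΣV` with hypergeometric variance per distinct event time and a
χ²(1) p-value, verified against lifelines and against a 10,000-permutation
oracle on small cohorts (agreement within 0.04 — three Monte-Carlo sd plus
an allowance for the discreteness of small-n permutation distributions).
The cutoff scan tests every midpoint between consecutive distinct
expression values with both groups ≥ `min_group_frac·n` (default 0.1,
preventing 1-vs-(n−1) splits), reports the argmin-p cutoff (ties broken
toward the median), and always reports the number of cutoffs scanned: the
scanned minimum p is anti-conservative, and the suite verifies the bias
under the null rather than hiding it. No correction is applied so the
behavior of the scanned analysis is reproduced transparently; users can
Bonferroni-correct with the reported count.

## Pipeline and problem sizes

`run_pipeline` chains all stages from a validated config whose defaults
mirror the study design (1 µM triplicate 384-well screens, θ = 50, m = 3,
20 µM/4-fold dilutions, 100/1500 mm³ and day-18 rules, 5 mice/arm);
stochastic behavior flows from the single config seed and reruns are
bit-identical (content-hashed manifest). The test suite's Monte-Carlo sizes
(200 seeds for driver recovery and clustering purity, 100 for concordance
and Bliss, 2000 for the ANOM and ANOVA calibrations, 10,000 permutations
for the log-rank oracle) were chosen so each check resolves its tolerance
with comfortable Monte-Carlo margin while the whole suite stays
interactive-fast.

## Known limitations

The Bonferroni ANOM is conservative for large k; the scan's minimum p is
reported uncorrected (by design, with the multiplicity note); percent
killing > 100 cannot arise from the generator (luminescence is clipped at
0), slightly truncating the upper tail of planted effects above 100; and
the two-way ANOVA treats repeated measures as independent, so its p-values
are anti-conservative for strongly autocorrelated growth curves — a
mixed-effects growth model is deliberately out of scope.
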