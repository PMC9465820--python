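# Methods

## Measurement model and deconvolution

A mixed-extract sample is modeled as a linear combination of the two
subpopulations' per-cell metabolite abundances:

```
I_mix(m) = alpha_P · N_P(m) · V_P + alpha_Q · N_Q(m) · V_Q + beta
```

for mix `m` of a condition (cell line × quiescence stimulus). The two
assumptions this rests on are (i) linearity of measured ion intensity in
the amount of metabolite injected — enforced upstream by the spike-in QC
and the biological-origin filter — and (ii) additivity of the two
extracts' contributions, i.e. no interaction between subpopulations in
the mixed extract. Cell volumes are set equal (`V = 1`) by default, as
forward-scatter-based volume estimates show no characteristic G0/non-G0
difference; the API accepts per-population volumes for sensitivity
analyses.

**Mixing design.** Extracts taken at 8 h (mostly proliferating) and 96 h
(mostly quiescent) after the stimulus are mixed at fractions
`f ∈ {1.00, 0.85, 0.70, 0.55, 0.40, 0.25, 0.10, 0.00}` of the 8-h
extract, in triplicate, at constant total cell number `T`. With G0
fractions `g8`, `g96` of the two end-point cultures (from cytometry
gating), the counts in a mix are `N_Q = T·(f·g8 + (1−f)·g96)` and
`N_P = T − N_Q`. The design is identifiable iff `g8 ≠ g96`; equal
fractions are rejected with a diagnostic rather than producing a
rank-deficient solve.

**Fit.** Per ion, `min ‖(I_mix − beta) − X·alpha‖²` subject to
`alpha ≥ 0`, solved by NNLS. The stacked design over all conditions is
block-diagonal (two columns per condition), so the joint solve is
executed condition-by-condition; this is exact, not an approximation.
Background-corrected intensities that fall below zero are kept as-is —
the nonnegativity constraint belongs on the coefficients, not the data.
On blocks whose unconstrained optimum is already nonnegative the NNLS
solution coincides with the closed-form normal-equations solution
(verified to 1e-10 relative in the tests); rank-deficient blocks are
flagged unidentifiable with NaN coefficients instead of silent zeros.

**Errors.** Residual (fixed-X) bootstrap: within each condition block,
residuals are resampled with replacement, added to the fitted values,
and the constrained model refit; the coefficient SD over 100 repetitions
is the reported error. Resampling is scoped to the block because the
design is fixed by construction and error structure is
condition-specific; each ion resamples independently. The bootstrap SD
carries the usual mild downward bias of fitted residuals
(≈ `sqrt(1 − p/n)` ≈ 0.96 for 24 rows and 2 parameters), which is left
uncorrected to keep the published procedure as stated.

**Purified profiles.** The end-point samples can be corrected for the
minor subpopulation: at 96 h, `I_G0 = I_mix − alpha_P·N_P·V_P`, divided
by `N_Q` for a per-cell value; the 8-h sample is treated symmetrically.
Negative purified intensities are floored at zero and flagged. If a
per-ion background is supplied it is subtracted before normalization, in
which case noise-free per-cell values equal the focal alpha exactly;
without it they carry the `beta/N` offset of the plain subtraction
equations. Downstream analyses use the alphas, which are invariant to
cell numbers, rather than the purified end-point profiles.

**Validation against reference profiles.** Deconvolved per-cell-line
abundances can be compared to an independent dataset by Spearman
correlation across shared cell lines, restricted to "characteristic"
ions whose cross-cell-line variation exceeds 3× the typical (median)
per-cell-line error; a permutation null scrambles the cell-line labels.

## Upstream QC

**Spike-in linearity.** Per ion and sample matrix, the saturation limit
is the intensity at the first spike level from which every subsequent
successive-difference slope stays below 10 % (configurable) of the
initial-region slope (OLS over the first 3 points); series with
non-positive initial slope are flagged non-responsive. Points at or
above the limit are excluded before the base OLS model (slope,
intercept, slope p-value, R²) is fitted; at least 3 unsaturated points
are required. Transferring a base slope to another matrix refits only
the intercept and reports `1 − SS_res/SS_tot`, which is negative when
the fixed slope fits worse than a constant and undefined (NaN) at zero
total variance.

**Biological-origin filter.** Ions are kept for deconvolution only if
their intensity scales with the number of cells extracted in at least
one cell line. One stacked regression per ion fits a slope per cell line
and a single shared intercept, with cell-free blanks as zero-cell rows
pinning that intercept to the MS background. The retention threshold is
Bonferroni-corrected, `alpha_fw/(n_ions × n_cell_lines)` with
`alpha_fw = 0.05`; at 2,099 ions and 6 cell lines this is 3.97e-06.

## Cytometry gating

DNA-content peaks (2n, 4n) are picked from a Freedman–Diaconis
histogram smoothed with a 3-bin moving average, ranked by prominence,
keeping the most prominent pair whose ratio lies in [1.7, 2.3]; with a
single detectable peak (e.g. a pure-G0 sample) the 4n peak is imputed at
2× with a fallback flag. DNA window half-widths are 2.5 robust SDs
(1.4826·MAD) of the 2n mode, the 4n half-width scaled by the peak ratio
(constant CV). The RNA threshold separating G0 from G1 is the 5th
percentile of RNA intensity among events in the S and G2/M DNA windows —
a robust lower envelope of the proliferating RNA distribution; deriving
it requires at least 2 % of events in those windows so that a pure-2n
sample's lognormal tail cannot masquerade as an S/G2M population. Gates
derived on the 8-h reference sample of a cell line are reused on its
96-h sample. Events outside all windows are reported as unclassified and
excluded from the fractions. All gate parameters scale with the data, so
gating is invariant to positive rescaling of either channel.

## Differential statistics

**Effect sizes.** `d = (alpha_Q − alpha_P)/SD_pooled`,
`SD_pooled = sqrt((SD_P² + SD_Q²)/2)`; undefined (NaN, excluded
downstream) when both SDs are zero. Negative `d` means lower abundance
in quiescent cells.

**G0 association.** For thresholds `t` from 3 up to the ceiling of the
mean absolute effect size (overridable to a fixed grid, e.g. 3–13), each
ion's conditions with `d > +t` and `d < −t` are counted and the sign
with the larger count prioritized (ties go to the sign with the larger
summed magnitude and are flagged). Significance is the upper-tail
hypergeometric probability of drawing at least the observed count when
sampling the ion's `n = 18` conditions from all same-sign effect sizes
pooled over the table (`n` truncated to the pool size; a switch restricts
draws to the ion's same-sign count instead). Per ion the
minimum-p threshold is reported, smallest threshold on ties, and BH
correction is applied once across ions after threshold selection — the
selection-induced optimism is part of the procedure and is reproduced,
not corrected. The scipy tail probability is checked against an
exhaustive combinatorial enumeration in the tests.

**Other tests.** One-way fixed-effects ANOVA across stimuli per ion
(≥ 2 groups of ≥ 2), BH-corrected. Dynamic treatment profiles are
normalized by a per-ion linear regression of abundance on confluence in
steady-state samples: `log2FC = log2(measured/expected)` at the matching
confluence (extrapolation beyond the steady-state range flagged,
non-positive expectations undefined), with unpaired t-tests against all
unperturbed samples and BH correction across ions per time point.

## Growth kinetics

Confluence is log10-transformed and OLS slopes fitted over 24-h moving
windows — `round(24/dt)` consecutive points, i.e. 16 points at the 1.5-h
sampling interval — advanced by `round(8/dt)` points (7.5 h at 1.5-h
sampling, since 8 h is not an integer number of points; the actual spans
are reported in the output). Windows containing non-positive confluence
are skipped; windows whose mean confluence exceeds 0.95 are excluded
from maximum-rate selection so tangents are never taken to saturated
regions. The lag time is `(log10(c_init) − a)/b` with `(a, b)` the
max-rate window's fit and `c_init` the first observation of the segment;
no positive-rate window yields a lag censored at the series end.
Expected lags at a given initial confluence are piecewise-linear
interpolations of untreated (confluence, lag) pairs, extended along the
nearest segment with a flag outside the hull; excess lag is observed
minus expected.

## Annotation

Neutral monoisotopic masses are computed from elemental formulas using
most-abundant-isotope masses (C, H, N, O, P, S plus a configurable
extension set). The default adduct rule is deprotonation
([M−H]⁻, expected m/z = M − 1.007276), configurable to [M+H]⁺ or neutral
matching; negative-mode flow injection is the assumed ionization.
Matching is strict at 0.003 m/z by default (inclusive comparison
available, with a 1e-12 Da guard for floating-point boundary cases); all
references within tolerance are reported closest-first, never collapsed.
Flagged alpha-keto acids gain phenylhydrazone derivative entries
(+C6H8N2 −H2O, +90.0582 Da, prefix `PHderiv_`) reflecting the
phenylhydrazine stabilization used during extraction. The bundled
reference list is a small curated set (30 common metabolites including
10 alpha-keto acids) for demonstrations and tests; production use
supplies full database exports as TSV.

## Synthetic-data generator

The generator emulates the four measurement types the workflow consumes
and always stores its ground truth.

- **Mixed-extract intensities** follow the mixing model above. Noise is
  mean-one multiplicative log-normal (CV parameter) plus an additive
  Gaussian floor, because MS intensity error is dominantly proportional
  at high signal and additive near the detection limit; both default to
  0 so the noise-free limit is exact. Saturation is a hard clip by
  default (a soft exponential-approach variant is available). Default
  conditions mirror the study design: 8 mix fractions, 3 replicates,
  1e4 cells per sample, G0 fractions 0.1 (8 h) and 0.8 (96 h). True
  alphas are log-normal across ions (median 20 intensity units/cell,
  log-SD 1), spanning the orders of magnitude typical of untargeted
  flow-injection data.
- **Spike-in series** are `base + slope·spike` through the same noise
  and saturation model, with a 3-decade geometric spike grid
  (3–3000 pmol) by default and triplicate rows.
- **Cytometry events** are log-normal clouds: G0/G1 DNA at the 2n peak,
  G2/M at 2×, S uniform between the flanks; RNA per phase with G0 far
  below the proliferating phases (locations 35 vs 140–160, log-SD
  0.15–0.18) and the proliferating clouds overlapping each other, so the
  lower-envelope RNA threshold lands in the G0/G1 gap. Per-event phase
  labels are stored so gating accuracy is measurable.
- **Confluence curves** are flat at `c0` until the lag, then
  `c0·10^(rate·(t−lag))` capped at a plateau, on a regular grid with
  optional additive noise.

What the generator does **not** emulate: raw spectra, isotope patterns,
ion suppression beyond a per-ion saturation cap, heteroscedastic
structure beyond the CV+floor model, cytometry doublets/debris, or
segmentation artifacts in confluence estimates. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
model, not robustness to every artifact of real instruments.

## Numerical choices and limitations

- NNLS convergence is delegated to scipy's active-set solver; oracle
  equivalence at 1e-10 relative on interior solutions is the acceptance
  bar.
- Hypergeometric p-values are floored at the smallest positive float so
  BH correction never sees an exact zero.
- The bootstrap, permutation null, and all simulations accept explicit
  seeds; identical seeds give bit-identical outputs.
- Problem sizes in the test suite and acceptance script (200–500 ions,
  100 bootstrap repetitions, 1e4 cytometry events, 100 random blocks)
  are chosen to pin the statistical claims while keeping a full run in
  the seconds-to-minutes range.
- Only the two-population case is validated end to end; the design
  matrix builder generalizes to more populations per condition, but no
  guarantees are claimed there.
- The exact published alpha-keto-acid list is not reproduced; the
  bundled set covers the common compounds without claiming equivalence.
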