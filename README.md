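# mixdeconv

Sorting-free deconvolution of subpopulation metabolic profiles from
designed mixtures of bulk cell extracts.

## The problem

Bulk metabolomics of a cell culture averages over every cell in the dish.
When the culture contains two co-occurring subpopulations — typically
quiescent (G0) and proliferating cells after a growth-arresting stimulus —
the bulk profile hides which metabolites differ between the two states,
and physically sorting cells perturbs the metabolome faster than it can be
measured. `mixdeconv` implements a sorting-free alternative: extracts
taken at two time points with different (cytometry-measured) G0 fractions
are mixed at a series of known ratios, and the measured ion intensity of
each metabolite across the mix series,

```
I_mix = alpha_P · N_P · V_P + alpha_Q · N_Q · V_Q + beta,
```

is decomposed by non-negative least squares into per-cell abundances
`alpha_P` (proliferating) and `alpha_Q` (quiescent). `N_P`, `N_Q` are the
known subpopulation cell counts in each mixed sample, `V` the relative
cell volumes (equal by default) and `beta` the ion-specific instrument
background estimated from cell-free blanks. Coefficient errors come from
a residual bootstrap (100 repetitions); standardized effect sizes
`d = (alpha_Q − alpha_P)/sqrt((SD_P² + SD_Q²)/2)` across a grid of cell
lines and quiescence stimuli feed a hypergeometric consistency test that
calls metabolites robustly associated with the quiescent state.

The package is aimed at metabolomics/proteomics groups running
flow-injection MS on heterogeneous cultures, and it covers the full
workflow around the regression: a synthetic experiment generator with
known ground truth, DNA/RNA cytometry gating (G0/G1/S/G2M), spike-in
linearity QC with saturation detection and a biological-origin ion
filter, purified per-population intensity profiles, downstream
differential statistics, growth-curve lag estimation, and accurate-mass
metabolite annotation.

## Worked example

`examples/deconvolve_mixture.py` simulates the 8-point mixing design
(100, 85, 70, 55, 40, 25, 10, 0 % of the 8-h extract in the 96-h extract,
three replicates, 10 % multiplicative noise) and recovers the planted
per-cell abundances:

```
    ion population  alpha_true  alpha_fit    sd
ion0000          P      28.256     28.134 1.004
ion0000          Q      20.577     21.780 1.294
ion0001          P      45.484     41.981 1.486
ion0001          Q      34.551     38.559 1.750
...
median relative error of the fitted alphas: 0.018
```

`alpha_fit` is the estimated per-cell ion intensity in each subpopulation
and `sd` its residual-bootstrap standard error; a median relative error
of ~2 % at 10 % measurement noise reflects the averaging across the 24
mix samples. The other scripts in `examples/` demonstrate cytometry
gating, spike-in linearity QC, G0-association calling, lag-time
estimation and m/z annotation, each printing a short annotated result.

A thin CLI mirrors the main steps
(`mixdeconv sim|gate|deconv|associate|growth|annotate|run`); run
`mixdeconv run` for an end-to-end synthetic pipeline with a JSON
manifest.

## Documentation

`docs/methods.md` describes the measurement model, the estimation
procedures and their assumptions, the synthetic-data generator and its
limits, and the numerical choices made where the published procedure
leaves details open.
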