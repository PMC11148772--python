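# Methods

## Melt model and normalization

Thermal denaturation of the soluble fraction is modeled by the
three-parameter Boltzmann sigmoid

f(T) = p + (1 − p) / (1 + exp((T − m)/s)),

the de-facto standard for thermal proteome profiling: midpoint m (°C),
transition scale s (°C, s > 0), and a plateau p ∈ [0, 1) for the
non-denaturing residual visible at the top of the gradient. The model
assumes two-state, effectively irreversible denaturation during the brief
heat pulse, and that reporter intensity is proportional to soluble
protein.

Curves are normalized to the lowest-temperature channel (37 °C on the
default ten-point gradient, 37–67 °C over TMT channels 126–131), so the
reference point is exactly 1 and log2 ratios to the reference are
recoverable as log2(fraction). Two normalization subtleties are explicit
design choices:

- **Baseline correction is optional and default-OFF for fitting.** The
  high-temperature residual can either be removed by the affine rescale
  (f − f(T_max))/(1 − f(T_max)) or absorbed by the plateau parameter.
  Doing both would double-correct, so the pipeline fits uncorrected
  fractions and applies the rescale only for 0–1 display parity in the
  heatmap; the choice is a recorded config field (`baseline_correct`).
- **Values above 1 are retained for fitting** (apparent stabilization
  above the reference) and clamped to [0, 1] only in the heatmap matrix.

Normalization divides by the observed reference intensity, which is
proportional to f(37). For melting midpoints well above the gradient start
f(37) ≈ 1 and the normalized curve is the model curve; for proteins
melting close to 37 °C the normalized curve is f(T)/f(37), a rescaled
sigmoid, and fitted midpoints acquire a small upward bias that cancels in
the vehicle–treatment difference. ΔTm statistics are therefore unbiased
under the null regardless of melting range.

## Brute-force fitting

Each (protein, condition, replicate) curve is fitted independently —
replicates are never averaged before fitting, because the shift test needs
replicate-level Tm values. The fit minimizes the sum of squared residuals
over an exhaustive grid:

- midpoint: 0.25 °C steps over [T_min − 2, T_max + 8] (35–75 °C for the
  default gradient) — sub-degree Tm resolution at tractable cost;
- slope: 25 log-spaced values in [0.3, 8] °C — log spacing because SSE is
  far more sensitive to s at the sharp end;
- plateau: 0.05 steps over [0, 0.45] — capped below 0.5 so any fitted
  curve still crosses the 0.5 soluble-fraction line.

That is ~40k grid points per curve, evaluated as one cached model matrix
per (grid, gradient) pair. Ties in SSE are broken lexicographically by
(m, s, p) — the first index in the grid's canonical ordering — so fits are
bit-reproducible. The returned grid SSE is exactly the minimum over the
grid; the test suite re-derives it with an independent point-by-point
evaluation and asserts bit equality.

The optional polish (default ON) is Nelder–Mead started at the grid
optimum and bounded by the grid ranges. An earlier variant confined the
simplex to one grid cell per parameter; that stranded the polish whenever
discretization traded midpoint error against slope/plateau error (the best
grid point can sit in a cell not containing the true optimum), leaving Tm
up to ~2 grid steps off on curves the model represents exactly. With
range-wide bounds the polish recovers noise-free curves to < 1e−3 °C
while remaining deterministic, and refined SSE ≤ grid SSE is guaranteed
because Nelder–Mead never discards its best vertex. Convergence tolerances
are xatol 1e−6, fatol 1e−15, capped at 500 iterations.

Tm is the closed-form 0.5-crossing m + s·ln((1 − p)/(0.5 − p) − 1),
flagged undefined when p ≥ 0.5. Constant curves are flagged non-melters:
no Tm, fit correlation reported as 0.

## Shift testing and hit calling

ΔTm = Tm(treated) − Tm(vehicle), paired by replicate id; replicates where
either Tm is undefined contribute nothing. The replicate shifts are tested
with a two-sided one-sample Student t-test against zero (the paired-design
analogue of the study's protein-level t statistics); a sign-flip
permutation test is available behind `method="permutation"` for designs
with more replicates, since with n = 3 its resolution is only 1/4.
Zero-variance degenerate input maps to p = 0 (nonzero mean) or p = 1
(exact null) rather than NaN.

A protein is called a specific interactor when all of:

- min fit correlation over all its curves (both arms, all replicates)
  strictly exceeds 0.7 — the correlation gates curve quality, not
  replicate agreement (between-replicate correlation is computable but
  does not gate by default);
- p < 0.01;
- every replicate shift has the same strict sign;
- at least `min_replicates` (default 2) shifts are available.

No multiple-testing correction gates the call; a Benjamini–Hochberg
q-value column is emitted for reference. Raising the r threshold or
lowering the p threshold can only remove hits (tested as an invariant).
The hit filters are purely statistical — a reproducible 0.3 °C shift can
pass — so practical target lists usually add an effect-size cut on the
mean shift; the table is sorted by |mean ΔTm| to make that easy.

The ΔTm density (display parity with the shift-distribution figure) is a
Gaussian KDE with Silverman bandwidth in absolute °C, computed directly
with numpy because scipy's `gaussian_kde` only exposes relative bandwidth
factors; zero-spread input falls back to a flagged 0.1 °C bandwidth.

## TMT plumbing

**Isotope impurities.** The impurity matrix A has entry (i, j) = fraction
of channel j's true signal observed in channel i (columns = true channel,
following vendor data sheets); the vendor-style −2/−1/+1/+2 percentage CSV
is expanded internally, with leakage beyond the plex boundary treated as
lost. Correction solves A·x = observed; diagonal dominance (validated on
input) guarantees invertibility. Solutions more negative than a relative
tolerance of 1e−6 of the total signal raise a warning flag; smaller
negatives are clipped to zero and flagged per entry. Mix followed by
correct round-trips to ~1e−15.

**PSM aggregation.** Protein intensity per (condition, replicate, channel)
is the channel-wise sum over the protein's PSMs (summing within, not
across, replicate injections). Uncertainty comes from a sum-based
bootstrap: PSMs resampled with replacement (default 1000 draws, seeded),
re-summed, and summarized by the 2.5/97.5 percentile interval and
resampling sd — percentile rather than BCa intervals for simplicity.
Curves with missing channels or a zero reference intensity are dropped
with a logged count; no imputation, because the fit needs the full
gradient.

## Global-proteome statistics

Spectrum-level log2 ratios are taken against the mean of the control
channels. Spectrum weights are inverse variances from a global
intensity-dependent variance model v = a + b/I fitted by least squares to
squared within-(protein, channel) residuals — a deliberate simplification
of the full weighted spectrum→peptide→protein model the field uses for
TMT statistics, which is substantially more machinery; uniform weights
(`weighting: uniform`) are the fallback and reduce exactly to plain means.
Protein ratios are standardized across proteins to Z-scores (mean 0,
sample-sd 1, enforced to 1e−9), compared between channel groups with a
pooled two-sample Student t-test (Welch behind a flag), and thresholded at
p < 0.05 (configurable) to define the foreground for enrichment.

Enrichment is the standard upper-tail hypergeometric over-representation
test against user-supplied GMT collections, BH-corrected across sets, with
the universe defaulting to all quantified proteins to avoid detection
bias. Set-level results are plain tables; no curated pathway database or
network visualization ships with the package, so enrichment output depends
entirely on the supplied GMT.

## Synthetic data: what it emulates, and what it does not

`generate_cetsa_dataset` plants, per protein, vehicle parameters
(midpoint ~ N(50, 4) °C, slope ~ U(0.8, 4), plateau ~ U(0, 0.3)) and, for
a `target_fraction` of proteins (default 10%), a treatment midpoint shift
(default +10 °C, the order of the headline target's shift). Slope and
plateau are shared between arms, so the true ΔTm equals the planted
midpoint shift exactly. Observed intensities are
abundance × f(T) × lognormal noise with unit mean and CV `noise_cv`
(default 5% — reporter noise is approximately multiplicative), abundance
log-normal (log-mean 13.8 ≈ 10^6 counts), with a per-replicate midpoint
wobble of 0.3 °C emulating biological replicate variation; the study
design values are triplicate runs over the ten-temperature gradient.
Optional extras: PSM-level tables (Poisson PSM counts, mean 5) and forward
impurity mixing. The noise magnitudes are this package's defaults for
sensitivity analysis, not measured values.

The generator does **not** emulate: missing channels or missing-at-low-
intensity mechanisms (tables are complete; missingness handling downstream
is drop-with-log), co-isolation interference beyond the linear impurity
model, ratio compression, between-plex batch effects, shared-peptide
protein inference, or abundance-dependent curve quality. Passing the
calibration and power tests therefore demonstrates correctness of the
estimation and calling machinery under the stated noise model — not
performance on real acquisitions, where fit-quality filtering and
normalization carry more weight.

## Problem sizes and numerical conventions

The simulation-based checks use 500 proteins × 2 arms × 3 replicates
(3000 curve fits) for calibration and power, 200 curves for noise-free
recovery, and 50 curves for the exhaustive-oracle comparison — sizes
chosen so the whole validation runs in about a minute on a single core
while keeping the binomial noise on the measured rates well inside the
asserted margins. Determinism conventions: all randomness flows through
`numpy.random.default_rng` seeds recorded in output metadata; grid
tie-breaks are lexicographic; table writers emit a manifest hash in header
comments, and identical configs reproduce outputs byte for byte.

## Known limitations

- Single-plex analysis only: no median/quantile normalization across TMT
  sets, no bridge-channel handling.
- The Boltzmann sigmoid is the only melt model (no biphasic or spline
  alternatives, no area-under-curve scoring).
- The t-test at n = 3 replicates leans on approximate normality of ΔTm;
  the permutation alternative has coarse resolution at that n.
- Isothermal dose-response CETSA designs are out of scope.
- Enrichment results depend entirely on the user-supplied GMT; no pathway
  database is bundled.
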