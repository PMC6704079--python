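# Methods

This note documents the models, conventions and design choices behind
prenylflux: what is simulated, what is assumed, and where the genuinely
open decisions were made.

## Pathway model

The measured pathway is the mevalonate / prenyl-pyrophosphate route of
*S. cerevisiae*: three C2 acetyl units condense into mevalonate (MEV,
C6), which is phosphorylated to mevalonate 5-phosphate (M5P) and
mevalonate 5-pyrophosphate (M5PP); decarboxylative elimination yields
the C5 units isopentenyl / dimethylallyl pyrophosphate (IPP/DMAPP), and
successive head-to-tail condensations build GPP (C10), FPP (C15) and
GGPP (C20). IPP and DMAPP are isobaric, co-elute, and are therefore one
merged kinetic pool and one MS signal; with its 6 isotopologues shared
between two chemical species, the quantifiable signals count
7 + 6 + 11 + 16 + 21 = 61 isotopologues per timepoint (M5P, IPP/DMAPP,
GPP, FPP, GGPP — six metabolic pools behind five signals), 671 over the
11-point sampling grid. MEV and M5PP give low, variable MS signals in
labeling experiments and are excluded from the isotopologue accounting
and half-time comparisons, but remain fully quantifiable in
metabolomics mode.

Pathway topology, formulas (free acids: MEV C6H12O4, M5P C6H13O7P,
M5PP C6H14O10P2, IPP/DMAPP C5H12O7P2, GPP C10H20O7P2, FPP C15H28O7P2,
GGPP C20H36O7P2), CAS numbers and retention times live in a YAML config
(`src/prenylflux/data/pathway.yaml`); validation enforces carbon
conservation per reaction and an acyclic topology. Exact [M−H]⁻ masses
use NIST monoisotopic atomic masses to ≥6 decimals and a proton mass of
1.007276466879 Da (electron mass accounted); only negative-mode
deprotonated ions are supported, matching the acquisition chemistry of
these acidic phosphorylated compounds.

## Labeling simulator

**Model.** The culture is at metabolic steady state (constant pools P_i
and flux f); at t = 0 the glucose feed switches to U-¹³C at purity
0.99. Each pool's mass-isotopologue distribution M_i relaxes toward its
inflow with first-order turnover:

    dM_i/dt = (f / P_i) · (M_inflow − M_i)

Inflows: threefold convolution of the acetyl-unit distribution for MEV;
the upstream pool for linear steps; the uniform random carbon-loss
operator M′_j = M_j(n−j)/n + M_{j+1}(j+1)/n for the decarboxylation;
and the convolution of the two substrate distributions for
condensations. Only mass isotopologues are tracked — positional
isotopomers are out of scope, so the carbon lost in the decarboxylation
is modeled as uniformly chosen.

**State-space convention.** The trajectory lives in the same space the
correction stage reports: the acetyl source carries the tracer purity
after the switch (binomial(2, 0.99)) and the natural-¹³C baseline
before it (binomial(2, 0.0107)), and the measurement layer applies the
exact forward operator that the correction inverts. Three consequences,
each exercised by tests: the t = 0 state is the natural-abundance
binomial for every pool; the long-time enrichment plateau equals the
tracer purity (0.99), so the simulated internal standard shows a
corrected mean enrichment of 99 %; and the zero-noise round trip
through measurement layer + correction is exact to ≤1e-8. An optional
first-order source lag is available but defaults to zero: glycolytic
labeling dynamics are fast relative to this pathway.

**Numerics.** LSODA with rtol 1e-9 / atol 1e-12; states are clipped at
zero and renormalized at reported times (distributions are
probabilities; drift is below integrator tolerance). Proportional
scaling of all pools and the flux leaves every turnover rate f/P_i, and
hence every trajectory, unchanged — the mechanism behind the observed
strain-independence of labeling dynamics when fluxes grow with pools.

**Default parameter set.** Pools (nmol/gDCW, wild type): MEV 2.0,
M5P 1.5, M5PP 1.0, IPP+DMAPP 3.0, GPP 0.8, FPP 1.2, GGPP 1.4. GGPP is
the measured wild-type value; the engineered strains scale all pools
and the flux by the measured GGPP ratios (S037 ×9.14, S023 ×6.07). The
other pools are fixture values in plausible ranges — absolute fluxes
and turnover times are not published, so the wild-type flux
(0.6 nmol/gDCW/min) was chosen once so that the noise-free half-times
span ≈5 min (M5P) to ≈16 min (GGPP), matching the reported 5–20 min
window; these are fixture values, not measured claims.

**Measurement layer.** Each true distribution is pushed through the
forward correction operator, scaled to MS areas via the injected amount
(pool × biomass × resuspension/injection bookkeeping; defaults 5 mL
extraction, 200 µL resuspension, 10 µL injection, 0.01 gDCW,
1000 area/pmol response, ISTD area 5000) and multiplied by per-row
lognormal noise of unit mean and CV `noise_cv` (default ILE 5 %,
quantification 10 %); a fully labeled ISTD area is emitted per
spectrum. What the simulator does **not** emulate: chromatographic
drift, ionization suppression, in-source fragmentation (the <10 %
M5PP→M5P interference is noted but not modeled), extraction losses, or
day-to-day drift. Passing tests therefore demonstrate the correctness
of the computational chain under a realistic noise magnitude, not
robustness to every instrumental artifact of real data.

## Isotopologue correction

High-resolution regime: at R = 70,000 with a 5 ppm extraction window,
non-carbon isotope peaks of these C/H/O/P compounds are resolved away,
so only carbon natural abundance (0.0107) and tracer purity (0.99) are
corrected. The forward matrix column for a species with j tracer
carbons is conv(Binom(j, purity), Binom(n−j, abundance)) — purity is
applied per tracer position (the standard convention; the alternative
"global" reading is not used). Inversion is non-negative least squares
followed by renormalization: noise can drive an unconstrained solution
negative, and NNLS plus renormalization always returns a valid
distribution. The relative residual is reported; a residual above 0.05
warns (model mismatch or heavy noise) but never fails, so pipelines
keep running on noisy spectra.

## Logistic kinetics

Mean enrichment is fitted as a fraction (the model is scale-invariant
for T₅₀, so percent vs. fraction is immaterial; fraction is used
throughout). The model is undefined at y₀ = 0, and a
natural-abundance-corrected series starts at exactly 0, so the
initialization floors y₀ at 1e-4; k starts at the maximum observed
enrichment (capped at 1) and T at the slope of the log-linear early
phase. Bounds: k ∈ (0, 1], y₀ ∈ (1e-6, 1], T ∈ (0, 10] /min; fits are
deterministic given the data. Series with total enrichment change
< 0.05 are flagged degenerate and excluded from half-time comparisons
(mirroring the exclusion of the low-signal pools); fits with y₀ ≥ k are
flagged degenerate as well. A y₀ already above k/2 yields T₅₀ ≤ 0,
returned with a warning rather than clamped. The identity E(T₅₀) = k/2
is verified to 1e-9 on every fit. Loss is unweighted least squares by
default — with n = 2 biological replicates, per-point SD weights are
too unstable to be the default, but weights can be supplied.

## IDMS quantification and validation

The ¹²C/¹³C ratio of a spectrum is the total analyte area over the
internal-standard area; because the ISTD co-elutes, any common response
perturbation cancels (tested). Calibration lines are fitted on
per-level replicate-mean ratios with 1/x² weighting by default. Both
choices are deliberate: level means keep the slope insensitive to
unbalanced replication, and with multiplicative detector noise over a
500-fold amount range, unweighted OLS lets the top levels displace the
intercept by more than the smallest cellular samples (sub-pmol on
column), which breaks their accuracy — 1/x² weighting is the standard
bioanalytical remedy and is what makes the validated RSD < 20 %
achievable at CV 10 % noise. Unweighted and 1/x fits remain available.

Validation follows the ±20 % rule: a contiguous span of levels is
acceptable when, refit on the span alone, every level back-calculates
with |bias| ≤ 20 % and RSD ≤ 20 % and the span is linear
(R² ≥ 0.99 on level means — without the linearity gate a bent line can
absorb detector saturation). The range is anchored at the lowest
workable level and extended upward (built up from the LOQ), must hold
≥5 levels, and the LOQ is its lowest level; LOD = 3σ/slope with σ from
blank replicates when supplied, else from the lowest calibration level
(the Eurachem-compatible convention; the guideline names no formula).
The synthetic calibration generator is linear to 50 pmol and compressed
above (saturation), with an additive blank floor, so the validated
upper bound lands at 50 pmol and levels below ~3×blank/response drop
out. Concentrations are amount-on-column × (resuspension/injection) /
biomass; ratios outside the validated range are flagged with a warning,
not rejected.

## Strain comparison and flux ratios

Welch's two-sided t test with fractional Welch–Satterthwaite degrees of
freedom (no integer rounding — required to reproduce p-values computed
from printed summaries). No multiple-testing correction is applied: raw
per-metabolite p-values are reported, matching how such panels are
usually presented. Under constant turnover the flux ratio equals the
pool ratio; its SD uses the first-order delta method with independent
group SDs, and a parametric bootstrap is provided as an alternative
estimator (ratio SDs from printed summaries are not uniquely
recoverable, so both are offered). A turnover-adjusted mode
((mean/T₅₀)/(mean/T₅₀)) covers the case where half-times do differ.

## Pipeline and I/O

All tables are UTF-8 CSV with '.' decimals; floats are written with
%.17g and read with round-trip precision, so write→read preserves every
value exactly. Output files carry provenance header lines (package
version, seed, SHA-256 of the scientific config — the output directory
is excluded from the hash so reruns in different locations stay
byte-identical). All randomness derives from a single run seed through
named SeedSequence children; a rerun with the same config and seed
reproduces every output byte for byte. Raw mzML parsing is explicitly
out of scope: the pipeline begins at integrated peak intensities.

## Problem sizes

Defaults were chosen so a full three-strain run (simulation,
correction of ~1500 spectra, ~30 logistic fits, 8 calibrations,
quantification and comparisons) completes in seconds on one core; the
validation script uses 24 seeded replicate sets of 3 replicates for the
precision figure and a single noise-free steady-state simulation for
the enrichment figure.

## Known limitations

* Mass isotopologues only; no positional isotopomer bookkeeping.
* Only the [M−H]⁻ adduct; no multi-element correction (would be needed
  for N/S-containing compounds or low-resolution data).
* The constant-turnover flux ratio is relative, not absolute; absolute
  flux estimation would require instationary ¹³C flux models, which are
  deliberately out of scope.
* The simulator's noise model is multiplicative lognormal plus a blank
  floor; correlated (batch, drift) error structures are not emulated.
* With n = 2 replicate half-times per strain, the Welch test on T₅₀ has
  low power; "not significant" there is weak evidence by construction.
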