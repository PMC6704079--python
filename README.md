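# prenylflux

Quantitative metabolomics and ¹³C isotopologue profiling of isoprenoid
precursors — the mevalonate and prenyl-pyrophosphate intermediates MEV,
M5P, M5PP, IPP/DMAPP, GPP, FPP and GGPP of *Saccharomyces cerevisiae* —
implemented as a tested, reusable Python pipeline.

The package is aimed at metabolomics and fluxomics practitioners who
work from integrated LC–HRMS peak intensities (vendor-export CSVs) and
need the complete downstream chain: correction of measured mass
fractions for natural isotope abundance and tracer purity, mean
¹³C-enrichment, logistic labeling kinetics with half-times, absolute
quantification by isotope dilution mass spectrometry (IDMS) with
Eurachem-style method validation, and turnover-based relative flux
comparison between strains. A first-class synthetic-data module
simulates an instationary ¹³C labeling experiment (switch to
U-¹³C-glucose at 99 % isotopic purity, sampling at
0–120 min) with a realistic measurement layer, so every stage is
testable against known ground truth.

## The models at the core

**Isotopologue correction.** For a compound with *n* carbons the
measured mass-fraction vector mixes the biological signal with natural
¹³C on non-tracer carbons (abundance *a* = 0.0107) and the finite
isotopic purity *p* = 0.99 of the tracer. The forward operator has
columns `conv(Binom(j, p), Binom(n−j, a))` for the species with *j*
tracer carbons; correction inverts it under non-negativity.

**Mean enrichment.** `E = (Σᵢ i·Mᵢ)/n`, the average fraction of carbon
positions occupied by ¹³C.

**Labeling kinetics.** Enrichment time courses are fitted with the
logistic model

```
E(t) = k·y₀·e^(t·T) / (k + y₀·e^(t·T) − y₀)
T₅₀  = (1/T)·ln((k − y₀)/y₀)
```

with plateau *k*, initial enrichment *y₀* and rate *T*; `E(T₅₀) = k/2`
holds exactly. T₅₀ is the time needed to exchange half of a pool's ¹²C.

**IDMS quantification.** Amounts come from the ¹²C/¹³C area ratio
against a fully ¹³C-labeled internal standard through a weighted
calibration line, validated with the ±20 % accuracy/precision rule
(LOD, LOQ, linear range).

**Flux inference.** A pool with size *P* and flux *f* exchanges label
with turnover *f/P*; when half-times do not differ between strains
(constant turnover), the relative flux change equals the pool-size
ratio, with delta-method uncertainty.

**Labeling simulator.** Each pool obeys
`dMᵢ/dt = (f/Pᵢ)·(M_inflow − Mᵢ)` where inflows are the threefold
acetyl-unit convolution (MEV), the upstream pool (linear steps), a
random carbon-loss operator (decarboxylation to IPP/DMAPP) or the
convolution of both substrates (prenyl condensations).

## Worked example

```python
from prenylflux.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(outdir="demo_run", rng_seed=1))
print(result.concentrations.query("metabolite == 'GGPP'"))
```

This simulates labeling and quantification experiments for the wild
type and two engineered strains (S037 and S023, pools anchored on the
measured GGPP concentrations), corrects all spectra, fits kinetics and
quantifies every compound. The GGPP rows of `concentrations.csv` read
(seed 1):

```
strain  concentration_nmol_gdcw  sd_nmol_gdcw  n_replicates  true_nmol_gdcw
WT                        1.52          0.16             3             1.4
S037                     12.50          1.67             3            12.8
S023                      9.01          1.25             3             8.5
```

i.e. all three pools are recovered well within the validated RSD < 20 %.
The strain comparison (`comparisons.csv`) gives a GGPP flux increase of
8.2 ± 1.4 for S037 vs. WT (Welch p = 0.007) under constant turnover,
and the fitted wild-type half-times (`fits.csv`) follow the pathway
order M5P → IPP/DMAPP → GPP → FPP → GGPP (4.8, 11.7, 12.6, 14.1,
15.7 min), with plateau enrichments near the 99 % tracer purity. The
same stages are exposed on the command line
(`prenylflux simulate|correct|fit-kinetics|quantify|run`).

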