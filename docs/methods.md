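# Methods

This note documents the models, parameter choices and numerical behaviour
of the package, and what the synthetic-data generators do and do not
emulate.

## Units, censoring and the bundled tables

All gas concentrations are stored internally in μmol/mol. Field tables
conventionally report major species (CO2, N2, O2, Ar, H2S) in mmol/mol and
trace hydrocarbons (CH4, C2H6) in μmol/mol, so readers require an explicit
per-column unit declaration and refuse to guess. Unit conversion on read
shifts the decimal representation exactly (via `decimal.Decimal`), which is
why the bundled gas table survives a read → write round trip byte-for-byte.

Below-detection cells (`<0.5`) are stored as detection limits, never as
numbers. Every downstream consumer must choose a substitution policy:
`half` (limit/2, the default and the standard censoring convention),
`zero`, or `limit`. A closure sanity check verifies that major species sum
to 900–1050 mmol/mol per sample.

The bundled tables are the survey's printed soil-gas compositions (five
depth profiles plus the bubbling-pool free gas), the soil pH/HCl/C/N
table (11 horizons over six sites), and the published top-10 SIMPER
contributions. The element table is **synthetic** (the survey's element
data are unpublished): it is constructed to reproduce the reported
relative-change structure of the toe-slope site versus the mean of the two
reference sites (Ca −93%, total P +604%, K +113%) and is labelled as such.

## End-member mixing

The forward model is linear: `c(f) = f·deep + (1−f)·air`, one global `f`
per sample. The air end member defaults to the standard dry atmosphere
(N2 780.9, O2 209.5, Ar 9.34, CO2 0.41 mmol/mol; CH4 1.9 μmol/mol; C2H6
and H2S 0) with δ13C-CO2 = −8.0 ‰; all values are overridable, since a
site's actual air CO2 inside a CO2 lake can differ.

Inversion from a single tracer is the exact quotient
`f = (obs − air)/(deep − air)`, clipped to [0, 1] with an explicit
`clipped` flag (measurement noise legitimately pushes rim samples slightly
negative). A species-set inversion minimises `Σ w_s (obs_s − c_s(f))²`
with default weights `1/air_s` (falling back to `1/deep_s` for species
absent from air). A 10⁴-point grid search is kept in the package as the
independence check for the closed form; it is used by tests, never by the
analysis path.

Ar is the default tracer because it is the only reported species with no
plausible source or sink in these soils; CO2 is the documented fallback
for samples where Ar is near or above the atmospheric value (rim and
back-slope profiles), where the Ar-anchored fraction clips to zero.

### Process anomalies

The relative anomaly of a diagnostic species is
`(obs − pred)/pred` at the fitted `f`; a flag is raised beyond a
threshold with the diagnostic sign (excess for N2 and CO2, depletion for
CH4 and O2). Two details matter:

* **Anchor tracers.** `classify_sample` judges each diagnostic species at
  the fraction implied by a different, anchored tracer — N2 at the
  sample's CO2; CO2, CH4 and O2 at the sample's N2 — mirroring how
  deviations are read off binary mixing diagrams (a point above the curve
  in the N2-vs-CO2 plane is "N2 in excess at its CO2"). A single
  Ar-anchored fit cannot reproduce the field pattern: rim profiles carry
  Ar at or above air, clip to f = 0, and then every species looks
  anomalous.
* **Threshold.** The default relative cutoff is 0.05. The N2 excess of
  the back-slope profiles peaks near +7% relative to the mixing line —
  a real, systematic offset produced by O2 consumption — so a 10% cutoff
  would miss a process the data clearly show, while 5% still sits well
  above the analytical scatter of the major-species measurements.

Ratio-diagram coordinates (Ar/CH4 vs CO2/N2) are computed in consistent
units by default; an as-printed mode (Ar in mmol/mol over CH4 in
μmol/mol) is available because published diagrams sometimes mix the two.

## Isotopes

Mixtures use concentration-weighted mass balance on 13C, not linear δ
averaging; with CO2 concentrations differing by ~2400× between the deep
gas and air, mixtures are deep-dominated at almost any f. The Rayleigh
calculation defaults to the linearized form `δ = δ0 + ε ln F` with the
exact α-form behind `exact=True`; for |ε| ≤ 30 ‰ and moderate consumption
the two differ by a few tenths of a per mil in δ (≈1–2% in F), comparable
to field δ13C-CH4 precision. The enrichment factor ε has **no default**:
it is strongly site- and community-dependent, the survey supplies none,
and any fraction-remaining estimate is exploratory and scales with the
assumed ε. F > 1 (a δ shift on the wrong side of δ0) is returned with a
`non_physical` flag rather than an error.

## Incubation kinetics

Analytes are tracked as cumulative amounts (μmol), not concentrations,
which absorbs the replacement of liquid removed for sampling. Headspace
fractions convert by the ideal gas law (R = 0.0820574 L·atm/(mol·K));
dissolved CO2/carbonate speciation is deliberately ignored (no correction
is part of the emulated protocol); a Henry's-law hook would slot into
`read_incubation_table` if ever needed.

Feeding cycles are half-open: a re-spike at day r ends the running cycle
just before r, and the first observation at or after r (which carries the
fresh H2 dose) opens the next one, so concatenated segments reproduce the
series exactly. H2 consumption is summed per cycle as start-minus-end.

The maximum specific rate is the largest OLS slope over every run of
`window_points` consecutive observations, divided by dry mass. The
default window is 3 points: it is exact on noiseless piecewise-linear
data and tracks the steep phase. Because the estimator takes a maximum
over windows, short windows under measurement noise are upward-biased;
for noisy series the window should cover the consumption phase (the
recovery analyses here use 8-point windows over a 9-point consumption
phase, giving ~6% median error at 5% noise). Dry mass is a required
input; the emulated protocol reports ~10 g wet soil per bottle, and the
generator default of 8 g dry corresponds to 20% moisture (configurable).

Electron yields use the fixed factors 8 eq/mol (acetate), 8 eq/mol (CH4),
2 eq/mol (H2): `yield% = 100·8·product/(2·H2)`. Unaccounted equivalents
are reported as a residual and never attributed to a process. Yields are
pooled over the whole incubation by default; per-cycle yields follow from
applying the same balance to each segment.

## Community statistics

Rarefaction draws a multivariate hypergeometric sample (subsampling reads
without replacement) per sample; Bray-Curtis and everything downstream
run on the rarefied counts by default (a proportion mode exists for
SIMPER). PERMANOVA partitions `SS_total = Σ_{i<j} d²_ij / n` into within-
and between-group parts and uses
`F = (SS_B/(a−1)) / (SS_W/(n−a))`. The p-value enumerates all distinct
label arrangements when there are no more of them than the requested
permutation count (then p is exact: the share of arrangements with
F ≥ F_obs); otherwise it Monte-Carlo samples with the +1 correction,
`p = (1 + hits)/(1 + n_perm)`, so p ≥ 1/(n_perm + 1) and the type-I error
at α is `⌊α(n_perm+1)⌋/(n_perm+1)`. A seed makes p bit-reproducible. All
samples identical is degenerate: F = 0, p = 1.

SIMPER computes per-OTU contributions as the mean over between-group
sample pairs of `|x_ij − x_ik| / Σ_s (x_sj + x_sk)`; contributions sum to
the mean between-group Bray-Curtis dissimilarity by construction (tested
to 1e-12). Ranking sorts by percent contribution descending with ties
broken lexicographically by OTU id for determinism. When accumulating a
*printed* (2-decimal) contribution column, the running total can differ
from a published cumulative column by one rounding ulp from rank 4 or so
onward — the published cumulative reflects unrounded contributions.

Agreement with scikit-bio (Bray-Curtis matrices to 1e-9, PERMANOVA
pseudo-F to machine precision) is asserted in the test suite; scikit-bio
is an oracle there, never the implementation.

## Synthetic data

* **Gas profiles**: mixing prediction at a true f per depth, times
  per-species process perturbation factors, times mean-preserving
  multiplicative lognormal noise (positivity); values falling below the
  field detection limits (O2 0.5 and H2S 0.05 mmol/mol, traces
  0.1 μmol/mol) are emitted censored.
* **Incubations**: linear H2 drawdown sized so the chosen electron yields
  hold exactly (acetate = y_ac·ΔH2/4, CH4 = y_ch4·ΔH2/4), a fresh dose
  per cycle (default 1963 μmol = 60% of an 80 mL headspace at 298 K),
  dense sampling during consumption plus an end-of-cycle point, and
  additive Gaussian noise proportional to the signal. A zero dose gives a
  control bottle with a flat baseline.
* **OTU tables**: a shared lognormal rank-abundance pool; per-group
  support restricted to the nominal richness (the low-richness group's
  support nests inside the high-richness group's where possible);
  a designated OTU subset shifted by a natural-log fold effect in the HC
  base composition; per-sample Dirichlet draws at concentration 200
  (single overdispersion parameter) and multinomial counts at fixed
  depth.

Everything is deterministic given (parameters, seed), and truths are
serialized alongside the data.

What the generators do **not** emulate: transport and diffusion in the
soil column (gas noise is uncorrelated across depths and species),
microbial growth dynamics (no lag or Monod phase; rates are piecewise
constant), compositional correlation structure between specific taxa, and
sequencing artefacts (chimeras, contamination, variable library size).
Recovery tests passing on synthetic data therefore demonstrate estimator
correctness under the stated error models, not robustness to every field
complication. Note also that with strong Dirichlet overdispersion the
*observed* richness at finite depth sits well below the nominal support
size; group contrasts, not absolute richness values, are the meaningful
output.

## Problem sizes and reproducibility

Analyses of the bundled tables are instantaneous. The calibration suites
use 500 incubation replicates,
null PERMANOVA simulations (2000 in both the test suite and the acceptance script) with 10 samples × 30 OTUs at 199 permutations,
and study-sized OTU simulations with 13 samples; the full test suite runs
in well under a minute. All randomness flows through explicit integer
seeds; derived seeds stay below 2³¹.
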