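# Methods

## Size distributions from DLS summaries

A DLS instrument reports a mean hydrodynamic diameter and a polydispersity
index (PDI); the encapsulation model needs a radius distribution. We treat
the pair as describing a number-weighted log-normal radius law with

- arithmetic mean radius = mean diameter / 2,
- squared coefficient of variation CV² = PDI,

so σ² = ln(1 + PDI) and μ = ln(mean radius) − σ²/2 via the log-normal
moment identities. Whether a given instrument's size is intensity-weighted
(Z-average) or number-weighted is a genuine ambiguity of DLS summaries; we
adopt the number-weighted reading as the simplest convention consistent
with a log-normal size assumption, and note that converting
intensity-weighted data properly would require Mie theory, which is out of
scope. PDI = 0 is allowed as an explicit monodisperse case (one grid point),
which doubles as the closed-form oracle for tests.

Discretization: the normal density of ln r is integrated over `n_points`
equal cells spanning μ ± `span`·σ (defaults 1000 and 5), cell centres are
exponentiated to radii, and weights are renormalized after truncation.
At span 5 the truncated mass is < 1e-6 for any PDI < 0.5; tests assert the
grid reproduces the requested mean and CV² within 0.5% and that doubling
`n_points` moves downstream TEE by < 0.1%.

## Geometric TEE model

Each vesicle is a sphere of outer radius r bounded by one bilayer of
thickness d; its two leaflets (radii r and r − d) are tiled at area a per
lipid, so it consumes 4π(r² + (r−d)²)/a lipids and encloses a lumen of
(4/3)π(r−d)³. Averaging both over the radius distribution, the lipid
budget c·V·N_A fixes the vesicle count and the expected lumen volume fixes
the encapsulated fraction. The dispersion volume V cancels analytically;
an invariance test holds the result to 1e-12 across V ∈ {0.1, 1, 10} mL.
TEE is exactly linear in c until the (unphysical) 100% cap, which is
enforced with a warning rather than an error.

Defaults: d = 4.8 nm (DPPC bilayer), a = 0.43 nm² (DPPC/cholesterol 1:1
monolayer), N_A = 6.02e23. Vesicles with r ≤ d keep their lipid demand
(outer leaflet only) but contribute zero lumen — clamping rather than
excluding them keeps the weights normalized; for realistic distributions
(mean radius ≫ d) the effect is negligible. Unit chain: radii in nm,
1 L = 1e24 nm³, c in mM → mol/L via 1e-3, all centralized in
`constants.py`.

Condition-level TEE converts the post-mixing mass concentration
ILC/(1 + FRR) (mg/mL) to mM through the mixture's mole-fraction-weighted
molar mass. The default composition is DPPC : cholesterol : DHSG :
PEG(5000)-DSPE at 5 : 5 : 1 : 0.066 with molar masses 734.04, 386.65,
696.0 and 5801 g/mol (the PEG-lipid mass is a nominal conjugate value);
every component is overridable since vendor lots differ.

## Measured metrics and calibration

LRR, loading and EE are ratio definitions (see README). Design points:

- Calibration curves are linear with a fitted intercept (ordinary least
  squares on a concentration/intensity table); the dilution applied before
  a plate read (e.g. 100 µL sample into 900 µL ethanol → 10×) is an
  explicit `dilution_factor` argument, never a hidden constant.
- LRR > 100% is reported as-is; recovery estimates above 100% are ordinary
  measurement noise in this assay and clipping them would bias averages.
- Readings below the calibration blank floor the concentration at zero
  with a warning.
- EE algebra: EE% = 100·[calcein]_pp·[lipid]_dev/([lipid]_pp·[calcein]_MS);
  a test holds this refactoring to 1e-12 against the loading-based form,
  and scale invariance of LRR/EE under global concentration rescaling is
  property-tested.

## Lamellarity

The TNS slope ratio assumes every bilayer of a multilamellar vesicle holds
as many lipids as the outermost one, so accessible surface per lipid
scales as 1/lamellarity. That assumption conflates concentric
multilamellar and multivesicular geometries — both depress the slope, and
the method cannot distinguish them. The regression fits a free intercept:
background fluorescence shifts titration lines but must not bias slopes.
Sub-unity lamellarities can occur (a sample with more accessible surface
per lipid than the sonicated standard, e.g. smaller vesicles) and are
reported, not clipped.

## Hydrodynamics and summaries

Linear velocity = TFR / cross-section with plain unit conversion. The
static-mixer channel is 1 mm circular (≈ 3.18 cm/s at 1500 µL/min); the
herringbone micromixer cross-section is represented through the "50×
smaller than the SM" relation (≈ 159 cm/s) and is overridable — exact
microchannel dimensions vary by vendor, so velocities derived from the
ratio are order-of-magnitude descriptors, not exact recomputations.
Cross-device summaries use unweighted means over matched conditions
(mean per ILC, then mean of means), which makes them invariant to row
order; unmatched conditions are skipped with a warning.

## Correlation screening

Pairwise-complete Pearson r with t = r·√(n−2)/√(1−r²) and two-sided
p-values from Student's t (n−2 df); stars at 0.05/0.01/0.001; no
multiple-testing correction, because the screen is exploratory flagging
(|r| ≥ 0.5), not inference. The device label enters the pooled matrix
coded 1 (SHM) / 2 (SM) — a point-biserial-style treatment. Both pooled and
per-device matrices are exposed: pooling answers "what does switching
devices do" (device–size, device–PDI), while within-device couplings such
as ILC–size are diluted in the pooled matrix by the large between-device
size offset, so they are screened per device. An independent permutation
test (10⁴ shuffles) backs the analytic p-values in the test suite.

## Synthetic campaign generator

The generator is phenomenological by design: it emulates the statistical
structure of a two-device formulation study, not self-assembly physics.

Forward model per condition (device, TFR, FRR, ILC):

1. True mean diameter, PDI: linear trends in ILC (and TFR for size) plus
   relative Gaussian noise. Trend coefficients are anchored to observed
   two-device behaviour — SHM ≈ 91→131 nm and PDI 0.074→0.224 over ILC
   15→90 mg/mL; SM ≈ 175→286 nm at PDI ≈ 0.07 with a weak negative TFR
   slope — linear forms being the simplest shapes consistent with the
   reported monotone trends.
2. True lamellarity λ: linear in ILC, floored at 0.5 (SM ≈ 1.7→11.9,
   SHM ≈ 0.93→1.3 over the same ILC range).
3. TEE from the geometric model on the true distribution; true
   EE = shortfall · TEE / λ, with mixing-shortfall 0.7 ∈ (0, 1]
   representing incomplete marker mixing at the moment of vesicle closure.
   Configs implying EE > 100% are rejected.
4. Concentration chain: MS reference from ILC/FRR and a 1 mM calcein
   stock; device-stage lipid via a recovery draw (mean 0.90, SD 0.08,
   clipped); purification changes lipid concentration by a fixed factor
   0.8; post-purification calcein = encapsulated portion + unencapsulated
   feed diluted by the ultrafiltration factor (default 1000×). The
   ground-truth table records both the model EE and the "apparent" EE a
   noise-free measurement chain would report (carry-over bias included) —
   recovery tests target the latter, since the carry-over is part of the
   measurement being emulated.
5. Fluorescence: linear channel maps with multiplicative log-normal noise
   (default 2% relative, matching the titration noise level used in the
   recovery studies; true instrument noise magnitudes are unreported, so
   these defaults are recovery-test settings, not instrument estimates).
   Channel gains are chosen so the faintest sample sits ≥ ~3× above the
   blank, as an assay designed for this concentration range would be.
6. TNS titrations: five points with slope standard/λ plus background and
   2% noise; an unbiased unilamellar STANDARD titration is always emitted.

One seeded generator stream drives everything; identical seeds give
bit-identical tables. The default campaign covers 2 devices × 5 flow
settings (TFR 1500/2000/2500 at FRR 3; FRR 4/5 at TFR 1500) × ILC
15/30/45/60/90 mg/mL = 50 samples — the factorial actually exercised in
such studies rather than the full 2×3×3×5 cross.

What passing recovery tests show: the analysis chain inverts the
generator's forward model within propagated noise. What they do not show:
robustness to non-log-normal size distributions, inner-filter or quenching
effects, lipid losses correlated with condition, or multimodal
populations — none of which the generator emulates.

## Numerical and testing choices

- Recovery criteria: lamellarity within 10% of truth (5-point titrations,
  2% noise, 100 replicates per λ); end-to-end EE within 3 propagated SDs
  for ≥ 95% of samples, where the per-sample SD propagates the relative
  fluorescence noise through the three concentration reads including each
  read's signal/(signal − blank) inflation.
- Worked-example tolerances for slope-ratio lamellarities are ±0.1
  absolute (±0.15 where the published values were computed from slopes
  carrying one more digit than printed).
- CSV output uses 10-significant-digit formatting, a write→read→write
  fixed point asserted byte-for-byte in tests.
- Desk-scale problem sizes throughout (50-sample campaigns, 100-replicate
  recovery loops, 10⁴-shuffle permutation oracle); the full suite runs in
  a few seconds.

## Known limitations

- The mean/PDI → log-normal map ignores intensity weighting (above).
- The TEE model has no multilamellar extension; lamellarity enters only
  through the synthetic generator's EE suppression, mirroring how the
  EE–TEE gap is interpreted, not mechanistically.
- No ethanol-entrapment correction: entrapped solvent lowering the inner
  marker concentration is folded into the single mixing-shortfall factor.
- The correlation screen treats the 1/2 device coding as linear, which is
  only meaningful for two devices.
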