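# Methods

## The chiral-balance model

Circular dichroism measures the differential absorbance of left- vs
right-circularly polarized light, ΔA = (ε_L − ε_D)·c·l. For a pair of
enantiomers the anisotropies are equal and opposite, so a mixture's signal
is additive and depends only on the chiral imbalance:

    I = K (c_L − c_D) + b,      K = (ε_L − ε_D) l.

Concentrations are carried as **mass fractions (mg/g)** rather than molar
concentrations: enantiomers share a molar mass, so the molar-to-mass
conversion is a constant that `K` absorbs, and all reported results are in
mg/g or g/g. `K` is never decomposed into ε_L, ε_D and l at runtime; only
the lumped sensitivity (and the offset `b`) are observable, and bracket
calibration never even needs `K` explicitly.

Three inverses are implemented:

* **direct titration** — known D-form amounts are added to sample aliquots
  and an ordinary least-squares line of I against c_D is fitted over *all*
  points (not just the two sign-bracketing ones — the data are few and
  exactly linear under the model, so OLS uses them all); the root of the
  line estimates c_L. An instrument offset b biases this estimate by
  exactly b/K, which is tested as an analytic identity.
* **single-point calibration** — c_L = (I/I_STD)(c_LSTD − c_D1) + c_D2;
  exact only for b = 0.
* **bracket calibration** — linear interpolation between a lower and a
  higher standard; the offset cancels algebraically, so the bracket is an
  exact inverse for any b. The implied (K, b) of the two-point fit is
  exposed separately (`bracket_detector`).

Solvers act on a single intensity (or peak area). How replicates are
combined is a caller decision: the pipelines average the *standards'*
replicate intensities (they anchor the calibration) and quantify each
*sample* replicate individually, so that per-replicate scatter survives
into the RSD. Averaging per-replicate concentrations instead is possible
through the same API and is algebraically identical for the bracket, which
is linear in I.

## Chromatography

Simulated peaks are Gaussian in time; real peak asymmetry (tailing) is not
modeled. Integration draws a straight baseline between the window
endpoints, subtracts it, and applies the trapezoidal rule — making the
area exactly invariant to any linear drift added inside the window (a
property test asserts this to 1e−9 relative). Peak windows are
user-specified by retention time, matching manual practice; a naive
local-maximum detector (5× baseline noise) exists only as a convenience
for the simulator's known layouts. Resolution uses the half-height
convention Rs = 1.18·Δt/(w_h1 + w_h2), appropriate for sharp, well-resolved
peaks; the enantiopurity ratio is 100·area_minor/area_major (minor/total
agrees to the printed 3-decimal rounding and the simpler convention is
fixed). Reported purity is rounded to 3 decimals in %, per-replicate mass
fractions to 4 decimals, grid means to 3 — rounding happens only at report
boundaries.

## Protein conversion

`c_protein = c_L·M_protein·M·m/(m_sample·n_Phe·M_Phe·m_solid)`, with c_L
converted from mg/g to g/g so the result is a g/g purity. Molar masses are
**average** (not monoisotopic) masses — the context is bulk material —
computed with Biopython from the one-letter sequences as residue masses
plus one water per chain, minus two hydrogens per declared disulfide bond.
For porcine insulin (two chains, three disulfides) this gives
5777.5 g/mol and n_Phe = 3; free phenylalanine is 165.19 g/mol. Hydrolysis
losses and racemization of liberated L-Phe are not modeled by default
(`recovery = 1.0`, `racemization = 0.0`); both factors are exposed because
acid hydrolysis must be characterised before the conversion can be trusted
on a new protein.

In the achiral hydrolysate separation the L- and D-Phe co-elute, so the
integrated CD peak area plays the role of I and is proportional to
K(c_L − c_D); the bracket algebra applies unchanged to areas.

## The simulator

The synthetic-data module emulates the validation experiments:

* **gravimetric series** — nominal levels perturbed by independent normal
  weighing errors with relative SD 0.01 mg/√3/200 mg ≈ 2.9e−5 (balance
  readability treated as a rectangular distribution on a ~200 mg aliquot);
  the perturbed value is the gravimetric truth the analyst reads off the
  balance, so weighing noise adds scatter, not bias. Fixed mode sets every
  c_D to 0.05 mg/g; variable mode matches c_D to c_L within a ±2 % uniform
  tolerance.
* **CD readings** — additive Gaussian noise, SD = σ/√(DIT/1 s): doubling
  the digital integration time improves S/N by √2, which is verified
  empirically. Defaults K = 200 signal units/(mg/g), b = 0, σ = 0.3 at
  1 s, DIT = 32 s; these place the simulated LOD (3·noise/K) at
  0.8 µg/g — the low-µg/g order the real instrument achieves. For the
  performance study the noise is instead specified *relative* to the true
  signal (default 0.5 %), which is the regime the sub-1 % bias/RSD claim
  refers to.
* **chromatograms** — Gaussian-peak sums per channel plus linear baseline
  drift and point noise; CD peaks signed L-positive (configurable), CD
  area = K(c_L − c_D), DAD area achiral (∝ c_L + c_D). No retention-time
  chemistry is modeled; apex positions are configuration.
* Default bracket standards sit at ±10 % of the expected sample imbalance,
  sharing the sample's internal-standard level — a symmetric bracket.

All randomness flows from one seed; identical seeds reproduce outputs
byte-for-byte. What the simulator does **not** contain: peak tailing and
co-elution interference, detector drift within a run beyond linear
baseline, hydrolysis side reactions, weighing covariances. Passing tests
therefore demonstrate the correctness of the estimators under the model's
own assumptions, not the field performance of an instrument.

## Statistics

* RSD uses the n−1 sample SD (the convention is not universal; it is fixed
  and documented here). Bias is 100·(mean − truth)/truth.
* LOD/LOQ = 3× and 10× the baseline noise divided by sensitivity; the
  "noise signal" is operationalized as the SD of a detrended 1-min blank
  region of the CD trace.
* Uncertainty propagation: first-order GUM with central-difference
  sensitivities (relative step 1e−6), uncorrelated inputs; a seeded
  Monte-Carlo mode (default 100 000 draws) cross-checks the Taylor result
  and agrees within Monte-Carlo error for the smooth, mildly nonlinear
  conversion equation. Input correlations are out of scope.
* En = |x_a − x_b|/√(U_a² + U_b²) on expanded (k = 2) uncertainties;
  En < 1 means agreement. Note: recomputing the published insulin
  comparison from its own inputs (0.922 ± 0.035 vs 0.892 ± 0.036 g/g)
  gives En = 0.597, not the 0.80 quoted alongside those numbers; this
  package always reports the recomputed value.
* Intra/inter-day precision: per-group RSDs plus the RSD of all values
  pooled, and the RSD of group means as a separate between-group figure.

## Problem sizes

The shipped study uses 6 concentration levels × 6 replicates for the
performance table, 200 runs for the noisy end-to-end recovery check,
10 000 draws for empirical noise-scaling checks and 20 000–100 000 draws
for Monte-Carlo propagation; chromatograms are sampled at 5–20 ms
equivalents over 10 min. These sizes make every statistical check stable
at the asserted tolerances while the whole suite runs in seconds.

## Known limitations

Single-wavelength CD only (no spectra, no secondary-structure analysis);
no vendor file formats; no modeling of mobile-phase chemistry or
hydrolysis kinetics; the printed-value fixtures cover the reporting paths,
not the instrument physics behind them.
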