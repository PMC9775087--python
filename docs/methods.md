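# Methods

This note records the models implemented in `synbind`, the assumptions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Log-normal spectral analysis (`synbind.spectra`)

Single-fluorophore emission bands are modelled as log-normal on the
wavenumber axis, ν = 10⁷/λ(nm) in cm⁻¹:

I(ν) = I_m · exp(−(ln2/ln²ρ)·ln²((a−ν)/(a−ν_m))) for ν < a, and exactly 0 at
ν ≥ a, with a = ν_m + Hρ/(ρ²−1).

* **Sign convention.** ν₊ denotes the blue-side (high-wavenumber) half-maximum
  and ν₋ the red-side one, with ρ = (ν_m−ν₋)/(ν₊−ν_m). For red-skewed
  emission this gives ρ > 1 and places the limiting point a above ν_m. The
  convention is self-consistent: the half-maximum positions of I(ν) recovered
  by root finding satisfy ν₊−ν₋ = H and the ρ ratio exactly (asserted in the
  tests).
* **Fitting.** Trust-region least squares over (I_m, ν_m, ρ, H) with a
  recomputed from the closed form. Initialisation: ν_m and I_m at the grid
  argmax, ρ = 1.3, H from a crude half-maximum scan; bounds ρ ∈ (1, 3],
  H > 0. These are robust on the coarse 10 nm acquisition grid (300–500 nm),
  whose very coarseness is the reason a lineshape model is needed at all.
  Degenerate spectra (fewer than 5 positive points) are rejected;
  non-convergence is reported via a flag, not silently.
* **Heterogeneity observables.** λ_max = 10⁷/ν_m and the FWHM on the
  wavelength axis, 10⁷/ν₋ − 10⁷/ν₊. The empirical reference line for free
  tryptophan in solvents of graded hydrophobicity is *user configuration*:
  it is published calibration data and is never synthesised here.
* **Free/bound decomposition.** Titration spectra are modelled as
  c_f·free + c_b·bound with c_f, c_b ≥ 0 and c_f + c_b = 1 (matched protein
  concentrations justify the closed simplex, and the constraint stops
  intensity-scale drift from masquerading as binding). On the simplex the
  quadratic programme is one-dimensional, and the exact solution is the
  unconstrained minimiser clamped to [0, 1]; no QP library is needed. For
  variants that never saturate, a saturated reference from another variant
  may be substituted (a per-variant configuration choice, mirrored by the
  generator).
* Spectra are assumed lipid-blank-subtracted upstream; the CSV reader makes
  no inner-filter or scattering corrections.

## Binding isotherm and residue profiles (`synbind.binding`)

Bound fraction from the quadratic bimolecular model with site concentration
S = B_max·[lipid]:

f_b = ((P+S+K_d) − sqrt((P+S+K_d)² − 4PS)) / 2P.

The discriminant is analytically nonnegative and numerically clamped at 0.

* **B_max fixed by default** at 1/59 sites per lipid — the value obtained for
  the wild-type protein from NMR intensity ratios in the saturating regime
  (see below) — rather than co-fitted; co-fitting K_d and B_max from a single
  titration is poorly conditioned. Co-fitting is available behind
  `Bmax="fit"`.
* **K_d is optimised in log10 space** (affinities span four decades across
  variants); the SEM is the square root of the covariance diagonal from the
  Jacobian at the optimum, delta-transformed to the linear scale; the
  p-value is a two-sided t-test of the K_d term with n−p degrees of freedom.
  Unweighted least squares by default.
* **Titration grid.** The union of twofold dilution ladders from decade
  anchors 10, 1, 0.1 and 0.01 mM down to the next anchor (16 points,
  1.25 µM–10 mM). The fit uses whatever grid the caller supplies.
* **Non-saturation flag.** Curves whose maximum bound fraction stays below
  0.9 are flagged `saturating=False` (the weakest-binding double mutant
  behaves this way at 10 mM lipid); the fit is still returned.
* **Lipids per site.** In the saturating regime every site is occupied, so
  bound protein = site concentration. The bound fraction is the median of
  (1 − intensity ratio) over N-terminal residues 1–9 (the tightest-binding
  stretch; ≥ 5 must be assigned), and 1/B_max = [lipid]/(f·P). The estimate
  is only meaningful under the saturating-regime assumption, which is the
  caller's responsibility.
* **Residue profiles.** Intensity ratios (+SUV/−SUV), Cα secondary shifts
  (observed − user-supplied random-coil table; published tables differ, so
  the reference is configuration) and PRE ratios (paramagnetic/diamagnetic)
  are key-aligned joins on residue number. Prolines and unassigned residues
  stay missing end-to-end; zero denominators become missing with a warning,
  never zeros.

## DEST and R₂ exchange analysis (`synbind.dest`)

### Forward model

A single ¹⁵N spin exchanges between a visible free state and one or two
invisible bound states. Magnetisation evolves under the homogeneous
McConnell equations: per state the (x, y, z) components are coupled by the
resonance offset Ω (rad/s), the CW saturation field ω₁ along x, transverse
and longitudinal relaxation, and first-order exchange; a constant first
vector element carries the R₁·p_eq recovery sources, making the system
linear time-invariant. The propagator is exp(L·T_sat) with T_sat = 0.9 s,
evaluated by a batched eigendecomposition over all offsets (validated
against scipy's Padé `expm` to ~10⁻¹¹, with a per-matrix `expm` fallback if
an eigenbasis is ill-conditioned). NaN/Inf in a propagation raises
immediately; nothing is clipped.

* **ω₁ calibration:** ω₁ = 2π·(nominal bandwidth), i.e. 400/175 Hz on one
  field and 500/200 Hz on the other, the ideal-linear-amplifier calibration.
* **Normalisation:** profiles are divided by the mean of the two
  extreme-offset (±30 kHz) points by default — at these offsets a
  non-exchanging spin is essentially unsaturated — or by an explicit
  zero-field propagation (`reference="unsaturated"`).
* **R₁** is a single rate shared by all states (default 1.5 s⁻¹,
  configurable); DEST at these powers is R₂-dominated, so the result is
  insensitive to it.
* **Chemical-shift difference** between free and bound states is neglected
  (both states share the offset grid): the bound state is broadened beyond
  detection and its saturation is far off-resonance by construction.
* The exchange contribution to the measured free-state R₂ (ΔR₂) is computed
  as the slowest-decaying eigenvalue of the transverse exchange matrix minus
  the free R₂ — the decay rate a CPMG experiment reads off the visible peak.

### Verification integrator

`simulate_dest_stepwise` is a fixed-step RK4 integrator over the same
evolution matrix, used only as an independent cross-check of the
matrix-exponential path, never by the fitting code. A fixed-step method must
resolve the fastest off-resonance oscillation (±30 kHz → 33 µs period): 10 µs
steps reproduce the two-state profiles to better than 10⁻⁶, while the
three-state system needs ~2 µs for the same agreement (at 10 µs its
under-resolved transverse transient leaves a ~2×10⁻⁶ residual; the
matrix-exponential path itself agrees with substepped Padé propagation to
~10⁻¹³ and is the accurate one).

### Kinetic models and fitting

* **Two-state:** global (k_on^app, k_off, R₂^bound) shared by all residues,
  each residue contributing its measured free-state R₂. Fitted by seeded
  multi-start trust-region least squares over log10-transformed rates;
  bounds k_on^app ∈ [10⁻³, 10³] s⁻¹, k_off ∈ [10⁻¹, 10⁴] s⁻¹, bound-state
  R₂ ∈ [10, 10⁵] s⁻¹. Rates span decades; log-space avoids boundary
  trapping.
* **Pseudo-two-state:** global (k_off, R₂^direct) plus per-residue
  (k₁^app, k₂^app, R₂^tethered); K₃(i) = k₂^app(i)/k₁^app(i) is derived,
  never a free parameter. The two-state fit seeds a single joint
  least-squares solve over all parameters; each residue's residuals depend
  only on the globals and its own three parameters, so the Jacobian is
  block-sparse and is finite-differenced in a handful of grouped
  evaluations. On noiseless synthetic data the joint solve recovers the
  generating truth to optimiser tolerance (asserted in the tests).
  Per-residue non-identifiability is flagged from the conditioning of the
  residue's Jacobian block at the optimum.
* **Interconversion (k₃, k₋₃)** between tethered and direct-contact modes is
  off by default; an optional refinement adds the two rates as globals and
  keeps them only if the objective improves.
* **Joint objective:** DEST residuals weighted by an assumed ratio noise
  (default 0.01, settable to the known level), ΔR₂ residuals by
  max(5% of ΔR₂, 0.2 s⁻¹). Model quality should be judged by how well the
  fit reproduces ΔR₂ — the basis of the two-state vs pseudo-two-state model
  discrimination test.
* Fits are restricted to the lipid-binding domain (residues ≤ 98 by
  default); the C-terminal tail does not bind and serves as an internal
  control. Residues missing from any input are skipped, not imputed.
* **CPMG R₂:** single-exponential fit of peak height vs relaxation delay
  (0–18 elements of 16.32 ms, order-scrambled); the triplicate mid-range
  point sets the absolute per-point noise when available, so the reported
  standard error reflects measured reproducibility.
* **Pseudo-first-order check:** the mean ΔR₂ should scale with lipid
  concentration (more binding sites → higher apparent on-rate) but not with
  protein concentration. Slopes against each concentration series carry
  residue-bootstrap 95% CIs; the verdict requires a lipid effect whose CI
  excludes zero and a protein effect that is small (< 25% relative across
  the series) or has a CI containing zero.

### Statistical resolution of per-residue parameters

A Cramér–Rao computation at the default synthetic design (20 residues,
23 offsets, two bandwidths, 2% absolute ratio noise, k_on^total = 3 s⁻¹,
k_off = 20 s⁻¹, R₂^tethered = 300 s⁻¹, R₂^direct = 5000 s⁻¹) puts the
per-residue relative standard deviation of K₃ at roughly 0.12–0.20. The
median recovery error observed in the tests sits well inside that envelope,
but the *worst* of 20 residues should be expected to exceed 25% more often
than not at this noise level — a property of the information content of the
design, not of the optimiser (which is exact on noiseless data). The strict
all-residues-within-25% acceptance test documents this expectation in its
failure message.

## Cell assays (`synbind.cells`)

* **Exocytosis.** Exo = (F_stim − F_basal)/(F_total − F_basal), each F a
  5-frame window mean (basal: the 5 frames before stimulation; stimulated:
  5 frames from the post-peak frame; total: 5 frames from NH₄Cl addition).
  The post-peak frame is auto-detected as the argmax of a 3-frame-smoothed
  trace between stimulation and NH₄Cl, overridable per cell — auto-detection
  approximates a manual choice and can mislead on noisy traces. Being a
  ratio of differences, Exo is invariant to gain/offset rescaling.
  Denominators below tolerance raise; out-of-[0,1] values are flagged, not
  clipped.
* **Outlier rule.** 1.5×IQR with quantiles by linear interpolation between
  order statistics (the numpy default) — the convention is fixed and
  documented because several exist. Comparisons are reported both with and
  without outlier removal.
* **Condition comparison.** Two-sample t-test on per-cell values after
  filtering; significance categories *** (p < 0.001), * (p < 0.05), NS.
  Mean(high) − mean(low) is the potentiation measure. Groups below 2 values
  get a descriptive report (p = NaN). The expression-level immunostaining
  comparison is served by the same machinery applied to per-cell mean
  intensities; no dedicated operation exists.
* **Peripheral shell.** The recycling-endosome peripheral fraction is
  100 × (intensity in the inner boundary band of the cell mask)/(total
  intensity in the mask), with the band produced by eroding the mask with a
  disk of the requested physical thickness (800 nm default). Shells thinner
  than one pixel raise, demanding a finer pixel size.
* **Droplet partition.** eGFP channel: 2 px Gaussian blur → rolling-ball
  background subtraction (radius 20 px = the stated 40 px diameter, via
  scikit-image's implementation) → Li minimum-cross-entropy threshold →
  8-connected labelling → area filter (> 0.2 µm²). Per droplet,
  PC = mean rhodamine inside / mean rhodamine outside all droplets.
  Two symmetric safeguards against blur contamination:
  * the *outside* region excludes a 2 px guard band around every droplet;
  * the *inside* mean excludes the droplet rim by eroding each labelled
    region by 3×(blur σ) = 6 px before measuring (`interior_margin_px`).
    This is a deliberate extension: Li thresholding of a blurred two-level
    field places the boundary well outside the true droplet edge (the
    threshold lands near 10% of the droplet amplitude), and the annexed
    halo otherwise dilutes the inside mean by tens of percent. Both
    safeguards can be disabled for literal replication of the
    inverted-threshold regions. Droplets whose eroded core is empty fall
    back to the full region.
  * Droplets containing tracer pixels at the dtype maximum (or an explicit
    saturation level) are dropped — an automated substitute for manual
    removal of saturated droplets.
  Group analysis log-transforms PCs, removes 1.5×IQR outliers, checks
  near-normality (Shapiro–Wilk) and applies a t-test, reporting the
  unfiltered p-value alongside.

## Synthetic-data generators (`synbind.simulate`)

Every generator is a deterministic function of its mandatory seed and
returns a machine-readable ground-truth table alongside the data. The
defaults encode the study designs:

| generator | design point |
|---|---|
| `gen_titration_spectra` | 0.1 µM protein, 1.25 µM–10 mM twofold lipid ladder, 300–500 nm / 10 nm grid; free reference peaking at ~350 nm, bound at ~334 nm |
| `gen_dest_dataset` | 900 ms saturation, offsets to ±30 kHz, 400/175 Hz bandwidths, 20-residue binding stretch, 100 µM protein / 1 mM SUV regime |
| `gen_intensity_profile` | N-to-C ratio ramp 0.15 → 1.0 over residues 1–98, optional break at 34 or 65, prolines missing |
| `gen_exo_traces` | 2 s frames, ~20 s baseline, stimulated plateau, NH₄Cl at frame 200 |
| `gen_droplet_image` | 512² field at 0.132 µm/px, 1–2 µm droplet radii, PC = 10, 16-bit |

Noise defaults — 1% relative for spectra, 2% absolute for NMR ratios and 2%
relative for R₂, 5% relative for cell traces, none for droplet images — are
plausible bench magnitudes (the study reports none) and are all overridable.
DEST ratio noise is *absolute* because peak-height noise is thermal:
deep-profile points are not more precise than shallow ones.

Kinetic truth values for the DEST generator (k_on^total = 3 s⁻¹ at 1 mM
lipid scaling linearly with lipid, k_off = 20 s⁻¹, R₂^tethered = 300 s⁻¹,
R₂^direct = 5000 s⁻¹, free R₂ ≈ 4 s⁻¹, K₃ ramping 0.2 → 2.0 along the
sequence) are realistic magnitudes for an intrinsically disordered protein
exchanging with ~40 nm vesicles on the DEST-sensitive timescale.

**What the generators do not emulate:** shot noise, spectrometer lineshapes,
scattering or inner-filter effects, cell-to-cell trace morphology beyond
plateaus, point-spread functions or uneven illumination in images, and any
correlation structure between residues. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical structure, not
robustness to every artefact of real data.

## Problem sizes used by the test suite

Unit tests run the exchange fits on 4–6 residue datasets with a 12-offset
grid; the acceptance tests use the full 20-residue, 23-offset design. The
binding, spectral, cell-assay and generator tests run at the full study
designs throughout, since those are fast.

## Known limitations

* No raw-data processing: NMR peak heights, chemical shifts, cell ROIs and
  masks arrive as tables/arrays; no FID processing, peak picking, cell
  segmentation or microscope-format parsing.
* The C-terminal tail (residues > 98) is never fitted as exchanging.
* The DEST forward model is a single-spin description: no multi-spin or
  CEST-style effects, no pulse-sequence emulation beyond the CW block, no
  temperature model (acquisition temperatures are metadata).
* Table-style p-values for isotherm fits test only the fitted K_d term
  against zero; they are not comparable across laboratories' conventions.
* The droplet pipeline assumes registered channels and roughly uniform
  background; saturated-droplet exclusion is automated rather than manual.
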