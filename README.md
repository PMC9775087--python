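# synbind

Quantitative analysis of alpha-synuclein membrane binding and its cellular
consequences: tryptophan-fluorescence spectral analysis and binding isotherms,
¹⁵N DEST / R₂ exchange-model fitting, and vesicle-release cell-assay
quantification — with synthetic-data generators that reproduce the statistical
structure of each experiment with known ground truth.

## Who this is for

Alpha-synuclein is an intrinsically disordered presynaptic protein whose
N-terminal lipid-binding domain (residues 1–94) folds into amphipathic helices
on membranes, either as one extended helix or as two helices (helix-1,
residues ~1–37; helix-2, ~45–94) joined by a flexible linker. How tightly and
in which mode the protein binds small unilamellar vesicles (SUVs) governs its
regulation of vesicle release. This package implements the numerical pipeline
needed to characterise that binding from spectroscopic and imaging data:

* **`synbind.spectra`** — fits single-tryptophan emission spectra with the
  biparametric log-normal lineshape, computes (λ_max, width) heterogeneity
  observables, and decomposes titration spectra into free/bound fractions by
  constrained least squares.
* **`synbind.binding`** — the quadratic bimolecular binding isotherm and K_d
  fitting; the lipids-per-binding-site (1/B_max) estimate from NMR intensity
  ratios; residue-wise intensity-ratio, Cα secondary-shift and PRE profiles.
* **`synbind.dest`** — simulation and joint fitting of ¹⁵N DEST saturation
  profiles and exchange-induced R₂ enhancements under the homogeneous
  McConnell (Bloch–McConnell) equations, with two-state and pseudo-two-state
  (tethered vs direct-contact) kinetic models, CPMG R₂ decay fitting, and a
  pseudo-first-order consistency check.
* **`synbind.cells`** — pHluorin exocytosis quantification, 1.5×IQR outlier
  filtering and condition comparisons, recycling-endosome peripheral-shell
  fractions, and condensate-droplet vesicle partition coefficients from
  two-channel images.
* **`synbind.simulate`** — seeded generators for all of the above with
  machine-readable ground truth.

## The core models

**Binding isotherm.** Protein P binds independent sites on the vesicle
surface whose concentration is S = B_max·[lipid]; with dissociation constant
K_d the bound fraction is the quadratic solution

    f_b = [(P + S + K_d) − √((P + S + K_d)² − 4·P·S)] / (2P),

fitted to fluorescence-derived bound fractions with B_max fixed at 1/59
sites per lipid (the NMR-derived value) by default.

**Log-normal emission lineshape.** On the wavenumber axis ν = 10⁷/λ(nm),

    I(ν) = I_m · exp(−(ln2/ln²ρ) · ln²((a−ν)/(a−ν_m)))   for ν < a,  0 otherwise,

with peak position ν_m, asymmetry ρ = (ν_m−ν₋)/(ν₊−ν_m) > 1, bandwidth
H = ν₊−ν₋ and limiting point a = ν_m + Hρ/(ρ²−1).

**DEST / exchange.** A long CW saturation pulse (900 ms, offsets to ±30 kHz,
two bandwidths) saturates the invisible vesicle-bound state; exchange
transfers the saturation to the visible free state. Magnetisation evolves
under exp(L·T_sat) where L couples (x, y, z) of every exchanging state
through offset, CW field ω₁, relaxation and the exchange rates. The
two-state model has global (k_on^app, k_off, R₂^bound); the pseudo-two-state
model splits the bound ensemble per residue into tethered (k₁^app(i),
R₂^tethered(i)) and direct-contact (k₂^app(i), shared R₂^direct) modes with
K₃(i) = k₂^app(i)/k₁^app(i). Fits are judged jointly against the DEST
profiles and the measured ΔR₂.

**Exocytosis.** Per cell, Exo = (F_stimulated − F_basal)/(F_total − F_basal),
each F the mean of a 5-frame window (pre-stimulation, post-peak, post-NH₄Cl).

## Worked example

Generate a noisy (1%) fluorescence titration of a WT-like variant with a
known K_d of 1.12 µM, decompose each spectrum against the free and fully
bound references, and fit the isotherm:

```python
import pandas as pd
import synbind as sb
from synbind.spectra import EmissionSpectrum, lognormal_eval

cfg = sb.SpectraGenConfig(seed=7, Kd=1.12e-6, noise_sd=0.01)
spectra, truth = sb.gen_titration_spectra(cfg)

nu = 1e7 / cfg.wavelengths
free = EmissionSpectrum(cfg.wavelengths, lognormal_eval(cfg.free_ref, nu),
                        0.0, cfg.protein_conc)
bound = EmissionSpectrum(cfg.wavelengths, lognormal_eval(cfg.bound_ref, nu),
                         1e-2, cfg.protein_conc)
points = [sb.BindingPoint(s.lipid_conc, sb.decompose_spectrum(s, free, bound))
          for s in spectra]
fit = sb.fit_binding_curve(points, cfg.protein_conc)
print(f"Kd = {fit.Kd:.3e} M  (SEM {fit.Kd_sem:.2e}), saturating={fit.saturating}")

peak = sb.fit_lognormal(spectra[-1])
print(f"highest-lipid spectrum: lambda_max = {peak.lambda_max:.1f} nm, "
      f"FWHM = {peak.fwhm_nm:.1f} nm")

prof = sb.ResidueProfile(pd.Series(0.1525, index=range(1, 10)), "intensity_ratio")
print(f"lipids per binding site: {sb.estimate_lipids_per_site(prof, 2.5e-3, 50e-6):.1f}")
```

prints

```
Kd = 1.125e-06 M  (SEM 1.10e-08), saturating=True
highest-lipid spectrum: lambda_max = 334.7 nm, FWHM = 53.0 nm
lipids per binding site: 59.0
```

The fitted K_d lands within 0.5% of the generating 1.12 µM despite 1%
spectral noise; the blue-shifted λ_max of ~335 nm at saturating lipid is the
signature of a tryptophan buried in the membrane (the free-state spectrum
peaks near 350 nm); and the worked lipids-per-site number reproduces the
59-lipid binding-site footprint from N-terminal intensity ratios measured at
2.5 mM lipid and 50 µM protein.

A command-line interface mirrors the library
(`synbind spectra|bind|nmr|dest|exo|re|droplets|simulate …`); run
`synbind --help` for the catalogue.

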