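"""Log-normal analysis of tryptophan fluorescence emission spectra.

Single-tryptophan emission bands of organic fluorophores are empirically
log-normal on the wavenumber (frequency) axis.  This module fits that
biparametric log-normal lineshape to coarsely sampled emission spectra,
derives peak position / width observables used to judge the environmental
heterogeneity of the emitting species, and decomposes titration spectra
into free and membrane-bound fractions by constrained least squares.

All lineshape arithmetic is carried out on the wavenumber axis
(nu = 1e7 / lambda_nm, in cm^-1); results are reported back in nm where
that is the conventional unit (lambda_max, FWHM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "EmissionSpectrum",
    "LogNormalFit",
    "HeterogeneityPoint",
    "nm_to_wavenumber",
    "wavenumber_to_nm",
    "lognormal_eval",
    "fit_lognormal",
    "heterogeneity_points",
    "decompose_spectrum",
    "read_spectra_csv",
    "write_fits_csv",
]

LN2 = np.log(2.0)

#: default emission grid: 300-500 nm in 10 nm steps
DEFAULT_WAVELENGTHS = np.arange(300.0, 501.0, 10.0)


def nm_to_wavenumber(lambda_nm):
    """Convert wavelength in nm to wavenumber in cm^-1 (nu = 1e7 / lambda)."""
    return 1.0e7 / np.asarray(lambda_nm, dtype=float)


def wavenumber_to_nm(nu):
    """Convert wavenumber in cm^-1 to wavelength in nm."""
    return 1.0e7 / np.asarray(nu, dtype=float)


@dataclass(frozen=True)
class EmissionSpectrum:
    """One baseline-subtracted emission spectrum at a single titration point.

    Parameters
    ----------
    wavelengths : array of float
        Emission wavelengths in nm, strictly increasing.
    intensities : array of float
        Fluorescence intensities (arbitrary units), blank-subtracted.
    lipid_conc : float
        Total lipid concentration (M), >= 0.
    protein_conc : float
        Protein concentration (M), > 0.
    label : str
        Variant / sample identifier.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    lipid_conc: float = 0.0
    protein_conc: float = 1e-7
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        iy = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.shape != iy.shape:
            raise ValueError("wavelengths and intensities must be matching 1-D arrays")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(iy)):
            raise ValueError("intensities must be finite")
        if self.lipid_conc < 0:
            raise ValueError("lipid_conc must be >= 0")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be > 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", iy)

    @property
    def wavenumbers(self) -> np.ndarray:
        """Wavenumber grid in cm^-1 (decreasing, mirrors the nm grid)."""
        return nm_to_wavenumber(self.wavelengths)


@dataclass(frozen=True)
class LogNormalFit:
    """Parameters of the biparametric log-normal emission lineshape.

    ``I(nu) = Im * exp(-(ln2 / ln^2 rho) * ln^2((a - nu)/(a - nu_m)))`` for
    nu < a and exactly 0 for nu >= a, where ``a = nu_m + H*rho/(rho^2 - 1)``.

    Attributes
    ----------
    Im : float
        Peak intensity (a.u.).
    nu_m : float
        Wavenumber of the fluorescence maximum (cm^-1).
    rho : float
        Band asymmetry parameter, > 1 for red-skewed emission.
    H : float
        Bandwidth nu_plus - nu_minus between the half-maximum wavenumbers (cm^-1).
    a : float
        Function limiting point (cm^-1); intensity is identically zero at nu >= a.
    residual_rms : float
        Root-mean-square fit residual (a.u.); 0 for analytically constructed fits.
    converged : bool
        Whether the optimiser reported convergence.
    """

    Im: float
    nu_m: float
    rho: float
    H: float
    a: float = field(default=np.nan)
    residual_rms: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if self.rho <= 1.0:
            raise ValueError("rho must be > 1")
        if self.H <= 0 or self.Im <= 0 or self.nu_m <= 0:
            raise ValueError("Im, nu_m and H must be positive")
        if np.isnan(self.a):
            object.__setattr__(self, "a", limiting_point(self.nu_m, self.rho, self.H))

    @property
    def lambda_max(self) -> float:
        """Wavelength of the emission maximum in nm."""
        return 1.0e7 / self.nu_m

    @property
    def nu_plus(self) -> float:
        """Blue-side (high-wavenumber) half-maximum position (cm^-1)."""
        return self.a - (self.a - self.nu_m) / self.rho

    @property
    def nu_minus(self) -> float:
        """Red-side (low-wavenumber) half-maximum position (cm^-1)."""
        return self.a - (self.a - self.nu_m) * self.rho

    @property
    def fwhm_nm(self) -> float:
        """Full width at half maximum on the wavelength axis (nm)."""
        return 1.0e7 / self.nu_minus - 1.0e7 / self.nu_plus


@dataclass(frozen=True)
class HeterogeneityPoint:
    """(lambda_max, peak width) pair used in heterogeneity plots."""

    lambda_max: float
    peak_width: float
    lipid_conc: float = 0.0

    def __post_init__(self):
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")


def limiting_point(nu_m: float, rho: float, H: float) -> float:
    """Limiting point ``a = nu_m + H * rho / (rho^2 - 1)`` in cm^-1."""
    return nu_m + H * rho / (rho * rho - 1.0)


def lognormal_eval(fit: LogNormalFit, nu):
    """Evaluate the log-normal lineshape at wavenumber(s) ``nu`` (cm^-1).

    Returns Im at nu = nu_m and exactly 0 for nu >= a.
    """
    nu = np.asarray(nu, dtype=float)
    out = np.zeros_like(nu)
    below = nu < fit.a
    arg = (fit.a - nu[below]) / (fit.a - fit.nu_m)
    out[below] = fit.Im * np.exp(-(LN2 / np.log(fit.rho) ** 2) * np.log(arg) ** 2)
    return out if out.ndim else float(out)


def _lognormal_curve(nu, Im, nu_m, rho, H):
    a = limiting_point(nu_m, rho, H)
    out = np.zeros_like(nu)
    below = nu < a
    arg = (a - nu[below]) / (a - nu_m)
    out[below] = Im * np.exp(-(LN2 / np.log(rho) ** 2) * np.log(arg) ** 2)
    return out


def fit_lognormal(spectrum: EmissionSpectrum) -> LogNormalFit:
    """Least-squares fit of the log-normal lineshape to one emission spectrum.

    The fit runs on the wavenumber axis with parameters (Im, nu_m, rho, H);
    the limiting point ``a`` is recomputed from the fitted parameters.

    Raises
    ------
    ValueError
        If fewer than 5 points have positive intensity (degenerate spectrum).
    """
    nu = spectrum.wavenumbers
    y = spectrum.intensities
    if np.count_nonzero(y > 0) < 5:
        raise ValueError("degenerate spectrum: need >= 5 points with positive intensity")

    # initialisation robust on a 10 nm grid: argmax for nu_m / Im, crude
    # half-max scan on the wavenumber axis for H
    imax = int(np.argmax(y))
    Im0, nu_m0 = float(y[imax]), float(nu[imax])
    half = Im0 / 2.0
    above = nu[y >= half]
    H0 = float(above.max() - above.min()) if above.size >= 2 else 3000.0
    H0 = max(H0, 500.0)
    x0 = np.array([Im0, nu_m0, 1.3, H0])

    lo = np.array([1e-12, nu.min() * 0.5, 1.0 + 1e-6, 1.0])
    hi = np.array([np.inf, nu.max() * 2.0, 3.0, np.inf])

    def resid(p):
        return _lognormal_curve(nu, *p) - y

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
    Im, nu_m, rho, H = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return LogNormalFit(
        Im=float(Im), nu_m=float(nu_m), rho=float(rho), H=float(H),
        residual_rms=rms, converged=bool(sol.success),
    )


def heterogeneity_points(fits, concentrations=None) -> list[HeterogeneityPoint]:
    """(lambda_max, FWHM-in-nm) pairs for a heterogeneity plot.

    The caller compares the points against an externally supplied empirical
    reference line (free tryptophan in solvents of graded hydrophobicity);
    that line is user configuration and is never synthesised here.
    """
    if concentrations is None:
        concentrations = [0.0] * len(fits)
    if len(concentrations) != len(fits):
        raise ValueError("concentrations must match fits")
    return [
        HeterogeneityPoint(lambda_max=f.lambda_max, peak_width=f.fwhm_nm, lipid_conc=c)
        for f, c in zip(fits, concentrations)
    ]


def decompose_spectrum(
    spectrum: EmissionSpectrum,
    free_ref: EmissionSpectrum,
    bound_ref: EmissionSpectrum,
) -> float:
    """Bound fraction from a two-reference spectral decomposition.

    Solves ``min || s - (c_f * free + c_b * bound) ||^2`` subject to
    ``c_f, c_b >= 0`` and ``c_f + c_b = 1``.  With the closed simplex the
    problem is one-dimensional in c_b and the constrained optimum is the
    unconstrained minimiser clamped to [0, 1]:

        c_b = clip( <s - f, b - f> / ||b - f||^2 , 0, 1 )

    The references must come from matched protein concentrations, which is
    what justifies the sum-to-one constraint.
    """
    for ref in (free_ref, bound_ref):
        if ref.wavelengths.shape != spectrum.wavelengths.shape or not np.allclose(
            ref.wavelengths, spectrum.wavelengths
        ):
            raise ValueError("all spectra must share an identical wavelength grid")
    f = free_ref.intensities
    b = bound_ref.intensities
    d = b - f
    denom = float(d @ d)
    if denom <= 1e-12 * max(float(f @ f), 1.0):
        raise ValueError("free and bound references are identical: decomposition ill-posed")
    c_b = float(d @ (spectrum.intensities - f)) / denom
    return float(np.clip(c_b, 0.0, 1.0))


# ---------------------------------------------------------------------------
# I/O: long-format CSV (label, lipid_conc_M, wavelength_nm, intensity)

def read_spectra_csv(path, protein_conc: float = 1e-7) -> list[EmissionSpectrum]:
    """Read titration spectra from a long-format CSV."""
    df = pd.read_csv(path)
    required = {"label", "lipid_conc_M", "wavelength_nm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV missing columns: {sorted(missing)}")
    out = []
    for (label, conc), grp in df.groupby(["label", "lipid_conc_M"], sort=True):
        grp = grp.sort_values("wavelength_nm")
        out.append(
            EmissionSpectrum(
                wavelengths=grp["wavelength_nm"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                lipid_conc=float(conc),
                protein_conc=protein_conc,
                label=str(label),
            )
        )
    return out


def write_fits_csv(fits: list[LogNormalFit], path, labels=None) -> pd.DataFrame:
    """Export log-normal fits as CSV; returns the DataFrame written."""
    rows = []
    for i, f in enumerate(fits):
        rows.append(
            {
                "label": labels[i] if labels is not None else str(i),
                "Im": f.Im, "nu_m_cm": f.nu_m, "rho": f.rho, "H_cm": f.H,
                "a_cm": f.a, "lambda_max_nm": f.lambda_max, "fwhm_nm": f.fwhm_nm,
                "residual_rms": f.residual_rms, "converged": f.converged,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
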