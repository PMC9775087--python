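"""Membrane-binding isotherms and residue-wise NMR profile quantities.

The affinity of alpha-synuclein for lipid vesicles is estimated from
bound-fraction titrations with a quadratic bimolecular binding model: protein
molecules (concentration P) bind independent sites on the vesicle surface
whose concentration S is proportional to total lipid, S = Bmax * [lipid].
1/Bmax is the minimum number of lipids constituting one binding site and is
determined for the wild-type protein from NMR intensity ratios measured in
the saturating regime.

The module also computes the standard residue-indexed NMR observables that
feed that estimate and the structural analysis: +/- SUV peak-intensity
ratios, C-alpha secondary chemical shifts, and PRE (paramagnetic /
diamagnetic) intensity ratios.  Residues missing from either input (prolines,
overlapped peaks) stay missing end-to-end; nothing is zero-filled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_LIPIDS_PER_SITE",
    "BindingPoint",
    "BindingFit",
    "ResidueProfile",
    "bound_fraction_model",
    "fit_binding_curve",
    "estimate_lipids_per_site",
    "compute_intensity_ratio",
    "compute_secondary_shift",
    "compute_pre_ratio",
    "titration_grid",
    "read_peak_table",
    "read_shift_table",
]

#: minimum number of lipids per binding site for WT-like analyses (1/Bmax)
DEFAULT_LIPIDS_PER_SITE = 59.0


@dataclass(frozen=True)
class BindingPoint:
    """One titration point: total lipid (M) and measured bound fraction."""

    lipid_conc: float
    bound_fraction: float

    def __post_init__(self):
        if self.lipid_conc < 0:
            raise ValueError("lipid_conc must be >= 0")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class BindingFit:
    """Result of a quadratic bimolecular isotherm fit.

    ``fit_pvalue`` is the two-sided p-value of the fitted Kd term
    (t = Kd / SEM against zero, df = n_points - n_params).
    """

    Kd: float
    Kd_sem: float
    Bmax: float
    Bmax_fitted: bool
    protein_conc: float
    converged: bool
    saturating: bool
    fit_pvalue: float
    n_points: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "Kd_M": self.Kd, "Kd_sem_M": self.Kd_sem,
                "Bmax_sites_per_lipid": self.Bmax,
                "lipids_per_site": 1.0 / self.Bmax,
                "Bmax_fitted": self.Bmax_fitted,
                "protein_conc_M": self.protein_conc,
                "converged": self.converged, "saturating": self.saturating,
                "fit_pvalue": self.fit_pvalue, "n_points": self.n_points,
            },
            indent=2,
        )


@dataclass(frozen=True)
class ResidueProfile:
    """Residue-indexed profile (intensity ratio, secondary shift or PRE ratio).

    ``values`` is a pandas Series indexed by residue number (1..n_residues);
    missing residues are simply absent from the index or stored as NaN.
    """

    values: pd.Series
    kind: str
    n_residues: int = 140

    _KINDS = ("intensity_ratio", "secondary_shift", "pre_ratio")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        s = pd.Series(self.values, dtype=float)
        s.index = s.index.astype(int)
        if len(s) and (s.index.min() < 1 or s.index.max() > self.n_residues):
            raise ValueError("residue indices must lie within 1..n_residues")
        object.__setattr__(self, "values", s.sort_index())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.values.index, "value": self.values.to_numpy(),
                             "kind": self.kind})


def bound_fraction_model(Kd, Bmax, protein_conc, lipid_conc):
    """Bound protein fraction from the quadratic bimolecular binding model.

    With S = Bmax * lipid_conc the binding-site concentration and P the total
    protein concentration, the bound protein concentration solves
    ``B = ((P + S + Kd) - sqrt((P + S + Kd)^2 - 4 P S)) / 2`` and the
    returned bound fraction is B / P, in [0, 1].  Vectorised in lipid_conc.
    """
    if Kd <= 0 or Bmax <= 0 or protein_conc <= 0:
        raise ValueError("Kd, Bmax and protein_conc must be positive")
    L = np.asarray(lipid_conc, dtype=float)
    if np.any(L < 0):
        raise ValueError("lipid_conc must be >= 0")
    P = protein_conc
    S = Bmax * L
    b = P + S + Kd
    disc = np.maximum(b * b - 4.0 * P * S, 0.0)  # analytically >= 0; guard rounding
    bound = (b - np.sqrt(disc)) / 2.0
    frac = bound / P
    return frac if frac.ndim else float(frac)


def titration_grid() -> np.ndarray:
    """Lipid titration grid (M): twofold dilution ladders from decade anchors.

    Anchors 10, 1, 0.1 and 0.01 mM, each diluted in twofold steps down to the
    next anchor, spanning 1.25 uM to 10 mM (16 concentrations, ascending).
    """
    grid = []
    for anchor in (10e-3, 1e-3, 0.1e-3, 0.01e-3):
        c = anchor
        while c > anchor / 10.0 * 1.0001:
            grid.append(c)
            c /= 2.0
    return np.array(sorted(grid))


def fit_binding_curve(
    points,
    protein_conc: float,
    Bmax: float | str = 1.0 / DEFAULT_LIPIDS_PER_SITE,
    saturation_threshold: float = 0.9,
) -> BindingFit:
    """Nonlinear least-squares fit of Kd from a bound-fraction titration.

    Parameters
    ----------
    points : sequence of BindingPoint
        At least 6 titration points spanning sub- to near-saturating lipid.
    protein_conc : float
        Total protein concentration (M).
    Bmax : float or "fit"
        Binding sites per lipid molecule.  Fixed by default (1/59 sites per
        lipid, the NMR-derived wild-type value); pass ``"fit"`` to co-fit it.
    saturation_threshold : float
        Curves whose maximum bound fraction stays below this are flagged as
        non-saturating (``saturating=False``), mirroring weak binders that do
        not plateau within the titration range.

    Kd is optimised in log10 space (affinities span decades); the SEM is the
    square root of the corresponding diagonal element of the parameter
    covariance from the Jacobian at the optimum, delta-transformed back to
    the linear scale.
    """
    points = list(points)
    if len(points) < 6:
        raise ValueError("need >= 6 titration points")
    L = np.array([p.lipid_conc for p in points])
    y = np.array([p.bound_fraction for p in points])
    if np.all(y == 0):
        raise ValueError("all bound fractions are zero: nothing to fit")

    fit_bmax = isinstance(Bmax, str)
    if fit_bmax and Bmax != "fit":
        raise ValueError("Bmax must be a positive float or 'fit'")
    bmax0 = 1.0 / DEFAULT_LIPIDS_PER_SITE if fit_bmax else float(Bmax)
    if bmax0 <= 0:
        raise ValueError("Bmax must be positive")

    # crude Kd init: lipid concentration at half-maximal signal
    half = 0.5 * y.max()
    kd0 = float(L[np.argmin(np.abs(y - half))]) * bmax0
    kd0 = min(max(kd0, 1e-12), 1.0)

    def resid(theta):
        kd = 10.0 ** theta[0]
        bm = 10.0 ** theta[1] if fit_bmax else bmax0
        return bound_fraction_model(kd, bm, protein_conc, L) - y

    x0 = [np.log10(kd0)] + ([np.log10(bmax0)] if fit_bmax else [])
    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, max_nfev=5000)
    theta = sol.x
    Kd_hat = float(10.0 ** theta[0])
    bm_hat = float(10.0 ** theta[1]) if fit_bmax else bmax0

    n, p = len(y), len(theta)
    dof = max(n - p, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        var_log10 = max(float(cov[0, 0]), 0.0)
        identifiable = True
    except np.linalg.LinAlgError:
        var_log10 = np.inf
        identifiable = False
    # delta method: d(Kd)/d(log10 Kd) = Kd * ln(10)
    Kd_sem = Kd_hat * np.log(10.0) * np.sqrt(var_log10)

    if Kd_sem > 0 and np.isfinite(Kd_sem):
        tstat = Kd_hat / Kd_sem
        pval = 2.0 * stats.t.sf(abs(tstat), dof)
    else:
        pval = float("nan") if not identifiable else 0.0

    converged = bool(sol.success) and identifiable
    if not converged:
        warnings.warn("binding-curve fit did not converge or Kd is non-identifiable",
                      stacklevel=2)
    return BindingFit(
        Kd=Kd_hat, Kd_sem=float(Kd_sem), Bmax=bm_hat, Bmax_fitted=fit_bmax,
        protein_conc=protein_conc, converged=converged,
        saturating=bool(y.max() >= saturation_threshold),
        fit_pvalue=float(pval), n_points=n,
    )


def estimate_lipids_per_site(
    profile: ResidueProfile,
    lipid_conc: float,
    protein_conc: float,
    n_terminal_residues: int = 9,
) -> float:
    """Minimum number of lipids per binding site (1/Bmax) from intensity ratios.

    In the saturating regime every binding site is occupied, so the bound
    protein concentration equals the site concentration.  The bound fraction
    is taken as the median of (1 - intensity_ratio) over the N-terminal
    residues (1..9 by default, the tightest-binding stretch), and the result
    is ``lipid_conc / (f * protein_conc)``.  The saturating-regime assumption
    is the caller's responsibility.
    """
    if profile.kind != "intensity_ratio":
        raise ValueError("profile must be an intensity_ratio profile")
    nterm = profile.values.loc[
        profile.values.index <= n_terminal_residues
    ].dropna()
    if len(nterm) < 5:
        raise ValueError(
            f"need >= 5 assigned residues among 1..{n_terminal_residues}"
        )
    f = float(np.median(1.0 - nterm.to_numpy()))
    if f <= 0:
        raise ValueError("no binding detected (median bound fraction <= 0)")
    return lipid_conc / (f * protein_conc)


def _ratio_profile(numer: pd.Series, denom: pd.Series, kind: str) -> ResidueProfile:
    numer = pd.Series(numer, dtype=float)
    denom = pd.Series(denom, dtype=float)
    common = numer.index.intersection(denom.index)
    num, den = numer.loc[common], denom.loc[common]
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} residue(s) with zero reference height set to missing",
            stacklevel=3,
        )
    ratio = num / den.where(~zero)
    return ResidueProfile(values=ratio.dropna(), kind=kind)


def compute_intensity_ratio(peaks_with, peaks_without) -> ResidueProfile:
    """Per-residue peak-height ratio, +SUV / -SUV.

    Inputs are residue-indexed height Series (or dicts); residues missing in
    either table are missing in the output.
    """
    return _ratio_profile(pd.Series(peaks_with), pd.Series(peaks_without),
                          "intensity_ratio")


def compute_secondary_shift(observed_ca, random_coil_ca) -> ResidueProfile:
    """C-alpha secondary shifts: observed minus random-coil reference (ppm).

    The random-coil reference table is user-supplied configuration; published
    tables differ and the choice is reported with the result, not made here.
    Sustained values above ~1 ppm indicate helical propensity.
    """
    obs = pd.Series(observed_ca, dtype=float)
    ref = pd.Series(random_coil_ca, dtype=float)
    common = obs.index.intersection(ref.index)
    delta = (obs.loc[common] - ref.loc[common]).dropna()
    return ResidueProfile(values=delta, kind="secondary_shift")


def compute_pre_ratio(paramagnetic, diamagnetic) -> ResidueProfile:
    """PRE intensity ratios: paramagnetic / diamagnetic (DTT-reduced) heights."""
    return _ratio_profile(pd.Series(paramagnetic), pd.Series(diamagnetic), "pre_ratio")


# ---------------------------------------------------------------------------
# I/O

def read_peak_table(path) -> pd.Series:
    """Read a TSV peak table (columns: residue, [assignment,] height)."""
    df = pd.read_csv(path, sep="\t")
    if "residue" not in df.columns or "height" not in df.columns:
        raise ValueError("peak table needs 'residue' and 'height' columns")
    return pd.Series(df["height"].to_numpy(float), index=df["residue"].astype(int))


def read_shift_table(path) -> pd.Series:
    """Read a TSV chemical-shift table (columns: residue, ca_ppm)."""
    df = pd.read_csv(path, sep="\t")
    if "residue" not in df.columns or "ca_ppm" not in df.columns:
        raise ValueError("shift table needs 'residue' and 'ca_ppm' columns")
    return pd.Series(df["ca_ppm"].to_numpy(float), index=df["residue"].astype(int))
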