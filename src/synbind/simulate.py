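"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one experiment type —
tryptophan-fluorescence titrations, residue-wise DEST/R2 exchange data,
N-to-C-graded NMR intensity-ratio profiles, pHluorin exocytosis traces and
two-channel condensate droplet images — at the study's design points
(sample sizes, concentration grids, acquisition schedules), and returns a
machine-readable ground-truth record alongside the data.  Every generator is
a deterministic function of its seed; the seed is mandatory wherever the
output is stochastic.

Default noise levels: 1% relative Gaussian for fluorescence spectra, 2% for
NMR ratios and R2, 5% for cell traces — plausible bench magnitudes, all
overridable.  Generators target statistical structure, not physical noise
models (no shot noise or lineshape effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binding import DEFAULT_LIPIDS_PER_SITE, bound_fraction_model, titration_grid
from .cells import ExoTrace
from .dest import (
    DESTExperimentConfig,
    DESTProfile,
    R2Profile,
    TwoStateFit,
    delta_r2_pseudo,
    delta_r2_two_state,
    residue_kinetics,
    _simulate_one,
)
from .spectra import DEFAULT_WAVELENGTHS, EmissionSpectrum, LogNormalFit, lognormal_eval

__all__ = [
    "HUMAN_ASYN_PROLINE_POSITIONS",
    "SpectraGenConfig",
    "DestGenConfig",
    "IntensityProfileConfig",
    "ExoGenConfig",
    "DropletGenConfig",
    "gen_titration_spectra",
    "gen_dest_dataset",
    "gen_intensity_profile",
    "gen_exo_traces",
    "gen_droplet_image",
]

#: proline positions of the (configurable) human alpha-synuclein sequence;
#: prolines lack an amide proton and are missing from 15N-1H correlation data
HUMAN_ASYN_PROLINE_POSITIONS = (108, 117, 120, 128, 138)


# ---------------------------------------------------------------------------
# Titration spectra

def _default_free_ref() -> LogNormalFit:
    # solvent-exposed tryptophan: red emission near 349 nm
    return LogNormalFit(Im=1000.0, nu_m=28600.0, rho=1.40, H=5200.0)


def _default_bound_ref() -> LogNormalFit:
    # membrane-buried tryptophan: blue-shifted (~334 nm), narrower, brighter
    return LogNormalFit(Im=1400.0, nu_m=29900.0, rho=1.35, H=4600.0)


@dataclass(frozen=True)
class SpectraGenConfig:
    """Ground truth for a fluorescence-monitored binding titration.

    Defaults follow the fluorescence assay design: 0.1 uM protein, twofold
    lipid dilution ladders spanning 1.25 uM - 10 mM, 300-500 nm emission grid
    in 10 nm steps, 59 lipids per binding site.
    """

    seed: int
    Kd: float = 1.12e-6
    lipids_per_site: float = DEFAULT_LIPIDS_PER_SITE
    protein_conc: float = 1e-7
    lipid_concs: np.ndarray = field(default_factory=titration_grid)
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())
    free_ref: LogNormalFit = field(default_factory=_default_free_ref)
    bound_ref: LogNormalFit = field(default_factory=_default_bound_ref)
    noise_sd: float = 0.01  # relative to the free-reference peak intensity
    label: str = "WT"


def gen_titration_spectra(cfg: SpectraGenConfig):
    """Titration spectra as free/bound log-normal mixtures with known Kd.

    The bound fraction at each lipid concentration comes from the quadratic
    bimolecular binding model; each spectrum is that convex combination of
    the free and bound reference lineshapes plus relative Gaussian noise.
    Returns ``(spectra, truth)`` where truth is a DataFrame with the
    per-point lipid concentration and true bound fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    nu = 1.0e7 / np.asarray(cfg.wavelengths, float)
    free_i = lognormal_eval(cfg.free_ref, nu)
    bound_i = lognormal_eval(cfg.bound_ref, nu)
    bmax = 1.0 / cfg.lipids_per_site
    spectra, rows = [], []
    for L in np.asarray(cfg.lipid_concs, float):
        fb = bound_fraction_model(cfg.Kd, bmax, cfg.protein_conc, L)
        y = (1.0 - fb) * free_i + fb * bound_i
        if cfg.noise_sd > 0:
            y = y + rng.normal(0.0, cfg.noise_sd * cfg.free_ref.Im, y.shape)
        spectra.append(EmissionSpectrum(
            wavelengths=cfg.wavelengths, intensities=y, lipid_conc=float(L),
            protein_conc=cfg.protein_conc, label=cfg.label,
        ))
        rows.append({"lipid_conc_M": float(L), "bound_fraction": float(fb)})
    truth = pd.DataFrame(rows)
    return spectra, truth


# ---------------------------------------------------------------------------
# DEST / R2 datasets

@dataclass(frozen=True)
class DestGenConfig:
    """Ground-truth exchange model for a residue-wise DEST + R2 dataset.

    The default emulates the acquisition design (900 ms saturation, offsets
    to +/-30 kHz, bandwidths 400/175 Hz) in the 100 uM protein / 1 mM SUV
    regime for a 20-residue synthetic lipid-binding stretch.  For the
    pseudo-two-state truth the contact equilibrium K3 steps linearly from
    ``K3_start`` at the first residue to ``K3_stop`` at the last, with the
    total apparent on-rate ``kon_total`` split accordingly
    (k1 = kon_total / (1 + K3), k2 = kon_total * K3 / (1 + K3)).  Apparent
    on-rates scale linearly with ``lipid_conc`` (pseudo-first-order binding
    to vesicle surface sites); ``protein_conc`` is metadata.
    """

    seed: int
    model: str = "pseudo_two_state"  # or "two_state"
    n_residues: int = 20
    n_tail_residues: int = 0         # appended non-exchanging (tail-like) residues
    koff: float = 20.0
    kon_total: float = 3.0           # s^-1 at the reference lipid concentration
    K3_start: float = 0.2
    K3_stop: float = 2.0
    R2_tethered: float = 300.0
    R2_direct: float = 5000.0
    R2_bound: float = 2000.0         # two-state truth only
    free_R2_mean: float = 4.0
    free_R2_spread: float = 1.5      # linear ramp across the sequence
    lipid_conc: float = 1e-3
    reference_lipid_conc: float = 1e-3
    protein_conc: float = 1e-4
    noise_sd: float = 0.02           # relative, on DEST ratios and R2 rates
    experiment: DESTExperimentConfig = field(default_factory=DESTExperimentConfig)


def gen_dest_dataset(cfg: DestGenConfig):
    """Simulate a residue-wise DEST + R2 dataset from a known exchange truth.

    Returns ``(dest_pair, r2_profiles, truth)``:

    * ``dest_pair`` - list of :class:`DESTProfile`, one per bandwidth;
    * ``r2_profiles`` - dict with ``"free"`` and ``"with_vesicles"``
      :class:`R2Profile` entries (the difference is the exchange
      contribution);
    * ``truth`` - DataFrame of the per-residue generating parameters.

    Tail residues (``n_tail_residues``) are generated with zero exchange and
    produce flat, narrow profiles like the non-binding C-terminal tail.
    """
    rng = np.random.default_rng(cfg.seed)
    exp = cfg.experiment
    scale = cfg.lipid_conc / cfg.reference_lipid_conc
    n_tot = cfg.n_residues + cfg.n_tail_residues
    residues = np.arange(1, n_tot + 1)
    free_r2 = cfg.free_R2_mean + cfg.free_R2_spread * np.linspace(-0.5, 0.5, n_tot)

    rows = []
    ratios = {bw: [] for bw in exp.bandwidths_hz}
    for i, res in enumerate(residues):
        tail = i >= cfg.n_residues
        if cfg.model == "two_state":
            kon = 0.0 if tail else cfg.kon_total * scale
            kin = TwoStateFit(kon_app=kon, koff=cfg.koff, R2_bound=cfg.R2_bound)
            dr2 = delta_r2_two_state(kon, cfg.koff, free_r2[i], cfg.R2_bound)
            rows.append({"residue": res, "kon_app": kon, "koff": cfg.koff,
                         "R2_bound": cfg.R2_bound, "free_R2": free_r2[i],
                         "delta_R2": dr2, "tail": tail})
        elif cfg.model == "pseudo_two_state":
            if tail:
                k1 = k2 = 0.0
                K3 = np.nan
            else:
                frac = i / max(cfg.n_residues - 1, 1)
                K3 = cfg.K3_start + (cfg.K3_stop - cfg.K3_start) * frac
                k1 = cfg.kon_total * scale / (1.0 + K3)
                k2 = cfg.kon_total * scale * K3 / (1.0 + K3)
            kin = residue_kinetics(k1, k2, cfg.koff, cfg.R2_tethered, cfg.R2_direct)
            dr2 = delta_r2_pseudo(k1, k2, cfg.koff, free_r2[i],
                                  cfg.R2_tethered, cfg.R2_direct)
            rows.append({"residue": res, "k1_app": k1, "k2_app": k2, "K3": K3,
                         "koff": cfg.koff, "R2_tethered": cfg.R2_tethered,
                         "R2_direct": cfg.R2_direct, "free_R2": free_r2[i],
                         "delta_R2": dr2, "tail": tail})
        else:
            raise ValueError("model must be 'two_state' or 'pseudo_two_state'")
        for bw in exp.bandwidths_hz:
            prof = _simulate_one(exp, kin, free_r2[i], bw)
            if cfg.noise_sd > 0:
                prof = prof + rng.normal(0.0, cfg.noise_sd, prof.shape)
            ratios[bw].append(prof)

    truth = pd.DataFrame(rows).set_index("residue")
    dest_pair = [
        DESTProfile(ratios=pd.DataFrame(np.stack(ratios[bw]), index=residues,
                                        columns=exp.offsets_hz), bandwidth_hz=bw)
        for bw in exp.bandwidths_hz
    ]
    r2_free = truth["free_R2"]
    r2_with = truth["free_R2"] + truth["delta_R2"]
    if cfg.noise_sd > 0:
        r2_free = r2_free * (1.0 + rng.normal(0.0, cfg.noise_sd, n_tot))
        r2_with = r2_with * (1.0 + rng.normal(0.0, cfg.noise_sd, n_tot))
    r2_profiles = {
        "free": R2Profile(values=r2_free.clip(lower=1e-3), condition="free"),
        "with_vesicles": R2Profile(values=r2_with.clip(lower=1e-3),
                                   condition="with_vesicles"),
    }
    return dest_pair, r2_profiles, truth


# ---------------------------------------------------------------------------
# Intensity-ratio profiles

@dataclass(frozen=True)
class IntensityProfileConfig:
    """N-to-C graded +/- SUV intensity-ratio profile with optional break.

    ``WT_like`` ramps monotonically from the tightly bound N-terminus
    (ratio ``n_term_ratio``) up to ``tail_ratio`` at the end of the
    lipid-binding domain; ``break_at_34`` / ``break_at_65`` add a step
    discontinuity of ``break_step`` at that residue, emulating variants whose
    helix propagation is interrupted.  Prolines are emitted as missing.
    """

    seed: int
    variant_style: str = "WT_like"   # WT_like | break_at_34 | break_at_65
    n_residues: int = 140
    n_term_ratio: float = 0.15
    tail_ratio: float = 1.0
    binding_domain_end: int = 98
    break_step: float = 0.4
    noise_sd: float = 0.0
    proline_positions: tuple[int, ...] = HUMAN_ASYN_PROLINE_POSITIONS


def gen_intensity_profile(cfg: IntensityProfileConfig):
    """Generate a residue-wise intensity-ratio profile and its truth table.

    Returns ``(profile, truth)`` where profile is a
    :class:`~synbind.binding.ResidueProfile` (kind ``intensity_ratio``) and
    truth records the noiseless ratio per residue.
    """
    from .binding import ResidueProfile

    styles = {"WT_like": None, "break_at_34": 34, "break_at_65": 65}
    if cfg.variant_style not in styles:
        raise ValueError(f"variant_style must be one of {sorted(styles)}")
    break_at = styles[cfg.variant_style]

    rng = np.random.default_rng(cfg.seed)
    residues = np.arange(1, cfg.n_residues + 1)
    ramp = np.clip((residues - 1) / max(cfg.binding_domain_end - 1, 1), 0.0, 1.0)
    ratio = cfg.n_term_ratio + (cfg.tail_ratio - cfg.n_term_ratio) * ramp
    if break_at is not None:
        ratio = np.where(residues >= break_at,
                         np.minimum(ratio + cfg.break_step, cfg.tail_ratio), ratio)
    truth = pd.Series(ratio, index=residues, name="intensity_ratio")
    noisy = truth.copy()
    if cfg.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.noise_sd, noisy.shape)
    noisy = noisy.drop(index=[p for p in cfg.proline_positions
                              if p <= cfg.n_residues], errors="ignore")
    profile = ResidueProfile(values=noisy, kind="intensity_ratio",
                             n_residues=cfg.n_residues)
    return profile, truth


# ---------------------------------------------------------------------------
# Exocytosis traces

@dataclass(frozen=True)
class ExoGenConfig:
    """Piecewise-plateau pHluorin traces with known exocytosed fractions.

    The timeline mirrors the imaging protocol: ~20 s baseline before
    stimulation, a stimulated plateau reached after the exocytosis peak and
    an NH4Cl plateau revealing the total vesicle pool at the end.
    ``conditions`` maps a condition label to (true mean Exo, between-cell SD,
    number of cells).
    """

    seed: int
    conditions: dict = field(default_factory=lambda: {"low": (0.2, 0.1, 50),
                                                      "high": (0.4, 0.1, 50)})
    frame_interval: float = 2.0   # s
    n_frames: int = 220
    stim_frame: int = 10
    peak_frame: int = 60
    nh4cl_frame: int = 200
    f_basal: float = 100.0
    f_total: float = 400.0
    noise_sd: float = 0.05        # relative, per frame


def gen_exo_traces(cfg: ExoGenConfig) -> list[ExoTrace]:
    """Generate per-cell exocytosis traces; each trace carries its truth.

    Returns ``(traces, truth)`` with truth a DataFrame (cell_id, condition,
    true_exo).  The per-cell true Exo is drawn from the condition's
    (mean, SD) and clipped to [0, 0.95]; the trace plateaus encode it
    exactly before noise.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_frames) * cfg.frame_interval
    traces, rows = [], []
    for cond, (mean_exo, sd_exo, n_cells) in cfg.conditions.items():
        for j in range(n_cells):
            exo = float(np.clip(rng.normal(mean_exo, sd_exo), 0.0, 0.95))
            f_stim = cfg.f_basal + exo * (cfg.f_total - cfg.f_basal)
            f = np.empty(cfg.n_frames)
            f[: cfg.stim_frame] = cfg.f_basal
            # rise to the stimulated plateau, flat through the peak window
            rise = slice(cfg.stim_frame, cfg.peak_frame)
            f[rise] = np.linspace(cfg.f_basal, f_stim, cfg.peak_frame - cfg.stim_frame)
            f[cfg.peak_frame: cfg.nh4cl_frame] = f_stim
            f[cfg.nh4cl_frame:] = cfg.f_total
            if cfg.noise_sd > 0:
                f = f * (1.0 + rng.normal(0.0, cfg.noise_sd, f.shape))
            cell_id = f"{cond}_{j:03d}"
            traces.append(ExoTrace(time=t, fluorescence=f,
                                   stim_frame=cfg.stim_frame,
                                   peak_frame=cfg.peak_frame,
                                   nh4cl_frame=cfg.nh4cl_frame,
                                   cell_id=cell_id, condition=cond))
            rows.append({"cell_id": cell_id, "condition": cond, "true_exo": exo})
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Droplet images

@dataclass(frozen=True)
class DropletGenConfig:
    """Two-channel condensate droplet field with known partition coefficient.

    Non-overlapping disks are rasterised with linear edge antialiasing on a
    condensate (eGFP-like) channel and a vesicle tracer (rhodamine-like)
    channel whose inside level is ``partition_coefficient`` times the outside
    level.  ``n_saturated`` droplets are painted at the dtype maximum of the
    tracer channel to exercise saturated-droplet exclusion;
    ``n_subresolution`` disks are painted below the area filter.
    """

    seed: int
    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.132
    n_droplets: int = 12
    radius_range_um: tuple[float, float] = (1.0, 2.0)
    partition_coefficient: float = 10.0
    gfp_background: float = 20.0
    gfp_amplitude: float = 200.0
    rho_background: float = 100.0
    noise_sd: float = 0.0          # relative, both channels
    n_saturated: int = 0
    n_subresolution: int = 0
    dtype: type = np.uint16


def gen_droplet_image(cfg: DropletGenConfig):
    """Generate a two-channel droplet image plus its per-droplet truth table.

    Returns ``(gfp, rhodamine, truth)``; truth lists centre, radius, area and
    whether the droplet is saturated or below the area filter.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    yy, xx = np.mgrid[0:h, 0:w]
    gfp = np.full(cfg.shape, cfg.gfp_background, float)
    rho = np.full(cfg.shape, cfg.rho_background, float)
    sat_value = float(np.iinfo(cfg.dtype).max)

    min_r_px = 0.5  # sub-resolution disks
    rows, placed = [], []
    specs = (
        [("normal", rng.uniform(*cfg.radius_range_um)) for _ in range(cfg.n_droplets)]
        + [("saturated", rng.uniform(*cfg.radius_range_um)) for _ in range(cfg.n_saturated)]
        + [("tiny", 0.2) for _ in range(cfg.n_subresolution)]
    )
    for kind, r_um in specs:
        r = max(r_um / cfg.pixel_size_um, min_r_px)
        pos = None
        for _ in range(500):
            cy = rng.uniform(r + 30, h - r - 30)
            cx = rng.uniform(r + 30, w - r - 30)
            if all((cy - y0) ** 2 + (cx - x0) ** 2 > (r + r0 + 12) ** 2
                   for y0, x0, r0 in placed):
                pos = (cy, cx)
                break
        if pos is None:
            continue
        placed.append((*pos, r))
        frac = np.clip(r - np.sqrt((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) + 0.5,
                       0.0, 1.0)
        gfp += cfg.gfp_amplitude * frac
        if kind == "saturated":
            rho = np.where(frac > 0.5, sat_value, rho)
        else:
            rho += (cfg.partition_coefficient - 1.0) * cfg.rho_background * frac
        rows.append({
            "cy_px": pos[0], "cx_px": pos[1], "radius_um": r * cfg.pixel_size_um,
            "area_um2": np.pi * (r * cfg.pixel_size_um) ** 2,
            "partition_coefficient": (np.nan if kind != "normal"
                                      else cfg.partition_coefficient),
            "saturated": kind == "saturated",
            "below_area_filter": kind == "tiny",
        })
    if cfg.noise_sd > 0:
        gfp = gfp * (1.0 + rng.normal(0.0, cfg.noise_sd, gfp.shape))
        rho = np.where(rho >= sat_value, rho,
                       rho * (1.0 + rng.normal(0.0, cfg.noise_sd, rho.shape)))
    gfp = np.clip(gfp, 0, sat_value).astype(cfg.dtype)
    rho = np.clip(rho, 0, sat_value).astype(cfg.dtype)
    return gfp, rho, pd.DataFrame(rows)
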