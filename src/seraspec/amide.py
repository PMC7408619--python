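"""Amide I band deconvolution into protein secondary-structure components.

The Amide I envelope (1720-1590 cm⁻¹, dominated by backbone C=O
stretching) is a superposition of overlapping sub-bands whose positions
encode secondary structure: β-sheet components at the high- (~1700-1682
cm⁻¹) and low-wavenumber (~1642-1600 cm⁻¹) edges, turns near 1670 cm⁻¹,
α-helix near 1666-1648 cm⁻¹ and disordered chains near 1648-1642 cm⁻¹.

The workflow fits a sum of Lorentzians to a class-mean spectrum:

1. :func:`class_mean_amide` — preprocess each spectrum (rubberband +
   vector norm by default), average the class, cut to 1590-1720 cm⁻¹;
2. :func:`second_derivative_minima` — Savitzky-Golay second derivative
   (window 7, cubic); each sufficiently deep negative minimum marks one
   sub-band (a Lorentzian's second derivative at its center is −2h/γ²);
3. :func:`initialise_bands` — invert that relation for starting heights;
4. :func:`fit_band_sum` — bounded nonlinear least squares on
   (center, height, hwhm) per band;
5. :func:`assign_and_fractionate` — map fitted centers to structures and
   report area fractions (Lorentzian area = π·height·hwhm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .preprocess import (
    PreprocessRecipe,
    Rubberband,
    VectorNorm,
    apply_recipe,
    cut_region,
    savgol_derivative,
)
from .spectra_io import Spectrum, SpectralDataset
from .synthetic_cohort import BandSpec, render_band_sum

__all__ = [
    "LorentzianBand",
    "DeconvolutionResult",
    "DEFAULT_STRUCTURE_TABLE",
    "AMIDE_I_REGION",
    "class_mean_amide",
    "second_derivative_minima",
    "initialise_bands",
    "fit_band_sum",
    "assign_and_fractionate",
    "deconvolve_class",
]

STRUCTURES = ("alpha_helix", "beta_sheet", "turn", "disordered")

#: Analysis window for the Amide I envelope, cm^-1.
AMIDE_I_REGION = (1590.0, 1720.0)

#: Default wavenumber -> secondary structure map, ordered high to low; a band
#: whose center lies in (lo, hi] takes the listed structure (the lowest
#: interval also includes its lower edge). Boundaries are approximate and
#: user-overridable.
DEFAULT_STRUCTURE_TABLE: tuple[tuple[float, float, str], ...] = (
    (1682.0, 1700.0, "beta_sheet"),
    (1666.0, 1682.0, "turn"),
    (1648.0, 1666.0, "alpha_helix"),
    (1642.0, 1648.0, "disordered"),
    (1600.0, 1642.0, "beta_sheet"),
)


@dataclass
class LorentzianBand:
    """A fitted Amide I component; ``area`` is the analytic π·h·γ."""

    center: float
    height: float
    hwhm: float
    structure: str | None = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("band height must be >= 0")
        if self.hwhm <= 0:
            raise ValueError("band hwhm must be > 0")

    @property
    def area(self) -> float:
        return float(np.pi * self.height * self.hwhm)

    def as_bandspec(self) -> BandSpec:
        return BandSpec(self.center, self.height, self.hwhm)


@dataclass
class DeconvolutionResult:
    bands: list[LorentzianBand]
    fitted: Spectrum
    residual_rms: float
    fractions: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def band_sum(self, axis: np.ndarray) -> np.ndarray:
        return render_band_sum([b.as_bandspec() for b in self.bands], axis)


def class_mean_amide(
    dataset: SpectralDataset,
    class_name: str,
    recipe: PreprocessRecipe | None = None,
    region: tuple[float, float] = AMIDE_I_REGION,
) -> Spectrum:
    """Preprocessed pointwise class mean, cut to the Amide I window.

    Each spectrum is preprocessed independently (default: rubberband
    baseline + vector normalisation) before averaging, so no spectrum
    dominates through its overall intensity.
    """
    subset = dataset.subset_classes([class_name])
    if not subset.spectra:
        raise ValueError(f"unknown or empty class {class_name!r}")
    if recipe is None:
        recipe = [Rubberband(), VectorNorm()]
    processed = apply_recipe(subset, recipe)
    mean = processed.mean_spectrum(spectrum_id=f"mean_{class_name}")
    return cut_region(mean, *region)


def second_derivative_minima(
    spectrum: Spectrum,
    region: tuple[float, float] = AMIDE_I_REGION,
    prominence_frac: float = 0.05,
    points: int = 7,
    poly_order: int = 3,
) -> tuple[np.ndarray, Spectrum]:
    """Locate sub-band positions as deep negative second-derivative minima.

    Returns the ascending minima positions together with the second
    derivative spectrum. A local minimum qualifies when its value is
    negative and its depth exceeds ``prominence_frac`` times the depth of
    the global minimum in the region.
    """
    if not 0 < prominence_frac < 1:
        raise ValueError("prominence_frac must be in (0, 1)")
    d2 = savgol_derivative(spectrum, points, poly_order, 2)
    lo, hi = min(region), max(region)
    if lo > d2.wavenumbers[-1] or hi < d2.wavenumbers[0]:
        raise ValueError(f"region {region} outside the spectrum axis")
    mask = (d2.wavenumbers >= lo) & (d2.wavenumbers <= hi)
    x, y = d2.wavenumbers[mask], d2.absorbances[mask]
    global_min = float(y.min())
    if global_min >= 0:
        return np.array([]), d2
    # strict interior local minima
    idx = np.where((y[1:-1] < y[:-2]) & (y[1:-1] < y[2:]))[0] + 1
    keep = [i for i in idx if y[i] < 0 and -y[i] >= prominence_frac * (-global_min)]
    return x[keep], d2


def initialise_bands(
    minima: Sequence[float], second_deriv: Spectrum, gamma0: float = 8.0
) -> list[LorentzianBand]:
    """Starting bands from second-derivative minima.

    At a Lorentzian's center the analytic second derivative is −2h/γ², so
    a minimum of depth d gives a starting height h = −d·γ₀²/2, clipped
    below at 1e-6 for shallow artefacts.
    """
    if len(minima) == 0:
        raise ValueError("no minima to initialise bands from")
    bands = []
    for c in minima:
        d = float(np.interp(c, second_deriv.wavenumbers, second_deriv.absorbances))
        height = max(-d * gamma0**2 / 2.0, 1e-6)
        bands.append(LorentzianBand(center=float(c), height=height, hwhm=gamma0))
    return bands


def fit_band_sum(
    spectrum: Spectrum,
    init: Sequence[LorentzianBand],
    center_window: float = 4.0,
    hwhm_bounds: tuple[float, float] = (3.0, 30.0),
    max_nfev: int = 20000,
) -> DeconvolutionResult:
    """Bounded nonlinear least-squares fit of a sum of Lorentzians.

    Per band, centers may move ±``center_window`` cm⁻¹ from their
    initialisation, heights stay non-negative and half-widths stay inside
    ``hwhm_bounds`` — enough freedom to fit, little enough to keep the
    components identifiable in a crowded 130 cm⁻¹ window. Bands are
    reported sorted by descending center. If the optimiser hits its
    iteration cap the best iterate is returned with ``converged=False``.
    """
    if not init:
        raise ValueError("need at least one initial band")
    x, y = spectrum.wavenumbers, spectrum.absorbances
    g_lo, g_hi = hwhm_bounds

    x0, lo, hi = [], [], []
    for b in init:
        x0 += [b.center, max(b.height, 1e-6), float(np.clip(b.hwhm, g_lo, g_hi))]
        lo += [b.center - center_window, 0.0, g_lo]
        hi += [b.center + center_window, np.inf, g_hi]

    def model(params: np.ndarray) -> np.ndarray:
        c, h, g = params[0::3], params[1::3], params[2::3]
        return (h[:, None] * g[:, None] ** 2 / ((x[None, :] - c[:, None]) ** 2 + g[:, None] ** 2)).sum(axis=0)

    def residual(params: np.ndarray) -> np.ndarray:
        return model(params) - y

    result = least_squares(
        residual,
        np.asarray(x0),
        bounds=(np.asarray(lo), np.asarray(hi)),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_nfev,
    )
    params = result.x
    bands = [
        LorentzianBand(center=float(params[3 * i]), height=float(params[3 * i + 1]),
                       hwhm=float(params[3 * i + 2]))
        for i in range(len(init))
    ]
    bands.sort(key=lambda b: -b.center)
    fitted_values = model(params)
    fitted = spectrum.replace(absorbances=fitted_values)
    rms = float(np.sqrt(np.mean((fitted_values - y) ** 2)))
    return DeconvolutionResult(
        bands=bands, fitted=fitted, residual_rms=rms, converged=result.status > 0
    )


def assign_and_fractionate(
    result: DeconvolutionResult,
    table: Sequence[tuple[float, float, str]] = DEFAULT_STRUCTURE_TABLE,
) -> DeconvolutionResult:
    """Assign each band a structure by its center and compute area fractions.

    The table lists (lo, hi, structure) intervals ordered high to low;
    first match wins, so a shared boundary belongs to the higher interval.
    A band center outside the table's coverage raises.
    """
    if not result.bands:
        raise ValueError("no fitted bands to assign")
    assigned = []
    for b in result.bands:
        structure = None
        for lo, hi, name in table:
            if lo <= b.center <= hi:
                structure = name
                break
        if structure is None:
            raise ValueError(
                f"band center {b.center:.1f} cm^-1 outside the assignment table coverage"
            )
        assigned.append(replace(b, structure=structure))
    total = sum(b.area for b in assigned)
    fractions: dict[str, float] = {}
    for b in assigned:
        fractions[b.structure] = fractions.get(b.structure, 0.0) + b.area / total
    return DeconvolutionResult(
        bands=assigned,
        fitted=result.fitted,
        residual_rms=result.residual_rms,
        fractions=fractions,
        converged=result.converged,
    )


def deconvolve_class(
    dataset: SpectralDataset,
    class_name: str,
    recipe: PreprocessRecipe | None = None,
    gamma0: float = 8.0,
    prominence_frac: float = 0.05,
    table: Sequence[tuple[float, float, str]] = DEFAULT_STRUCTURE_TABLE,
) -> DeconvolutionResult:
    """End-to-end class-mean Amide I deconvolution (steps 1-5 of the workflow)."""
    mean = class_mean_amide(dataset, class_name, recipe)
    minima, d2 = second_derivative_minima(mean, prominence_frac=prominence_frac)
    if len(minima) == 0:
        raise ValueError(f"class {class_name!r}: no Amide I sub-band minima found")
    init = initialise_bands(minima, d2, gamma0=gamma0)
    fit = fit_band_sum(mean, init)
    return assign_and_fractionate(fit, table)
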