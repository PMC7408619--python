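"""Spectral preprocessing: baseline correction, normalisation, EMSC, binning.

Two named recipes are shipped, mirroring the two analysis branches of the
pipeline:

* :func:`pca_recipe` — cut to the fingerprint region (1800-900 cm⁻¹),
  rubberband (lower convex hull) baseline correction, vector (ℓ₂)
  normalisation; used for exploratory PCA and class-mean deconvolution.
* :func:`clf_recipe` — extended multiplicative signal correction against a
  pooled-serum reference, cut to 1800-1000 cm⁻¹, min-max normalisation to
  [0, 1], binning by a factor of 8; used to build classifier feature
  matrices (801 points → 100 features on a 1 cm⁻¹ axis).

Every step is strictly per-spectrum; the only shared statistic is the EMSC
reference, which is a fixed input (never estimated from data the recipe is
applied to).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import Spectrum, SpectralDataset

__all__ = [
    "cut_region",
    "rubberband_baseline",
    "vector_normalise",
    "minmax_normalise",
    "bin_spectrum",
    "emsc_correct",
    "savgol_derivative",
    "apply_recipe",
    "pca_recipe",
    "clf_recipe",
    "Cut",
    "Rubberband",
    "VectorNorm",
    "MinMax",
    "Bin",
    "EMSC",
    "SavGol",
    "PreprocessRecipe",
]


def cut_region(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep points with lo <= ν <= hi (closed interval, order-normalised).

    The bounds may be given in either order (spectroscopy convention often
    quotes high→low, e.g. "1800-900").
    """
    lo, hi = (lo, hi) if lo < hi else (hi, lo)
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r}: cut({lo}, {hi}) leaves no points "
            f"(axis {spectrum.wavenumbers[0]}-{spectrum.wavenumbers[-1]})"
        )
    return spectrum.replace(
        wavenumbers=spectrum.wavenumbers[mask], absorbances=spectrum.absorbances[mask]
    )


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Indices of the lower convex hull of (x, y), x strictly ascending."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k unless (j, k, i) makes a strict left turn
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def rubberband_baseline(spectrum: Spectrum) -> Spectrum:
    """Subtract the lower convex hull ("rubberband") baseline.

    The baseline is the piecewise-linear lower hull of (ν, A) between the
    first and last axis points; the corrected spectrum is >= 0 everywhere
    and exactly 0 at every hull contact point.
    """
    if len(spectrum) < 3:
        raise ValueError(f"spectrum {spectrum.spectrum_id!r}: rubberband needs >= 3 points")
    x, y = spectrum.wavenumbers, spectrum.absorbances
    hull = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[hull], y[hull])
    corrected = np.maximum(y - baseline, 0.0)  # clamp fp residue at contacts
    return spectrum.replace(absorbances=corrected)


def vector_normalise(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.absorbances))
    if norm < 1e-12:
        raise ValueError(f"spectrum {spectrum.spectrum_id!r}: zero norm, cannot normalise")
    return spectrum.replace(absorbances=spectrum.absorbances / norm)


def minmax_normalise(spectrum: Spectrum) -> Spectrum:
    """Rescale linearly so min = 0 and max = 1."""
    a = spectrum.absorbances
    lo, hi = float(a.min()), float(a.max())
    if hi - lo < 1e-12:
        raise ValueError(f"spectrum {spectrum.spectrum_id!r}: constant spectrum, min == max")
    return spectrum.replace(absorbances=(a - lo) / (hi - lo))


def bin_spectrum(spectrum: Spectrum, factor: int) -> Spectrum:
    """Average consecutive non-overlapping groups of ``factor`` points.

    Both the axis and the absorbances are replaced by their group means;
    a trailing remainder of fewer than ``factor`` points is dropped.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    n = len(spectrum)
    if factor > n:
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r}: binning factor {factor} exceeds length {n}"
        )
    if factor == 1:
        return spectrum
    m = n // factor
    w = spectrum.wavenumbers[: m * factor].reshape(m, factor).mean(axis=1)
    a = spectrum.absorbances[: m * factor].reshape(m, factor).mean(axis=1)
    return spectrum.replace(wavenumbers=w, absorbances=a)


def emsc_correct(
    spectrum: Spectrum,
    reference: Spectrum | np.ndarray,
    poly_degree: int = 2,
) -> tuple[Spectrum, np.ndarray]:
    """Extended multiplicative signal correction against a reference.

    Fits ``A(ν) ≈ b·R(ν) + Σ_{k=0..d} a_k t^k`` by least squares, with t
    the axis rescaled to [-1, 1], and returns the corrected spectrum
    ``(A − Σ a_k t^k)/b`` together with the coefficient vector
    ``(b, a_0, …, a_d)``. Removes multiplicative scatter (film-thickness
    gain) and low-order additive drift in one step.
    """
    if isinstance(reference, Spectrum):
        if len(reference) != len(spectrum) or not np.allclose(
            reference.wavenumbers, spectrum.wavenumbers
        ):
            raise ValueError(
                f"spectrum {spectrum.spectrum_id!r}: EMSC reference is on a different axis"
            )
        ref = reference.absorbances
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != spectrum.absorbances.shape:
            raise ValueError(
                f"spectrum {spectrum.spectrum_id!r}: EMSC reference length mismatch"
            )
    if float(ref.max() - ref.min()) < 1e-12:
        raise ValueError("EMSC reference is constant")
    x = spectrum.wavenumbers
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    design = np.column_stack([ref] + [t**k for k in range(poly_degree + 1)])
    coef, _, rank, _ = np.linalg.lstsq(design, spectrum.absorbances, rcond=None)
    if rank < design.shape[1]:
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r}: rank-deficient EMSC design "
            "(reference collinear with the polynomial terms?)"
        )
    b = float(coef[0])
    if abs(b) < 1e-8:
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r}: EMSC gain ~ 0, spectrum unrelated to reference"
        )
    additive = design[:, 1:] @ coef[1:]
    corrected = (spectrum.absorbances - additive) / b
    return spectrum.replace(absorbances=corrected), coef


def savgol_derivative(
    spectrum: Spectrum, points: int, poly_order: int, deriv_order: int
) -> Spectrum:
    """Savitzky-Golay smoothing / differentiation on a uniform axis.

    Fits a local polynomial of ``poly_order`` in a sliding window of
    ``points`` (odd) samples and evaluates its ``deriv_order``-th
    derivative with respect to wavenumber (so units are
    absorbance·cm^deriv). Edge positions whose window would extend past
    the data are dropped: the output keeps only the interior axis,
    ``points//2`` samples shorter on each side.
    """
    points = int(points)
    if points % 2 == 0 or points <= poly_order:
        raise ValueError("savgol: points must be odd and > poly_order")
    if deriv_order > poly_order:
        raise ValueError("savgol: deriv_order must be <= poly_order")
    if len(spectrum) < points:
        raise ValueError(f"spectrum {spectrum.spectrum_id!r}: fewer points than the window")
    d = np.diff(spectrum.wavenumbers)
    spacing = float(d.mean())
    if np.max(np.abs(d - spacing)) > 1e-6 * abs(spacing):
        raise ValueError(
            f"spectrum {spectrum.spectrum_id!r}: non-uniform axis spacing, "
            "Savitzky-Golay requires a uniform grid"
        )
    filtered = savgol_filter(
        spectrum.absorbances, points, poly_order, deriv=deriv_order, delta=spacing
    )
    half = points // 2
    return spectrum.replace(
        wavenumbers=spectrum.wavenumbers[half:-half], absorbances=filtered[half:-half]
    )


# --- recipes -----------------------------------------------------------------


@dataclass(frozen=True)
class Cut:
    lo: float
    hi: float


@dataclass(frozen=True)
class Rubberband:
    pass


@dataclass(frozen=True)
class VectorNorm:
    pass


@dataclass(frozen=True)
class MinMax:
    pass


@dataclass(frozen=True)
class Bin:
    factor: int


@dataclass(frozen=True)
class EMSC:
    reference: Spectrum
    poly_degree: int = 2


@dataclass(frozen=True)
class SavGol:
    points: int = 7
    poly_order: int = 3
    deriv_order: int = 0


Step = Union[Cut, Rubberband, VectorNorm, MinMax, Bin, EMSC, SavGol]
PreprocessRecipe = Sequence[Step]


def _apply_step(spectrum: Spectrum, step: Step) -> Spectrum:
    if isinstance(step, Cut):
        return cut_region(spectrum, step.lo, step.hi)
    if isinstance(step, Rubberband):
        return rubberband_baseline(spectrum)
    if isinstance(step, VectorNorm):
        return vector_normalise(spectrum)
    if isinstance(step, MinMax):
        return minmax_normalise(spectrum)
    if isinstance(step, Bin):
        return bin_spectrum(spectrum, step.factor)
    if isinstance(step, EMSC):
        corrected, _ = emsc_correct(spectrum, step.reference, step.poly_degree)
        return corrected
    if isinstance(step, SavGol):
        return savgol_derivative(spectrum, step.points, step.poly_order, step.deriv_order)
    raise TypeError(f"unknown preprocessing step {step!r}")


def apply_recipe(dataset: SpectralDataset, recipe: PreprocessRecipe) -> SpectralDataset:
    """Apply the steps in order to every spectrum; metadata is untouched."""
    out: list[Spectrum] = []
    for s in dataset.spectra:
        current = s
        for i, step in enumerate(recipe):
            try:
                current = _apply_step(current, step)
            except ValueError as exc:
                raise ValueError(
                    f"recipe step {i} ({type(step).__name__}) failed on "
                    f"spectrum {s.spectrum_id!r}: {exc}"
                ) from exc
        out.append(current)
    return SpectralDataset(out)


def apply_recipe_spectrum(spectrum: Spectrum, recipe: PreprocessRecipe) -> Spectrum:
    """Apply a recipe to a single spectrum."""
    for step in recipe:
        spectrum = _apply_step(spectrum, step)
    return spectrum


def pca_recipe() -> list[Step]:
    """Exploration preset: fingerprint cut, rubberband, vector normalisation."""
    return [Cut(900.0, 1800.0), Rubberband(), VectorNorm()]


def clf_recipe(reference: Spectrum, poly_degree: int = 2, bin_factor: int = 8) -> list[Step]:
    """Classification preset: EMSC, cut 1800-1000, min-max, bin."""
    return [EMSC(reference, poly_degree), Cut(1000.0, 1800.0), MinMax(), Bin(bin_factor)]
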