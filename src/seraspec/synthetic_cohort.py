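"""Synthetic serum-like mid-infrared cohorts with known class effects.

Dried-film serum ATR-FTIR spectra are emulated as a sum of Lorentzian
absorption bands (Amide I/II/III, lipid ester and CH bending modes,
carbohydrate/glycogen C-O stretches and nucleic-acid phosphate stretches
across the 1800-900 cm⁻¹ fingerprint region) with four nested noise
sources mimicking the acquisition of three sample wells per patient, each
scanned in triplicate:

* patient-level biological heterogeneity — a lognormal factor on each
  band height, shared by all nine of a patient's spectra;
* per-well multiplicative gain — film-thickness/contact variation, the
  scatter that EMSC preprocessing is designed to remove;
* per-replicate height jitter, baseline polynomial + random drift;
* additive white detector noise.

Class templates ship for control, GBM, PCNSL, meningioma and metastasis
serum. Their band positions follow the standard biofluid assignments; the
class effects encode the qualitative directions reported for these
groups (GBM: β-sheet ~1630-1637 down, α-helix ~1650-1660 up; PCNSL the
reverse; metastasis: carbohydrate/phosphate 1012-1050 up). Effect
magnitudes are free simulation parameters, not literature claims.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra_io import Spectrum, SpectralDataset, ValidationError

__all__ = [
    "BandSpec",
    "ClassProfile",
    "CohortConfig",
    "render_band_sum",
    "simulate_patient",
    "generate_cohort",
    "default_profiles",
    "default_profile",
    "BASE_SERUM_BANDS",
]


@dataclass(frozen=True)
class BandSpec:
    """One Lorentzian band: L(ν) = height · γ² / ((ν − center)² + γ²).

    ``hwhm`` is the half width at half maximum γ (FWHM = 2γ) — the same
    parameterisation the Amide I deconvolution fits.
    """

    center: float  # cm^-1
    height: float  # absorbance units
    hwhm: float    # cm^-1

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError(f"band at {self.center}: hwhm must be > 0")
        if self.height < 0:
            raise ValueError(f"band at {self.center}: height must be >= 0")


@dataclass
class ClassProfile:
    """Population template for one class: mean bands plus variance knobs.

    All SDs are >= 0 and act as follows per simulated spectrum:
    ``band_sd`` relative (lognormal) SD of band heights across patients;
    ``replicate_sd`` the same, per individual spectrum; ``scatter_sd`` SD of
    the log multiplicative well gain; ``baseline`` fixed quadratic
    coefficients (on the axis rescaled to [-1, 1]) with ``drift_sd`` the SD
    of random per-spectrum perturbations of those coefficients;
    ``noise_sd`` additive white-noise SD in absorbance units.
    """

    name: str
    bands: Sequence[BandSpec]
    band_sd: float = 0.08
    scatter_sd: float = 0.06
    baseline: Sequence[float] = (0.02, 0.01, 0.005)
    drift_sd: float = 0.004
    noise_sd: float = 0.0015
    replicate_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"profile {self.name!r}: needs at least one band")
        for sd_name in ("band_sd", "scatter_sd", "drift_sd", "noise_sd", "replicate_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"profile {self.name!r}: {sd_name} must be >= 0")
        self.bands = tuple(self.bands)
        self.baseline = tuple(float(c) for c in self.baseline)
        if len(self.baseline) > 3:
            raise ValueError(f"profile {self.name!r}: baseline degree must be <= 2")


@dataclass
class CohortConfig:
    """Axis, per-class profiles with patient counts, and the master seed."""

    axis: tuple[float, float, float] = (900.0, 1800.0, 1.0)  # (low, high, spacing)
    profiles: Mapping[str, tuple[ClassProfile, int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        low, high, spacing = self.axis
        if spacing <= 0:
            raise ValueError("axis spacing must be > 0")
        if not (low <= 900.0 and high >= 1800.0):
            raise ValueError("axis must cover 1800-900 cm^-1")
        for name, (profile, n) in self.profiles.items():
            if n < 1:
                raise ValueError(f"class {name!r}: n_patients must be >= 1")

    def axis_values(self) -> np.ndarray:
        low, high, spacing = self.axis
        n = int(round((high - low) / spacing)) + 1
        return low + spacing * np.arange(n)


def render_band_sum(bands: Sequence[BandSpec], axis: np.ndarray) -> np.ndarray:
    """Evaluate Σᵢ hᵢ·γᵢ²/((ν−cᵢ)²+γᵢ²) on ``axis`` (zeros for no bands)."""
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    for b in bands:
        out += b.height * b.hwhm**2 / ((axis - b.center) ** 2 + b.hwhm**2)
    return out


def _polynomial_baseline(coeffs: Sequence[float], axis: np.ndarray) -> np.ndarray:
    """Quadratic baseline evaluated on the axis rescaled to [-1, 1]."""
    t = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
    out = np.zeros_like(axis)
    for k, c in enumerate(coeffs):
        out += c * t**k
    return out


def simulate_patient(
    profile: ClassProfile,
    patient_id: str,
    axis: np.ndarray,
    rng: np.random.Generator,
) -> list[Spectrum]:
    """Simulate one patient's nine spectra (3 wells × 3 replicates).

    One patient-level lognormal height factor per band is shared by all
    nine spectra; each well draws a multiplicative scatter gain; each
    replicate adds height jitter, the baseline polynomial plus random
    drift, and white noise.
    """
    axis = np.asarray(axis, dtype=float)
    heights = np.array([b.height for b in profile.bands])
    n_bands = len(heights)
    patient_factor = np.exp(rng.normal(0.0, profile.band_sd, size=n_bands))
    spectra: list[Spectrum] = []
    for well in (1, 2, 3):
        gain = float(np.exp(rng.normal(0.0, profile.scatter_sd)))
        for replicate in (1, 2, 3):
            rep_factor = np.exp(rng.normal(0.0, profile.replicate_sd, size=n_bands))
            h = heights * patient_factor * rep_factor
            bands = [
                BandSpec(b.center, float(hi), b.hwhm)
                for b, hi in zip(profile.bands, h)
            ]
            signal = gain * render_band_sum(bands, axis)
            coeffs = np.zeros(3)
            coeffs[: len(profile.baseline)] = profile.baseline
            coeffs = coeffs + rng.normal(0.0, profile.drift_sd, size=3)
            baseline = _polynomial_baseline(coeffs, axis)
            noise = rng.normal(0.0, profile.noise_sd, size=axis.shape)
            spectra.append(
                Spectrum(
                    spectrum_id=f"{patient_id}_w{well}r{replicate}",
                    patient_id=patient_id,
                    well=well,
                    replicate=replicate,
                    wavenumbers=axis,
                    absorbances=signal + baseline + noise,
                    label=profile.name,
                )
            )
    return spectra


def generate_cohort(config: CohortConfig) -> SpectralDataset:
    """Generate a labelled cohort: 9 spectra per patient, deterministic in the seed."""
    axis = config.axis_values()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    spectra: list[Spectrum] = []
    seen: set[str] = set()
    for class_name, (profile, n_patients) in config.profiles.items():
        for i in range(n_patients):
            patient_id = f"{class_name}_{i:04d}"
            if patient_id in seen:
                raise ValidationError(f"overlapping patient id {patient_id!r}")
            seen.add(patient_id)
            spectra.extend(simulate_patient(profile, patient_id, axis, rng))
    return SpectralDataset(spectra)


# --- default serum templates -------------------------------------------------

#: Base dried-serum band set (center cm^-1, height AU, hwhm cm^-1) spanning the
#: fingerprint region: Amide I sub-bands resolved by secondary structure, Amide
#: II/III, lipid and carbohydrate/glycogen/phosphate modes.
BASE_SERUM_BANDS: tuple[BandSpec, ...] = (
    # Amide I secondary-structure components (1600-1700)
    BandSpec(1690.0, 0.10, 9.0),   # beta-sheet (high-wavenumber)
    BandSpec(1670.0, 0.13, 9.0),   # turns
    BandSpec(1658.0, 0.42, 11.0),  # alpha-helix
    BandSpec(1650.0, 0.28, 10.0),  # alpha-helix
    BandSpec(1645.0, 0.16, 9.0),   # disordered
    BandSpec(1637.0, 0.26, 10.0),  # beta-sheet
    BandSpec(1615.0, 0.07, 9.0),   # beta-sheet / side chains
    # Amide II
    BandSpec(1550.0, 0.40, 16.0),
    BandSpec(1515.0, 0.08, 9.0),
    # lipids / proteins
    BandSpec(1750.0, 0.04, 9.0),   # lipid C=O stretch
    BandSpec(1470.0, 0.10, 9.0),   # lipid CH2 scissoring
    BandSpec(1400.0, 0.13, 11.0),  # CH3 bending
    BandSpec(1340.0, 0.05, 9.0),   # phospholipid CH2 wagging
    # Amide III
    BandSpec(1310.0, 0.05, 11.0),
    BandSpec(1245.0, 0.09, 13.0),  # + asymmetric PO2- stretch
    # carbohydrates / glycogen / nucleic-acid phosphate
    BandSpec(1170.0, 0.05, 10.0),
    BandSpec(1080.0, 0.08, 13.0),  # symmetric PO2- stretch
    BandSpec(1050.0, 0.07, 11.0),  # carbohydrate/glycogen C-O-C
    BandSpec(1045.0, 0.07, 11.0),  # DNA/RNA symmetric PO2-
    BandSpec(1030.0, 0.08, 10.0),  # glycogen C-O stretch
    BandSpec(1012.0, 0.06, 10.0),  # carbohydrate C-O stretch
)

#: Class effects as multiplicative factors on the base band heights, keyed by
#: band center. Directions follow the qualitative serum findings for these
#: groups; magnitudes are simulation choices.
CLASS_EFFECTS: dict[str, dict[float, float]] = {
    "control": {},
    "GBM": {1637.0: 0.80, 1615.0: 0.85, 1658.0: 1.15, 1650.0: 1.10},
    "PCNSL": {1637.0: 1.25, 1615.0: 1.20, 1658.0: 0.92, 1650.0: 0.95},
    "meningioma": {1658.0: 1.06, 1637.0: 1.05, 1645.0: 1.08},
    "metastasis": {1030.0: 1.30, 1045.0: 1.30, 1050.0: 1.25, 1012.0: 1.20, 1080.0: 1.15},
}


def default_profile(class_name: str, **overrides) -> ClassProfile:
    """Build a shipped class template, optionally overriding variance knobs.

    ``band_scale`` in ``overrides`` may map band centers to extra height
    factors (applied on top of the class effect).
    """
    if class_name not in CLASS_EFFECTS:
        raise KeyError(
            f"no default template for {class_name!r}; choose from {sorted(CLASS_EFFECTS)}"
        )
    effects = dict(CLASS_EFFECTS[class_name])
    extra = overrides.pop("band_scale", {}) or {}
    bands = []
    for b in BASE_SERUM_BANDS:
        factor = effects.get(b.center, 1.0) * float(extra.get(b.center, 1.0))
        bands.append(BandSpec(b.center, b.height * factor, b.hwhm))
    return ClassProfile(name=class_name, bands=bands, **overrides)


def default_profiles(**overrides) -> dict[str, ClassProfile]:
    """All five shipped class templates keyed by class name."""
    return {name: default_profile(name, **copy.deepcopy(overrides)) for name in CLASS_EFFECTS}
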