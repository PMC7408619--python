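import numpy as np
import pytest

from seraspec import (
    BandSpec,
    ClassProfile,
    CohortConfig,
    SpectralDataset,
    Spectrum,
    default_profile,
    generate_cohort,
)


def make_spectrum(
    wavenumbers,
    absorbances,
    spectrum_id="s1",
    patient_id="p1",
    well=1,
    replicate=1,
    label=None,
):
    return Spectrum(
        spectrum_id=spectrum_id,
        patient_id=patient_id,
        well=well,
        replicate=replicate,
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        absorbances=np.asarray(absorbances, dtype=float),
        label=label,
    )


@pytest.fixture
def spectrum_factory():
    return make_spectrum


@pytest.fixture
def fingerprint_axis():
    """1 cm^-1 axis covering 900-1800 cm^-1 (901 points)."""
    return 900.0 + np.arange(901.0)


@pytest.fixture
def toy_dataset():
    """Two patients x 9 spectra on a 5-point axis, two classes."""
    axis = np.arange(1000.0, 1005.0)
    spectra = []
    for p, label in (("pA", "control"), ("pB", "GBM")):
        for well in (1, 2, 3):
            for rep in (1, 2, 3):
                base = 1.0 if label == "control" else 2.0
                spectra.append(
                    make_spectrum(
                        axis,
                        base + 0.1 * well + 0.01 * rep + 0.001 * np.arange(5),
                        spectrum_id=f"{p}_w{well}r{rep}",
                        patient_id=p,
                        well=well,
                        replicate=rep,
                        label=label,
                    )
                )
    return SpectralDataset(spectra)


@pytest.fixture(scope="session")
def two_class_cohort():
    """Seeded 8+8-patient control/GBM cohort with default templates."""
    config = CohortConfig(
        profiles={
            "control": (default_profile("control"), 8),
            "GBM": (default_profile("GBM"), 8),
        },
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture
def quiet_profile():
    """Single-band profile with every variance knob at zero."""
    return ClassProfile(
        name="quiet",
        bands=[BandSpec(1655.0, 1.0, 10.0)],
        band_sd=0.0,
        scatter_sd=0.0,
        baseline=(0.0,),
        drift_sd=0.0,
        noise_sd=0.0,
        replicate_sd=0.0,
    )
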