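"""Reading, writing and validation of spectral datasets.

A dataset is stored as a pair of comma-separated text files:

* a *spectra* table whose first column is the wavenumber axis
  (``wavenumber_cm-1``) and whose remaining columns hold one absorbance
  trace each, headed by the spectrum id;
* a *metadata* table with columns ``spectrum_id, patient_id, well,
  replicate, label`` linking every trace to its patient, sample well
  (1..3), acquisition replicate (1..3) and optional class label.

Instruments commonly emit the axis in descending wavenumber order; the
canonical in-memory order is ascending, and files in either order are
accepted and re-ordered consistently on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "read_dataset",
    "write_dataset",
    "ValidationError",
]

WAVENUMBER_COLUMN = "wavenumber_cm-1"
METADATA_COLUMNS = ["spectrum_id", "patient_id", "well", "replicate", "label"]


class ValidationError(ValueError):
    """A spectrum or dataset violates one of its structural invariants."""


@dataclass
class Spectrum:
    """One absorbance trace on a wavenumber axis.

    Parameters
    ----------
    spectrum_id, patient_id
        Free-text identifiers; ``spectrum_id`` must be unique within a dataset.
    well, replicate
        Acquisition position: sample well 1..3 and replicate scan 1..3
        (three wells, each scanned in triplicate, give nine spectra per
        patient).
    wavenumbers
        Strictly monotone axis in cm⁻¹; stored ascending.
    absorbances
        Absorbance values, same length as the axis, all finite.
    label
        Optional class name (e.g. ``"GBM"``, ``"control"``).
    """

    spectrum_id: str
    patient_id: str
    well: int
    replicate: int
    wavenumbers: np.ndarray
    absorbances: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        sid = self.spectrum_id
        if self.wavenumbers.ndim != 1 or self.absorbances.ndim != 1:
            raise ValidationError(f"spectrum {sid!r}: axis and absorbances must be 1-D")
        if len(self.wavenumbers) != len(self.absorbances):
            raise ValidationError(
                f"spectrum {sid!r}: axis length {len(self.wavenumbers)} != "
                f"absorbance length {len(self.absorbances)}"
            )
        if len(self.wavenumbers) < 1:
            raise ValidationError(f"spectrum {sid!r}: needs at least 1 point")
        d = np.diff(self.wavenumbers)
        if d.size and np.all(d < 0):  # descending input: canonicalise to ascending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbances = self.absorbances[::-1].copy()
        elif d.size and not np.all(d > 0):
            raise ValidationError(f"spectrum {sid!r}: wavenumber axis not strictly monotone")
        if not np.all(np.isfinite(self.absorbances)):
            raise ValidationError(f"spectrum {sid!r}: non-finite absorbance values")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError(f"spectrum {sid!r}: non-finite wavenumbers")
        if int(self.well) not in (1, 2, 3):
            raise ValidationError(f"spectrum {sid!r}: well must be 1..3, got {self.well}")
        if int(self.replicate) not in (1, 2, 3):
            raise ValidationError(
                f"spectrum {sid!r}: replicate must be 1..3, got {self.replicate}"
            )
        self.well = int(self.well)
        self.replicate = int(self.replicate)
        if self.label is not None:
            self.label = str(self.label)

    def replace(self, **changes) -> "Spectrum":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass
class SpectralDataset:
    """An aligned collection of spectra sharing one wavenumber axis."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.spectra:
            return
        axis = self.spectra[0].wavenumbers
        seen_ids: set[str] = set()
        seen_triples: set[tuple[str, int, int]] = set()
        patient_label: dict[str, str | None] = {}
        for s in self.spectra:
            if len(s.wavenumbers) != len(axis) or not np.array_equal(s.wavenumbers, axis):
                raise ValidationError(
                    f"spectrum {s.spectrum_id!r}: wavenumber axis differs from the shared axis"
                )
            if s.spectrum_id in seen_ids:
                raise ValidationError(f"duplicate spectrum id {s.spectrum_id!r}")
            seen_ids.add(s.spectrum_id)
            triple = (s.patient_id, s.well, s.replicate)
            if triple in seen_triples:
                raise ValidationError(
                    f"spectrum {s.spectrum_id!r}: duplicate (patient, well, replicate) {triple}"
                )
            seen_triples.add(triple)
            if s.patient_id in patient_label:
                if patient_label[s.patient_id] != s.label:
                    raise ValidationError(
                        f"spectrum {s.spectrum_id!r}: patient {s.patient_id!r} has "
                        f"conflicting labels {patient_label[s.patient_id]!r} and {s.label!r}"
                    )
            else:
                patient_label[s.patient_id] = s.label

    # -- convenience accessors -------------------------------------------------

    @property
    def axis(self) -> np.ndarray:
        if not self.spectra:
            raise ValidationError("empty dataset has no axis")
        return self.spectra[0].wavenumbers

    @property
    def class_names(self) -> list[str]:
        """Distinct labels in first-appearance order (unlabelled excluded)."""
        out: list[str] = []
        for s in self.spectra:
            if s.label is not None and s.label not in out:
                out.append(s.label)
        return out

    @property
    def patient_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.spectra:
            if s.patient_id not in out:
                out.append(s.patient_id)
        return out

    def patient_labels(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {}
        for s in self.spectra:
            out.setdefault(s.patient_id, s.label)
        return out

    def subset_patients(self, patient_ids: Iterable[str]) -> "SpectralDataset":
        wanted = set(patient_ids)
        return SpectralDataset([s for s in self.spectra if s.patient_id in wanted])

    def subset_classes(self, labels: Iterable[str]) -> "SpectralDataset":
        wanted = set(labels)
        return SpectralDataset([s for s in self.spectra if s.label in wanted])

    def absorbance_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) matrix in dataset order."""
        return np.stack([s.absorbances for s in self.spectra])

    def mean_spectrum(self, spectrum_id: str = "mean") -> Spectrum:
        if not self.spectra:
            raise ValidationError("cannot average an empty dataset")
        return Spectrum(
            spectrum_id=spectrum_id,
            patient_id=spectrum_id,
            well=1,
            replicate=1,
            wavenumbers=self.axis.copy(),
            absorbances=self.absorbance_matrix().mean(axis=0),
        )

    def __len__(self) -> int:
        return len(self.spectra)


def read_dataset(spectra_path: str | Path, metadata_path: str | Path) -> SpectralDataset:
    """Read a spectra/metadata CSV pair into a validated :class:`SpectralDataset`.

    The spectra file's first column is the wavenumber axis and each further
    column one spectrum, headed by its id. The metadata file maps each
    spectrum id to patient, well, replicate and (optional) label. Raises
    :class:`ValidationError` on missing ids, non-numeric cells, a
    non-monotone axis or duplicate (patient, well, replicate) triples.
    """
    spectra_df = pd.read_csv(spectra_path)
    if spectra_df.shape[1] < 2:
        raise ValidationError("spectra file must have a wavenumber column plus >= 1 spectrum")
    meta_df = pd.read_csv(
        metadata_path, dtype={"spectrum_id": str, "patient_id": str, "label": str}
    )
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta_df.columns]
    if missing_cols:
        raise ValidationError(f"metadata file missing columns {missing_cols}")

    if len(spectra_df) < 2:
        raise ValidationError("spectra file must contain at least 2 axis points")
    axis_raw = spectra_df.iloc[:, 0].to_numpy()
    try:
        axis = np.asarray(axis_raw, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric wavenumber cell: {exc}") from exc

    columns = {str(c): c for c in spectra_df.columns[1:]}
    meta_ids = list(meta_df["spectrum_id"])
    if len(set(meta_ids)) != len(meta_ids):
        dupes = sorted({i for i in meta_ids if meta_ids.count(i) > 1})
        raise ValidationError(f"duplicate spectrum ids in metadata: {dupes}")
    absent = [sid for sid in meta_ids if sid not in columns]
    if absent:
        raise ValidationError(f"metadata references absent spectrum column(s): {absent}")
    orphan = [sid for sid in columns if sid not in set(meta_ids)]
    if orphan:
        raise ValidationError(f"spectrum column(s) missing from metadata: {orphan}")

    spectra: list[Spectrum] = []
    for row in meta_df.itertuples(index=False):
        sid = str(row.spectrum_id)
        values_raw = spectra_df[columns[sid]].to_numpy()
        try:
            values = np.asarray(values_raw, dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"spectrum {sid!r}: non-numeric absorbance cell ({exc})") from exc
        label = None if pd.isna(row.label) else str(row.label)
        try:
            well = int(row.well)
            replicate = int(row.replicate)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"spectrum {sid!r}: non-integer well/replicate") from exc
        spectra.append(
            Spectrum(
                spectrum_id=sid,
                patient_id=str(row.patient_id),
                well=well,
                replicate=replicate,
                wavenumbers=axis,
                absorbances=values,
                label=label,
            )
        )
    return SpectralDataset(spectra)


def write_dataset(
    dataset: SpectralDataset, spectra_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the CSV pair; ``read_dataset`` round-trips to <= 1e-9 relative."""
    if not dataset.spectra:
        raise ValidationError("refusing to write an empty dataset")
    columns = {WAVENUMBER_COLUMN: dataset.axis}
    columns.update({s.spectrum_id: s.absorbances for s in dataset.spectra})
    spectra_df = pd.DataFrame(columns)
    spectra_df.to_csv(spectra_path, index=False, float_format="%.12g")
    meta_df = pd.DataFrame(
        {
            "spectrum_id": [s.spectrum_id for s in dataset.spectra],
            "patient_id": [s.patient_id for s in dataset.spectra],
            "well": [s.well for s in dataset.spectra],
            "replicate": [s.replicate for s in dataset.spectra],
            "label": [s.label if s.label is not None else "" for s in dataset.spectra],
        }
    )
    meta_df.to_csv(metadata_path, index=False)
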