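"""Raman spectra containers and the CSV dialect used to exchange them.

A batch of spectra is stored wide: one ``wavenumber_cm-1`` column followed by
one intensity column per sample.  Concentration labels live in a separate
two-column CSV (``sample_id,concentration_ppm``) so the spectral matrix stays
purely numeric.  Axis mismatches across files are errors, never interpolation
triggers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import SpectraFormatError

AXIS_COLUMN = "wavenumber_cm-1"
LABEL_COLUMNS = ("sample_id", "concentration_ppm")


@dataclass
class Spectrum:
    """One Raman trace: an axis in cm^-1, intensities in arbitrary units,
    and an optional concentration label in ppm."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    concentration: float | None = None
    sample_id: str = "sample"

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectraFormatError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise SpectraFormatError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavenumbers) < 2:
            raise SpectraFormatError("a spectrum needs at least 2 channels")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectraFormatError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("intensities must be finite")
        if self.concentration is not None and not (
            np.isfinite(self.concentration) and self.concentration >= 0
        ):
            raise SpectraFormatError("concentration must be a finite ppm value >= 0")

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass
class SpectraDataset:
    """Spectra sharing one wavenumber grid, in insertion order."""

    spectra: list[Spectrum] = field(default_factory=list)
    axis: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        if not self.spectra and self.axis.size == 0:
            return
        if self.axis.size == 0 and self.spectra:
            self.axis = self.spectra[0].wavenumbers.copy()
        self.validate()

    def validate(self) -> None:
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise SpectraFormatError("sample_ids must be unique")
        for s in self.spectra:
            if len(s.wavenumbers) != len(self.axis) or not np.array_equal(
                s.wavenumbers, self.axis
            ):
                raise SpectraFormatError(
                    f"spectrum {s.sample_id!r} is not on the shared axis"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def concentrations(self) -> np.ndarray:
        """Per-sample ppm labels; NaN where a sample is unlabeled."""
        return np.array(
            [np.nan if s.concentration is None else s.concentration for s in self.spectra]
        )

    def intensity_matrix(self) -> np.ndarray:
        """(n_samples, n_channels) matrix in insertion order."""
        if not self.spectra:
            return np.empty((0, self.axis.size))
        return np.vstack([s.intensities for s in self.spectra])

    @classmethod
    def from_matrix(
        cls,
        axis: np.ndarray,
        intensities: np.ndarray,
        sample_ids: Sequence[str] | None = None,
        concentrations: Sequence[float | None] | None = None,
    ) -> "SpectraDataset":
        intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        n = intensities.shape[0]
        if sample_ids is None:
            sample_ids = [f"s{i:03d}" for i in range(n)]
        if concentrations is None:
            concentrations = [None] * n
        spectra = [
            Spectrum(axis, intensities[i], concentrations[i], str(sample_ids[i]))
            for i in range(n)
        ]
        return cls(spectra, np.asarray(axis, dtype=float))

    def replace_intensities(self, intensities: np.ndarray) -> "SpectraDataset":
        """New dataset with the same axis/labels and fresh intensities."""
        return SpectraDataset.from_matrix(
            self.axis, intensities, self.sample_ids,
            [s.concentration for s in self.spectra],
        )

    def subset(self, indices: Iterable[int]) -> "SpectraDataset":
        spectra = [self.spectra[i] for i in indices]
        return SpectraDataset(
            [Spectrum(s.wavenumbers, s.intensities, s.concentration, s.sample_id)
             for s in spectra],
            self.axis.copy(),
        )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)


# -- CSV I/O ------------------------------------------------------------------

def read_spectra_csv(path, labels_path=None) -> SpectraDataset:
    """Read a wide spectra CSV (first column ``wavenumber_cm-1``) plus an
    optional two-column labels CSV mapping sample_id -> concentration_ppm.

    Raises
    ------
    SpectraFormatError
        Non-monotone axis, wrong header, ragged columns or non-finite values.
    KeyError
        A label references a sample_id absent from the spectra file.
    """
    frame = pd.read_csv(path)
    if frame.columns.size == 0 or frame.columns[0] != AXIS_COLUMN:
        raise SpectraFormatError(
            f"first column must be {AXIS_COLUMN!r}, got {list(frame.columns[:1])!r}"
        )
    if frame.isna().any().any():
        raise SpectraFormatError(f"{path}: ragged or non-numeric cells detected")
    axis = frame[AXIS_COLUMN].to_numpy(dtype=float)
    sample_ids = list(frame.columns[1:])

    labels: dict[str, float] = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        missing = [c for c in LABEL_COLUMNS if c not in lab.columns]
        if missing:
            raise SpectraFormatError(f"labels file lacks columns {missing}")
        for sid, conc in zip(lab["sample_id"].astype(str), lab["concentration_ppm"]):
            if sid not in sample_ids:
                raise KeyError(f"label for unknown sample_id {sid!r}")
            labels[sid] = float(conc)

    if len(sample_ids) == 0:
        return SpectraDataset([], axis)
    matrix = frame[sample_ids].to_numpy(dtype=float).T
    return SpectraDataset.from_matrix(
        axis, matrix, sample_ids, [labels.get(sid) for sid in sample_ids]
    )


def write_spectra_csv(dataset: SpectraDataset, path, labels_path=None) -> None:
    """Write a dataset in the dialect of :func:`read_spectra_csv`.

    Column order follows insertion order.  An empty dataset yields a
    header-only CSV.  Labels are written only for labeled samples.
    """
    data = {AXIS_COLUMN: dataset.axis}
    for s in dataset:
        data[s.sample_id] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False)

    if labels_path is not None:
        labeled = [(s.sample_id, s.concentration) for s in dataset
                   if s.concentration is not None]
        pd.DataFrame(labeled, columns=list(LABEL_COLUMNS)).to_csv(
            labels_path, index=False
        )
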