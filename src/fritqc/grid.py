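"""Canonical wavelength grid and in-memory spectral containers.

A handheld InGaAs NIR instrument records absorbance on a fixed 900-1700 nm
grid at 1 nm spacing (801 points).  Everything downstream of I/O assumes this
grid, so it is validated aggressively and never silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GridError",
    "FormatError",
    "WavelengthGrid",
    "CANONICAL_GRID",
    "Spectrum",
    "SpectraSet",
    "ORIGIN_NAMES",
]


class GridError(ValueError):
    """Wavelength axis does not match the canonical instrument grid."""


class FormatError(ValueError):
    """A spectra file or container violates the expected layout."""


#: Species names in class-id order (0..3).
ORIGIN_NAMES = (
    "F. cirrhosa",
    "F. ussuriensis",
    "F. pallidiflora",
    "F. thunbergii",
)


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis in nanometres."""

    start_nm: float = 900.0
    end_nm: float = 1700.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start_nm) and np.isfinite(self.end_nm)
                and np.isfinite(self.step_nm)):
            raise GridError("grid bounds must be finite")
        if self.step_nm <= 0 or self.end_nm <= self.start_nm:
            raise GridError("grid must be strictly increasing")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise GridError("grid span is not an integer number of steps")

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact grid wavelength (raises GridError if off-grid)."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if idx < 0 or idx >= self.n_points or abs(pos - idx) > 1e-6:
            raise GridError(f"{wavelength_nm} nm is not on the grid")
        return idx

    def validate_axis(self, values) -> None:
        """Check a wavelength header against this grid, naming the first mismatch."""
        values = np.asarray(values, dtype=float)
        expected = self.wavelengths
        if values.shape != expected.shape:
            # locate the first expected wavelength that is absent
            present = set(np.round(values, 6))
            for w in expected:
                if round(float(w), 6) not in present:
                    raise GridError(
                        f"wavelength axis has {values.size} points, expected "
                        f"{expected.size}; first missing wavelength: {w:g} nm"
                    )
            raise GridError(
                f"wavelength axis has {values.size} points, expected {expected.size}"
            )
        bad = np.nonzero(np.abs(values - expected) > 1e-6)[0]
        if bad.size:
            i = int(bad[0])
            raise GridError(
                f"wavelength axis mismatch at position {i}: found {values[i]:g} nm, "
                f"expected {expected[i]:g} nm"
            )


CANONICAL_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """One absorbance vector on a wavelength grid."""

    absorbance: np.ndarray
    grid: WavelengthGrid = CANONICAL_GRID

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 1:
            raise FormatError("absorbance must be one-dimensional")
        if self.absorbance.size != self.grid.n_points:
            raise GridError(
                f"absorbance length {self.absorbance.size} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise FormatError("absorbance contains non-finite values")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def copy_with(self, absorbance: np.ndarray) -> "Spectrum":
        return Spectrum(np.asarray(absorbance, dtype=float), self.grid)


@dataclass
class SpectraSet:
    """An n x p matrix of spectra with per-row labels.

    ``label_kind`` is ``"origin"`` (integer class ids 0..3) or ``"fraction"``
    (adulteration mass fraction in (0, 1)).  ``batch_ids`` are optional
    per-row integers recording acquisition batch.
    """

    X: np.ndarray
    labels: np.ndarray
    label_kind: str = "origin"
    batch_ids: Optional[np.ndarray] = None
    grid: WavelengthGrid = CANONICAL_GRID
    class_names: tuple = ORIGIN_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise FormatError("X must be a 2-D matrix (rows are spectra)")
        if self.X.shape[1] != self.grid.n_points:
            raise GridError(
                f"spectra have {self.X.shape[1]} points, grid has {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.X)):
            raise FormatError("spectra contain non-finite values")
        if self.label_kind not in ("origin", "fraction"):
            raise FormatError(f"unknown label_kind {self.label_kind!r}")
        dtype = int if self.label_kind == "origin" else float
        self.labels = np.asarray(self.labels, dtype=dtype)
        if self.labels.shape != (self.X.shape[0],):
            raise FormatError("labels must have one entry per spectrum row")
        if self.label_kind == "fraction" and self.labels.size:
            if self.labels.min() < 0 or self.labels.max() > 1:
                raise FormatError("adulteration fractions must lie in [0, 1]")
        if self.batch_ids is not None:
            self.batch_ids = np.asarray(self.batch_ids, dtype=int)
            if self.batch_ids.shape != (self.X.shape[0],):
                raise FormatError("batch_ids must have one entry per spectrum row")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.X[i], self.grid)

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            self.X[idx],
            self.labels[idx],
            label_kind=self.label_kind,
            batch_ids=None if self.batch_ids is None else self.batch_ids[idx],
            grid=self.grid,
            class_names=self.class_names,
            meta=dict(self.meta),
        )

    def with_matrix(self, X: np.ndarray) -> "SpectraSet":
        """Same labels/metadata, new (equally shaped) spectra matrix."""
        return SpectraSet(
            np.asarray(X, dtype=float),
            self.labels,
            label_kind=self.label_kind,
            batch_ids=self.batch_ids,
            grid=self.grid,
            class_names=self.class_names,
            meta=dict(self.meta),
        )

    def class_mean(self, class_id: int) -> Spectrum:
        if self.label_kind != "origin":
            raise FormatError("class_mean requires an origin-labelled set")
        mask = self.labels == class_id
        if not mask.any():
            raise FormatError(f"no spectra with class id {class_id}")
        return Spectrum(self.X[mask].mean(axis=0), self.grid)
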