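"""Core data model for mass-spectrometry-imaging (MSI) datasets.

An MSI dataset is a raster of pixels, each carrying one mass spectrum
(m/z values with non-negative intensities). Downstream analysis works on
a *common representation*: a pixels × features matrix whose feature axis
is either a uniform m/z binning or a picked peak list shared across
samples.

Grid convention: pixel coordinates are 0-based integers ``(x, y)`` with
the origin at the top-left; the physical position of a pixel centre is
``coordinate × pixel_size``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Spectrum",
    "SampleKind",
    "Grade",
    "SampleMeta",
    "MSIDataset",
    "CommonRepresentation",
    "TissueMask",
]


@dataclass(frozen=True)
class Spectrum:
    """A single mass spectrum: strictly increasing m/z, non-negative intensity."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1:
            raise ValidationError("spectrum arrays must be one-dimensional")
        if mz.shape != inten.shape:
            raise ValidationError(
                f"m/z and intensity lengths differ ({mz.size} vs {inten.size})"
            )
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValidationError("m/z values must be strictly increasing")
        if inten.size and np.min(inten) < 0:
            raise ValidationError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        """Total ion current (sum of intensities)."""
        return float(self.intensity.sum())

    def shifted(self, delta_mz: float) -> "Spectrum":
        """Return a copy with a constant additive m/z shift (intensities untouched)."""
        return Spectrum(self.mz + delta_mz, self.intensity)


class SampleKind(str, enum.Enum):
    section = "section"
    replica = "replica"


class Grade(str, enum.Enum):
    low = "low"
    high = "high"


@dataclass
class SampleMeta:
    """Per-sample annotations carried alongside the pixel data.

    ``batch_id`` identifies the imaging session; the grading cross-validation
    excludes training spectra sharing either the test sample's patient or
    its session.
    """

    sample_id: str
    kind: SampleKind
    patient_id: str = ""
    batch_id: str = ""
    grade: Grade | None = None
    timepoint: str | None = None  # "D0" | "D5"
    treatment: str | None = None  # "T0" (control) | "T1" (treated)

    def __post_init__(self) -> None:
        self.kind = SampleKind(self.kind)
        if self.grade is not None and self.grade != "":
            self.grade = Grade(self.grade)
        elif self.grade == "":
            self.grade = None
        for attr in ("timepoint", "treatment"):
            v = getattr(self, attr)
            if v == "":
                setattr(self, attr, None)
        if self.timepoint is not None and self.timepoint not in ("D0", "D5"):
            raise ValidationError(f"timepoint must be D0 or D5, got {self.timepoint!r}")
        if self.treatment is not None and self.treatment not in ("T0", "T1"):
            raise ValidationError(f"treatment must be T0 or T1, got {self.treatment!r}")

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "patient_id": self.patient_id,
            "batch_id": self.batch_id,
            "kind": self.kind.value,
            "grade": self.grade.value if self.grade else "",
            "timepoint": self.timepoint or "",
            "treatment": self.treatment or "",
        }

    @classmethod
    def from_row(cls, row: Mapping) -> "SampleMeta":
        def opt(key):
            v = row.get(key, "")
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return ""
            return str(v)

        return cls(
            sample_id=str(row["sample_id"]),
            kind=SampleKind(str(row["kind"])),
            patient_id=opt("patient_id"),
            batch_id=opt("batch_id"),
            grade=opt("grade") or None,
            timepoint=opt("timepoint") or None,
            treatment=opt("treatment") or None,
        )


class MSIDataset:
    """Pixel-indexed raw spectra with sample metadata.

    Parameters
    ----------
    coords:
        Integer array of shape (n_pixels, 2) holding (x, y) grid coordinates.
    spectra:
        One :class:`Spectrum` per pixel, in the same order as ``coords``.
    pixel_size:
        Edge length of a pixel in micrometres (µm).
    meta:
        Sample-level annotations.
    """

    def __init__(
        self,
        coords: np.ndarray,
        spectra: list[Spectrum],
        pixel_size: float,
        meta: SampleMeta | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
        if coords.shape[0] != len(spectra):
            raise ValidationError("coords and spectra counts differ")
        if coords.size and coords.min() < 0:
            raise ValidationError("grid coordinates must be non-negative")
        if pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        uniq = {tuple(c) for c in coords.tolist()}
        if len(uniq) != coords.shape[0]:
            raise ValidationError("duplicate pixel coordinates")
        self.coords = coords
        self.spectra = list(spectra)
        self.pixel_size = float(pixel_size)
        self.meta = meta if meta is not None else SampleMeta("unnamed", SampleKind.section)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[tuple[tuple[int, int], Spectrum]]:
        for (x, y), s in zip(self.coords.tolist(), self.spectra):
            yield (x, y), s

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx) extent of the bounding grid (0 origin)."""
        if not len(self):
            return (0, 0)
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def tic_per_pixel(self) -> np.ndarray:
        return np.array([s.tic for s in self.spectra])


@dataclass
class CommonRepresentation:
    """Pixels × features matrix on a shared m/z feature axis.

    ``mode`` is ``"binned"`` (features are centres of a uniform bin axis) or
    ``"peaks"`` (features are picked peak apex m/z values). ``provenance``
    records the preprocessing parameters that produced the matrix.
    """

    matrix: np.ndarray
    feature_mz: np.ndarray
    coords: np.ndarray
    mode: str = "binned"
    pixel_size: float = 100.0
    meta: SampleMeta | None = None
    provenance: dict = field(default_factory=dict)
    zero_tic: np.ndarray | None = None  # flag per pixel, set by TIC normalization

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if self.matrix.ndim != 2:
            raise ValidationError("matrix must be 2-D (pixels × features)")
        if self.matrix.shape[1] != self.feature_mz.size:
            raise ValidationError("column count must equal feature axis length")
        if self.matrix.shape[0] != self.coords.shape[0]:
            raise ValidationError("row count must equal pixel count")
        if self.feature_mz.size > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValidationError("feature m/z axis must be strictly increasing")
        if self.mode not in ("binned", "peaks"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        if not self.n_pixels:
            return (0, 0)
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def copy_with(self, matrix: np.ndarray, **prov) -> "CommonRepresentation":
        """New representation with the same axes and updated provenance."""
        provenance = dict(self.provenance)
        provenance.update(prov)
        return CommonRepresentation(
            matrix=matrix,
            feature_mz=self.feature_mz,
            coords=self.coords,
            mode=self.mode,
            pixel_size=self.pixel_size,
            meta=self.meta,
            provenance=provenance,
            zero_tic=self.zero_tic,
        )

    def to_image(self, column: int) -> np.ndarray:
        """Render one feature column as a 2-D image (NaN outside recorded pixels)."""
        ny, nx = self.grid_shape
        img = np.full((ny, nx), np.nan)
        img[self.coords[:, 1], self.coords[:, 0]] = self.matrix[:, column]
        return img


@dataclass
class TissueMask:
    """Boolean per-pixel tissue indicator on the dataset's bounding grid."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValidationError("mask grid must be 2-D")

    def pixel_flags(self, coords: np.ndarray) -> np.ndarray:
        """Per-pixel tissue flag in the order of ``coords`` rows."""
        coords = np.asarray(coords, dtype=np.int64)
        return self.grid[coords[:, 1], coords[:, 0]]

    @property
    def n_tissue(self) -> int:
        return int(self.grid.sum())
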