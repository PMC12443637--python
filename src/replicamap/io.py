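"""I/O: imzML interchange, sidecar metadata tables, and HDF5 result bundles.

imzML (with its binary ``.ibd`` companion) is the interchange format for
MSI data; sample-level annotations that imzML has no slots for
(patient, imaging session, specimen kind, grade, timepoint, treatment)
travel in a sidecar CSV keyed by ``sample_id``. Derived artefacts
(representations, masks, result tables) round-trip through a single-file
HDF5 bundle with an explicit schema version.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import CommonRepresentation, MSIDataset, SampleMeta, Spectrum, TissueMask
from .errors import FormatError, ValidationError

__all__ = [
    "read_imzml",
    "write_imzml",
    "read_metadata_csv",
    "write_metadata_csv",
    "save_bundle",
    "load_bundle",
    "BUNDLE_SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

BUNDLE_SCHEMA_VERSION = 1

METADATA_COLUMNS = [
    "sample_id",
    "patient_id",
    "batch_id",
    "kind",
    "grade",
    "timepoint",
    "treatment",
]


#: sentinel encoding of a zero-length spectrum (imzML writers cannot store
#: truly empty arrays); converted back to an empty spectrum on read
_EMPTY_SENTINEL = (np.array([0.0]), np.array([0.0]))


def write_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write a dataset as a processed-mode imzML/ibd pair.

    Returns the path of the ``.imzML`` file. imzML coordinates are 1-based;
    the package's 0-based grid coordinates are shifted on write and
    shifted back on read, so round trips are exact. Zero-length spectra
    are stored as a single zero-intensity point at m/z 0 and restored to
    empty on read.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    try:
        if len(dataset) == 0:
            return _write_empty_imzml(path)
        with ImzMLWriter(
            str(path),
            mode="processed",
            mz_dtype=np.float64,
            intensity_dtype=np.float64,
        ) as writer:
            for (x, y), spec in dataset:
                mz, inten = (spec.mz, spec.intensity) if len(spec) else _EMPTY_SENTINEL
                writer.addSpectrum(mz, inten, (x + 1, y + 1, 1))
    except OSError as exc:  # unwritable path
        raise FormatError(f"cannot write imzML to {path}: {exc}") from exc
    return path


def _write_empty_imzml(path: Path) -> Path:
    """A schema-valid imzML/ibd pair containing zero spectra.

    The writer library computes pixel extents over the spectra and so
    cannot emit the degenerate file itself; a one-spectrum document is
    written and the spectrum element stripped, the ibd truncated to its
    16-byte UUID header.
    """
    import re

    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(
        str(path), mode="processed", mz_dtype=np.float64, intensity_dtype=np.float64
    ) as writer:
        writer.addSpectrum(*_EMPTY_SENTINEL, (1, 1, 1))
    xml = path.read_text()
    xml = re.sub(r"<spectrum\b.*?</spectrum>\s*", "", xml, flags=re.S)
    xml = xml.replace('<spectrumList count="1"', '<spectrumList count="0"')
    path.write_text(xml)
    ibd = path.with_suffix(".ibd")
    ibd.write_bytes(ibd.read_bytes()[:16])
    return path


def read_imzml(path: str | Path, meta: SampleMeta | None = None) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Accepts both continuous and processed mode. ``meta`` may supply the
    sample annotations (e.g. looked up from a sidecar CSV); otherwise the
    file stem is used as the sample id.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"imzML file not found: {path}")
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FormatError(f"missing binary companion {ibd}")
    if '<spectrumList count="0"' in path.read_text():
        if meta is None:
            meta = SampleMeta(sample_id=path.stem, kind="section")
        return MSIDataset(np.empty((0, 2), dtype=np.int64), [], 100.0, meta)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parser = ImzMLParser(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    coords = []
    spectra = []
    n_empty = 0
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, intens = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        intens = np.asarray(intens, dtype=float)
        if mzs.size == 1 and mzs[0] == 0.0 and intens[0] == 0.0:
            mzs, intens = np.array([]), np.array([])  # empty-spectrum sentinel
        if mzs.size == 0:
            n_empty += 1
        if mzs.size > 1 and not np.all(np.diff(mzs) > 0):
            raise ValidationError(f"non-monotone m/z axis in spectrum {i} of {path}")
        coords.append((x - 1, y - 1))
        spectra.append(Spectrum(mzs, intens))
    if n_empty:
        logger.warning("%s: %d empty spectra retained", path.name, n_empty)

    # pixel size from the scan settings if present, else 100 µm
    pixel_size = 100.0
    try:
        pix = parser.imzmldict.get("pixel size x")
        if pix:
            pixel_size = float(pix)
    except Exception:
        pass
    if meta is None:
        meta = SampleMeta(sample_id=path.stem, kind="section")
    return MSIDataset(np.array(coords).reshape(-1, 2), spectra, pixel_size, meta)


def write_metadata_csv(metas: list[SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([m.to_row() for m in metas], columns=METADATA_COLUMNS).to_csv(
        path, index=False
    )
    return path


def read_metadata_csv(path: str | Path) -> dict[str, SampleMeta]:
    """Load the sidecar table as a mapping sample_id → :class:`SampleMeta`."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"sample_id", "kind"} - set(df.columns)
    if missing:
        raise FormatError(f"metadata CSV lacks required columns: {sorted(missing)}")
    return {row["sample_id"]: SampleMeta.from_row(row) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# HDF5 bundles


def save_bundle(obj, path: str | Path) -> Path:
    """Serialize a representation, mask, or DataFrame to an HDF5 bundle."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = BUNDLE_SCHEMA_VERSION
        if isinstance(obj, CommonRepresentation):
            f.attrs["kind"] = "representation"
            g = f.create_group("representation")
            g.create_dataset("matrix", data=obj.matrix)
            g.create_dataset("feature_mz", data=obj.feature_mz)
            g.create_dataset("coords", data=obj.coords)
            g.attrs["mode"] = obj.mode
            g.attrs["pixel_size"] = obj.pixel_size
            g.attrs["provenance"] = json.dumps(obj.provenance)
            if obj.zero_tic is not None:
                g.create_dataset("zero_tic", data=obj.zero_tic)
            if obj.meta is not None:
                g.attrs["meta"] = json.dumps(obj.meta.to_row())
        elif isinstance(obj, TissueMask):
            f.attrs["kind"] = "mask"
            f.create_dataset("grid", data=obj.grid)
        elif isinstance(obj, pd.DataFrame):
            f.attrs["kind"] = "table"
            g = f.create_group("table")
            g.attrs["columns"] = json.dumps(list(obj.columns))
            for col in obj.columns:
                values = obj[col].to_numpy()
                if values.dtype == object:
                    values = values.astype("S")
                g.create_dataset(str(col), data=values)
        else:
            raise ValidationError(f"cannot bundle object of type {type(obj).__name__}")
    return path


def load_bundle(path: str | Path):
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != BUNDLE_SCHEMA_VERSION:
            raise FormatError(
                f"bundle schema version {version} incompatible with "
                f"supported version {BUNDLE_SCHEMA_VERSION}"
            )
        kind = f.attrs["kind"]
        if kind == "representation":
            g = f["representation"]
            meta = None
            if "meta" in g.attrs:
                meta = SampleMeta.from_row(json.loads(g.attrs["meta"]))
            return CommonRepresentation(
                matrix=g["matrix"][...],
                feature_mz=g["feature_mz"][...],
                coords=g["coords"][...],
                mode=str(g.attrs["mode"]),
                pixel_size=float(g.attrs["pixel_size"]),
                meta=meta,
                provenance=json.loads(g.attrs["provenance"]),
                zero_tic=g["zero_tic"][...] if "zero_tic" in g else None,
            )
        if kind == "mask":
            return TissueMask(f["grid"][...])
        if kind == "table":
            g = f["table"]
            columns = json.loads(g.attrs["columns"])
            data = {}
            for col in columns:
                values = g[str(col)][...]
                if values.dtype.kind == "S":
                    values = values.astype(str)
                data[col] = values
            return pd.DataFrame(data, columns=columns)
        raise FormatError(f"unknown bundle kind {kind!r}")
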