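"""CSV import/export for labelled spectra sets.

Layout (wide, one row per spectrum, matching instrument-export convention):

    sample_id,label,species,batch,900,901,...,1700      (origin sets)
    sample_id,label,batch,900,901,...,1700              (fraction sets)

``label`` holds the integer class id for origin sets (with the species name
echoed in ``species``) or the decimal adulteration fraction (0.05, never
percent) for mixture sets.  Absorbance values are written with 17 significant
digits so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CANONICAL_GRID, FormatError, GridError, SpectraSet, ORIGIN_NAMES

__all__ = ["read_spectra_csv", "write_spectra_csv"]

_META_COLS = ("sample_id", "label", "species", "batch")


def write_spectra_csv(spectra: SpectraSet, path) -> Path:
    """Write a SpectraSet to ``path``; returns the path written."""
    path = Path(path)
    wl = spectra.grid.wavelengths
    header = ["sample_id", "label"]
    if spectra.label_kind == "origin":
        header.append("species")
    if spectra.batch_ids is not None:
        header.append("batch")
    header += [f"{w:g}" for w in wl]
    try:
        fh = path.open("w", newline="", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write spectra CSV to {path}: {exc}") from exc
    with fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(spectra.n):
            row = [str(i)]
            if spectra.label_kind == "origin":
                cid = int(spectra.labels[i])
                row.append(str(cid))
                row.append(spectra.class_names[cid] if cid < len(spectra.class_names)
                           else f"class_{cid}")
            else:
                row.append(repr(float(spectra.labels[i])))
            if spectra.batch_ids is not None:
                row.append(str(int(spectra.batch_ids[i])))
            row += [f"{v:.17g}" for v in spectra.X[i]]
            writer.writerow(row)
    return path


def read_spectra_csv(path, grid=CANONICAL_GRID) -> SpectraSet:
    """Read a SpectraSet written by :func:`write_spectra_csv`.

    The wavelength header is validated against the canonical grid; any
    permutation, truncation or off-grid axis is rejected (never resampled).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    if "label" not in df.columns or "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required 'sample_id'/'label' columns")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        axis = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header: {exc}") from exc
    grid.validate_axis(axis)  # raises GridError with the first mismatch named

    try:
        X = df[wl_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric absorbance value: {exc}") from exc

    label_kind = "origin" if "species" in df.columns else "fraction"
    try:
        if label_kind == "origin":
            labels = df["label"].to_numpy(dtype=int)
        else:
            labels = df["label"].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: bad label column: {exc}") from exc

    batch_ids = None
    if "batch" in df.columns:
        batch_ids = df["batch"].to_numpy(dtype=int)

    class_names = ORIGIN_NAMES
    if label_kind == "origin" and len(df):
        seen = {}
        for cid, name in zip(labels, df["species"]):
            seen[int(cid)] = str(name)
        if seen:
            class_names = tuple(
                seen.get(i, ORIGIN_NAMES[i] if i < len(ORIGIN_NAMES) else f"class_{i}")
                for i in range(max(seen) + 1)
            )

    return SpectraSet(
        X,
        labels,
        label_kind=label_kind,
        batch_ids=batch_ids,
        grid=grid,
        class_names=class_names,
        meta={"source": str(path)},
    )
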