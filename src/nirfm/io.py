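"""File I/O: wide-CSV spectra, minimal ENVI cubes, PNG + CSV truth masks.

Spectra travel as UTF-8 comma-separated files with '.' decimals, one row per
sample: ``sample_id,label,<λ1>,<λ2>,...`` with numeric wavelengths in the
header.  Cubes use the de-facto ENVI container: a plain-text ``.hdr`` next to
a raw BSQ float32 payload.  Ground-truth object masks are single-channel PNGs
(0 = background, object ids >= 1) with a CSV mapping object id -> class.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import (
    Hypercube,
    SpectraFormatError,
    SpectraSet,
    TruthObject,
    WavelengthGrid,
)

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_envi_cube",
    "write_envi_cube",
    "read_truth_masks",
    "write_truth_masks",
]


def write_spectra_csv(S: SpectraSet, path: str | os.PathLike) -> None:
    """Write a SpectraSet as a wide CSV, round-trippable to ~1e-15."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "label"] + [repr(float(v)) for v in S.grid.values]
        )
        for i in range(S.n_samples):
            writer.writerow(
                [S.sample_ids[i], int(S.labels[i])]
                + [repr(float(v)) for v in S.absorbance[i]]
            )


def read_spectra_csv(path: str | os.PathLike) -> SpectraSet:
    """Read a wide spectra CSV written by :func:`write_spectra_csv`.

    Raises :class:`~nirfm.core.SpectraFormatError` naming the offending row
    or column on malformed headers, labels outside {0, 1}, or ragged rows.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectraFormatError(f"{path}: empty file") from None
        if len(header) < 4 or header[0] != "sample_id" or header[1] != "label":
            raise SpectraFormatError(
                f"{path}: header must start with sample_id,label and carry "
                "at least two wavelengths"
            )
        try:
            wavelengths = np.array([float(v) for v in header[2:]])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: non-numeric wavelength header: {exc}")
        try:
            grid = WavelengthGrid(wavelengths)
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: bad wavelength header: {exc}")

        ids: list[str] = []
        labels: list[int] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise SpectraFormatError(
                    f"{path}: row {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            if row[1] not in ("0", "1"):
                raise SpectraFormatError(
                    f"{path}: row {lineno} has label {row[1]!r}, must be 0 or 1"
                )
            try:
                values = [float(v) for v in row[2:]]
            except ValueError as exc:
                raise SpectraFormatError(f"{path}: row {lineno}: {exc}")
            ids.append(row[0])
            labels.append(int(row[1]))
            rows.append(values)

    absorbance = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(grid)), dtype=float)
    )
    return SpectraSet(
        grid=grid,
        absorbance=absorbance,
        labels=np.array(labels, dtype=int),
        sample_ids=ids,
    )


# --- ENVI cubes -------------------------------------------------------------
#
# Only the subset of the ENVI dialect this package writes is supported:
# BSQ interleave, IEEE float32 (data type 4), little endian, a wavelength
# block in nanometres.

_ENVI_DTYPE = 4  # float32


def write_envi_cube(cube: Hypercube, header_path: str | os.PathLike) -> None:
    """Write an ENVI header (+ ``.img`` payload next to it).

    Truth objects are not serialised here; see :func:`write_truth_masks`.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        raise ValueError("ENVI header path must end in .hdr")
    data_path = header_path.with_suffix(".img")
    lines, pixels, bands = cube.data.shape
    wl = ", ".join(f"{v:.6f}" for v in cube.band_centers.values)
    header = (
        "ENVI\n"
        "description = {nirfm simulated line-scan cube}\n"
        f"samples = {pixels}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header, encoding="utf-8")
    # BSQ: band-sequential — transpose (lines, pixels, bands) -> (bands, lines, pixels)
    np.ascontiguousarray(
        cube.data.transpose(2, 0, 1), dtype="<f4"
    ).tofile(data_path)


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            for cont in lines:
                parts.append(cont)
                if "}" in cont:
                    break
            value = " ".join(parts)
        fields[key] = value
    return fields


def read_envi_cube(header_path: str | os.PathLike) -> Hypercube:
    """Read a BSQ float32 ENVI cube written by :func:`write_envi_cube`."""
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text(encoding="utf-8"))
    for required in ("samples", "lines", "bands"):
        if required not in fields:
            raise SpectraFormatError(f"{header_path}: missing '{required}'")
    if "wavelength" not in fields:
        raise SpectraFormatError(
            f"{header_path}: missing 'wavelength' metadata"
        )
    if int(fields.get("data type", "4")) != _ENVI_DTYPE:
        raise SpectraFormatError(f"{header_path}: only data type 4 supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise SpectraFormatError(f"{header_path}: only BSQ interleave supported")
    pixels = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    wl_text = fields["wavelength"].strip().strip("{}")
    band_centers = WavelengthGrid(
        np.array([float(v) for v in wl_text.split(",") if v.strip()])
    )
    if len(band_centers) != bands:
        raise SpectraFormatError(
            f"{header_path}: {bands} bands but {len(band_centers)} wavelengths"
        )
    data_path = header_path.with_suffix(".img")
    if not data_path.exists():
        raise FileNotFoundError(data_path)
    raw = np.fromfile(data_path, dtype="<f4")
    if raw.size != lines * pixels * bands:
        raise SpectraFormatError(
            f"{data_path}: payload size {raw.size} does not match "
            f"{lines}x{pixels}x{bands}"
        )
    data = raw.reshape(bands, lines, pixels).transpose(1, 2, 0)
    return Hypercube(data=np.asarray(data, dtype=float), band_centers=band_centers)


# --- Truth masks ------------------------------------------------------------


def write_truth_masks(
    objects: list[TruthObject], png_path: str | os.PathLike,
    classes_csv_path: str | os.PathLike,
) -> None:
    """Write truth objects as a uint16 label PNG plus an id->class CSV."""
    if not objects:
        raise ValueError("no truth objects to write")
    label_img = np.zeros(objects[0].mask.shape, dtype=np.uint16)
    for obj in objects:
        if obj.object_id < 1:
            raise ValueError("object ids must be >= 1 (0 is background)")
        label_img[obj.mask] = obj.object_id
    iio.imwrite(Path(png_path), label_img)
    pd.DataFrame(
        {"object_id": [o.object_id for o in objects],
         "class": [o.cls for o in objects]}
    ).to_csv(classes_csv_path, index=False)


def read_truth_masks(
    png_path: str | os.PathLike, classes_csv_path: str | os.PathLike
) -> list[TruthObject]:
    label_img = np.asarray(iio.imread(Path(png_path)))
    table = pd.read_csv(classes_csv_path)
    objects = []
    for _, row in table.iterrows():
        oid = int(row["object_id"])
        mask = label_img == oid
        if not mask.any():
            raise SpectraFormatError(
                f"object {oid} listed in {classes_csv_path} has no pixels"
            )
        objects.append(TruthObject(object_id=oid, cls=str(row["class"]), mask=mask))
    return objects
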