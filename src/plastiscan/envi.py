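"""ENVI hyperspectral cube I/O with wavenumber calibration.

Implements the subset of the ENVI standard that FTIR imaging instruments
emit: an ASCII header (``.hdr``) describing a flat binary payload in BSQ,
BIL or BIP interleave, float32 or float64 samples, little or big endian.
Band centers are read from a ``wavelength`` (or ``wavenumber``) block and
interpreted as cm^-1.

Coordinate convention used throughout the package: ``(row, col)``, origin
at the top-left pixel, 0-based. The in-memory cube is indexed
``(row, col, band)`` regardless of the on-disk interleave.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "WavenumberAxis",
    "HyperspectralImage",
    "EnviHeader",
    "EnviFormatError",
    "UnsupportedDataTypeError",
    "CorruptFileError",
    "parse_envi_header",
    "read_envi",
    "write_envi",
    "default_axis",
]

# ENVI data type codes restricted to floating cubes; instrument exports of
# absorbance images use float, and integer raster types are out of scope.
_DTYPES = {4: np.dtype("float32"), 5: np.dtype("float64")}
_DTYPE_CODES = {v: k for k, v in _DTYPES.items()}

_MANDATORY = ("samples", "lines", "bands", "interleave", "data type")

_WAVENUMBER_UNITS = {"", "1/cm", "cm-1", "cm^-1", "wavenumber", "wavenumbers"}


class EnviFormatError(ValueError):
    """Malformed or incomplete ENVI header."""


class UnsupportedDataTypeError(EnviFormatError):
    """Header declares a data type code this reader does not support."""


class CorruptFileError(IOError):
    """Binary payload inconsistent with the header."""


def default_axis(start: float = 1250.0, step: float = 4.0, n_bands: int = 587) -> "WavenumberAxis":
    """Measurement grid synthesized when a header carries no band centers.

    The default covers 1250..3594 cm^-1 in 4 cm^-1 steps (587 bands), the
    grid of a typical FPA-based uFTIR transmission measurement.
    """
    return WavenumberAxis(start + step * np.arange(n_bands))


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotone, positive band-center grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("axis must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavenumbers must be finite and positive")
        d = np.diff(v)
        if v.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def ascending(self) -> bool:
        return len(self) < 2 or self.values[1] > self.values[0]

    @property
    def lo(self) -> float:
        return float(self.values.min())

    @property
    def hi(self) -> float:
        return float(self.values.max())


@dataclass
class HyperspectralImage:
    """Absorbance cube ``(row, col, band)`` with its wavenumber axis.

    ``pixel_pitch`` is the physical edge length of a pixel in micrometers
    (e.g. ~11 um for a 64x64 FPA detector).
    """

    cube: np.ndarray
    axis: WavenumberAxis
    pixel_pitch: float = 11.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        if self.cube.ndim != 3:
            raise ValueError("cube must be (rows, cols, bands)")
        if self.cube.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {self.cube.shape[2]} bands but axis has {len(self.axis)}"
            )
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if not np.all(np.isfinite(self.cube)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0] * self.cube.shape[1]


@dataclass
class EnviHeader:
    samples: int
    lines: int
    bands: int
    interleave: str
    data_type: int
    byte_order: int = 0
    header_offset: int = 0
    wavelengths: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        """(lines, samples, bands) == (rows, cols, bands)."""
        return (self.lines, self.samples, self.bands)

    @property
    def dtype(self) -> np.dtype:
        dt = _DTYPES[self.data_type]
        return dt.newbyteorder(">" if self.byte_order == 1 else "<")


def _tokenize_header(text: str) -> dict[str, str]:
    # key = value pairs; values in { } may span lines
    body = text
    if body.lstrip().lower().startswith("envi"):
        body = body.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([^={}\n][^=\n]*?)\s*=\s*", re.M)
    pos = 0
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        rest = body[m.end():]
        if rest.lstrip().startswith("{"):
            close = rest.index("}")
            value = rest.lstrip()[1:close - (len(rest) - len(rest.lstrip()))]
            pos = m.end() + close + 1
        else:
            eol = rest.find("\n")
            eol = len(rest) if eol < 0 else eol
            value = rest[:eol]
            pos = m.end() + eol
        fields[key] = value.strip()
    return fields


def parse_envi_header(text: str) -> EnviHeader:
    """Parse ENVI header text into a structured record.

    Raises :class:`EnviFormatError` naming the first missing mandatory key,
    and :class:`UnsupportedDataTypeError` for non-float data type codes.
    """
    fields = _tokenize_header(text)
    for key in _MANDATORY:
        if key not in fields:
            raise EnviFormatError(f"ENVI header is missing mandatory key '{key}'")

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        data_type = int(fields["data type"])
    except ValueError as exc:
        raise EnviFormatError(f"non-integer value in ENVI header: {exc}") from exc

    if data_type not in _DTYPES:
        raise UnsupportedDataTypeError(
            f"ENVI data type code {data_type} not supported (float codes 4 and 5 only)"
        )

    interleave = fields["interleave"].strip().lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unknown interleave '{interleave}'")

    byte_order = int(fields.get("byte order", "0"))
    if byte_order not in (0, 1):
        raise EnviFormatError(f"byte order must be 0 or 1, got {byte_order}")

    wavelengths = None
    wl_key = "wavelength" if "wavelength" in fields else (
        "wavenumber" if "wavenumber" in fields else None
    )
    if wl_key is not None:
        units = fields.get("wavelength units", "").strip().lower()
        if units not in _WAVENUMBER_UNITS:
            raise EnviFormatError(
                f"unsupported wavelength units '{units}' (expected wavenumbers, cm^-1)"
            )
        try:
            wavelengths = np.array(
                [float(tok) for tok in re.split(r"[,\s]+", fields[wl_key]) if tok],
                dtype=float,
            )
        except ValueError as exc:
            raise EnviFormatError(f"malformed band-center list: {exc}") from exc
        if wavelengths.size != bands:
            raise EnviFormatError(
                f"{wavelengths.size} band centers for {bands} bands"
            )

    known = {*_MANDATORY, "byte order", "header offset", "wavelength",
             "wavenumber", "wavelength units"}
    meta = {k: v for k, v in fields.items() if k not in known}

    return EnviHeader(
        samples=samples,
        lines=lines,
        bands=bands,
        interleave=interleave,
        data_type=data_type,
        byte_order=byte_order,
        header_offset=int(fields.get("header offset", "0")),
        wavelengths=wavelengths,
        metadata=meta,
    )


# axis order of each interleave relative to the in-memory (row, col, band) cube
_INTERLEAVE_AXES = {
    "bsq": (2, 0, 1),  # band, line, sample
    "bil": (0, 2, 1),  # line, band, sample
    "bip": (0, 1, 2),  # line, sample, band
}


def read_envi(
    header_path: str | os.PathLike,
    data_path: str | os.PathLike | None = None,
    *,
    pixel_pitch: float = 11.0,
    transmittance: bool = False,
) -> HyperspectralImage:
    """Read a paired ENVI header + binary payload into a cube.

    The cube is returned in ``(row, col, band)`` order whatever the on-disk
    interleave. If the header carries no band centers a default wavenumber
    grid is synthesized. With ``transmittance=True`` the payload is
    converted to absorbance via ``-log10``.
    """
    header_path = os.fspath(header_path)
    if data_path is None:
        data_path = re.sub(r"\.hdr$", "", header_path)
        if data_path == header_path:
            raise ValueError("cannot infer data path; pass data_path explicitly")
    with open(header_path, "r") as fh:
        hdr = parse_envi_header(fh.read())

    itemsize = hdr.dtype.itemsize
    expected = hdr.samples * hdr.lines * hdr.bands * itemsize
    found = os.path.getsize(data_path) - hdr.header_offset
    if found != expected:
        raise CorruptFileError(
            f"ENVI payload size mismatch: expected {expected} bytes "
            f"({hdr.lines}x{hdr.samples}x{hdr.bands} x {itemsize}B), found {found}"
        )

    raw = np.fromfile(data_path, dtype=hdr.dtype, offset=hdr.header_offset)
    rows, cols, bands = hdr.dims
    axes = _INTERLEAVE_AXES[hdr.interleave]
    disk_shape = tuple((rows, cols, bands)[a] for a in axes)
    cube = raw.reshape(disk_shape).transpose(np.argsort(axes))

    if hdr.wavelengths is not None:
        axis = WavenumberAxis(hdr.wavelengths)
    else:
        axis = default_axis(n_bands=bands)

    cube = np.ascontiguousarray(cube)
    if transmittance:
        cube = -np.log10(np.clip(cube, 1e-12, None))

    return HyperspectralImage(
        cube=cube, axis=axis, pixel_pitch=pixel_pitch, metadata=dict(hdr.metadata)
    )


def write_envi(
    img: HyperspectralImage,
    header_path: str | os.PathLike,
    data_path: str | os.PathLike | None = None,
    *,
    interleave: str = "bsq",
    dtype: str | np.dtype = "float32",
    byte_order: int = 0,
) -> None:
    """Write a cube as ENVI header + flat binary; round-trips value-exactly.

    Note the default float32 on-disk type truncates a float64 cube; pass
    ``dtype='float64'`` for an exact round trip of double-precision data.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVE_AXES:
        raise ValueError(f"unknown interleave '{interleave}'")
    dt = np.dtype(dtype)
    if dt not in _DTYPE_CODES:
        raise ValueError("on-disk dtype must be float32 or float64")
    dt = dt.newbyteorder(">" if byte_order == 1 else "<")

    header_path = os.fspath(header_path)
    if data_path is None:
        data_path = re.sub(r"\.hdr$", "", header_path)
        if data_path == header_path:
            raise ValueError("cannot infer data path; pass data_path explicitly")

    rows, cols, bands = img.shape
    axes = _INTERLEAVE_AXES[interleave]
    payload = np.ascontiguousarray(img.cube.transpose(axes), dtype=dt)

    wl = ", ".join(repr(float(v)) for v in img.axis.values)
    lines = [
        "ENVI",
        "description = {plastiscan export}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        f"byte order = {byte_order}",
        "wavelength units = 1/cm",
        "wavelength = {" + wl + "}",
    ]
    for key, val in img.metadata.items():
        if key.lower() not in ("description",):
            lines.append(f"{key} = {val}")

    with open(header_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    payload.tofile(data_path)
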