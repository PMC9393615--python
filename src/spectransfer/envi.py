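"""Minimal ENVI cube I/O: BIL interleave, float32, text header.

Covers exactly what the pipeline needs — writing rendered cubes and reading
them back with their wavelength metadata.  Header fields beyond the ones
written here are ignored on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .preprocess import SpectralCube

_DTYPES = {4: np.float32, 5: np.float64}


def write_envi(path: str | Path, cube: SpectralCube) -> None:
    """Write ``<path>`` (binary BIL) and ``<path>.hdr`` (text header)."""
    path = Path(path)
    rows, cols, bands = cube.values.shape
    header = "\n".join(
        [
            "ENVI",
            "file type = ENVI Standard",
            f"samples = {cols}",
            f"lines = {rows}",
            f"bands = {bands}",
            "header offset = 0",
            "data type = 4",
            "interleave = bil",
            "byte order = 0",
            "wavelength units = Nanometers",
            "wavelength = {" + ", ".join(f"{w:g}" for w in cube.wavelengths) + "}",
            "",
        ]
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)
    # BIL: line-major, then band, then sample
    cube.values.transpose(0, 2, 1).astype(np.float32).tofile(path)


def _header_fields(text: str) -> dict[str, str]:
    # join brace-delimited multi-line values before splitting on lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str | Path, kind: str = "raw") -> SpectralCube:
    path = Path(path)
    hdr = path.with_suffix(path.suffix + ".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr}")
    fields = _header_fields(hdr.read_text())
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bil").lower()
    if interleave != "bil":
        raise ValueError(f"only BIL interleave supported, got {interleave!r}")
    dtype = _DTYPES.get(int(fields.get("data type", "4")))
    if dtype is None:
        raise ValueError("only float32/float64 ENVI data supported")
    wl_match = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
    if not wl_match:
        raise ValueError("header has no wavelength list")
    wavelengths = np.array([float(v) for v in wl_match.group(1).split(",")])
    data = np.fromfile(path, dtype=dtype)
    if data.size != rows * cols * bands:
        raise ValueError("ENVI data size does not match header dimensions")
    values = data.reshape(rows, bands, cols).transpose(0, 2, 1).astype(float)
    return SpectralCube(values, wavelengths, kind=kind)
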