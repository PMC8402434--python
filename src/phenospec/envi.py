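"""ENVI-convention cube I/O, white/dark reflectance calibration and band cropping.

The ENVI format stores a cube as a raw little-endian binary file plus a
plain-text header declaring ``samples`` (columns), ``lines`` (rows),
``bands``, the byte ``interleave`` (``bil``/``bip``/``bsq``), the data
type and a wavelength list. Push-broom imagers write one spatial line at
a time; calibration to reflectance uses co-acquired white (high
reflectance standard) and dark (shutter closed) references:

    R = (S - D) / (W - D)

per pixel and band, clamped to a non-negative range.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .containers import HyperCube

__all__ = ["read_envi", "write_envi", "calibrate_reflectance", "crop_bands"]

# ENVI numeric codes for the dtypes this package reads/writes.
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict; ``{...}`` blocks become lists."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        raw = m.group(2).strip()
        if raw.startswith("{"):
            items = [s.strip() for s in raw[1:-1].replace("\n", " ").split(",")]
            fields[key] = [s for s in items if s]
        else:
            fields[key] = raw
    return fields


def read_envi(header_path, data_path=None) -> HyperCube:
    """Read an ENVI header/raw pair into a ``(lines, samples, bands)`` cube.

    ``data_path`` defaults to the header path with its suffix replaced by
    ``.raw``. All three interleaves materialise to the same in-memory order.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".raw")
    fields = _parse_header(header_path.read_text())

    for req in ("samples", "lines", "bands", "interleave", "data type"):
        if req not in fields:
            raise ValueError(f"ENVI header missing required field '{req}'")
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = str(fields["interleave"]).lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}; expected one of {_INTERLEAVES}")
    code = int(fields["data type"])
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    if int(fields.get("byte order", 0)) != 0:
        raise ValueError("only little-endian (byte order = 0) files are supported")

    wavelengths = np.asarray([float(w) for w in fields["wavelength"]])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    raw = np.fromfile(Path(data_path), dtype=_DTYPES[code])
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"file holds {raw.size} values but header implies {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )

    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    units = "reflectance" if np.dtype(_DTYPES[code]).kind == "f" else "raw"
    meta = {
        k: v
        for k, v in fields.items()
        if k not in ("samples", "lines", "bands", "interleave", "data type", "byte order", "wavelength", "header offset")
    }
    return HyperCube(np.ascontiguousarray(data), wavelengths, units=units, metadata=meta)


def write_envi(cube: HyperCube, header_path, data_path=None, interleave: str = "bil") -> None:
    """Write a cube as an ENVI header/raw pair (little-endian)."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".raw")

    data = cube.data
    dtype = np.dtype(data.dtype)
    if dtype not in _DTYPE_CODES:
        # standard convention: reflectance as float32, raw counts as uint16
        dtype = np.dtype(np.float32 if dtype.kind == "f" else np.uint16)
    lines, samples, bands = data.shape

    if interleave == "bip":
        out = data
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:  # bsq
        out = data.transpose(2, 0, 1)

    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    extra = "".join(f"{k} = {v}\n" for k, v in cube.metadata.items() if isinstance(v, str))
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"{extra}"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(out, dtype=dtype).tofile(Path(data_path))


def _reference_band_means(ref: HyperCube) -> np.ndarray:
    """Average a reference cube over its spatial extent -> per-band vector."""
    return ref.data.reshape(-1, ref.n_bands).mean(axis=0)


def calibrate_reflectance(
    raw: HyperCube, white: HyperCube, dark: HyperCube, clip_max: float = 2.0
) -> HyperCube:
    """Convert raw counts to reflectance via R = (S - D) / (W - D).

    White and dark references may be single-line strips or full cubes; they
    are averaged over their spatial extent band-wise before division
    (standard push-broom practice, reduces reference noise). The result is
    clamped to ``[0, clip_max]`` since detector noise can push S below D.
    """
    for ref, name in ((white, "white"), (dark, "dark")):
        if ref.n_bands != raw.n_bands or not np.allclose(ref.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} reference band axis does not match the raw cube")
    w = _reference_band_means(white)
    d = _reference_band_means(dark)
    denom = w - d
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        b = int(bad[0])
        raise ValueError(
            f"white minus dark reference is non-positive at band {b} "
            f"({raw.wavelengths[b]:.1f} nm); check reference acquisition"
        )
    refl = (raw.data.astype(np.float64) - d) / denom
    refl = np.clip(refl, 0.0, clip_max)
    return HyperCube(
        refl.astype(np.float32),
        raw.wavelengths,
        units="reflectance",
        metadata=dict(raw.metadata),
    )


def crop_bands(cube: HyperCube, lambda_min: float, lambda_max: float) -> HyperCube:
    """Retain only bands with lambda_min <= wavelength <= lambda_max (nm)."""
    if lambda_min > lambda_max:
        raise ValueError("lambda_min must not exceed lambda_max")
    keep = (cube.wavelengths >= lambda_min) & (cube.wavelengths <= lambda_max)
    if not keep.any():
        raise ValueError(
            f"no bands inside [{lambda_min}, {lambda_max}] nm "
            f"(cube spans {cube.wavelengths[0]:.1f}-{cube.wavelengths[-1]:.1f} nm)"
        )
    return HyperCube(
        cube.data[:, :, keep],
        cube.wavelengths[keep],
        units=cube.units,
        metadata=dict(cube.metadata),
    )
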