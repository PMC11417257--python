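"""Plain-text readers/writers for the four measurement modalities.

File dialects (all plain text, tab-separated, '#'-prefixed headers):

* topography: ``# rows R`` / ``# cols C`` / ``# pixel_size_um P`` (one value for
  square pixels, two for rectangular), body of whitespace-separated heights in
  nm.  TIFF import/export (32-bit float, nm) is provided via tifffile.
* force-distance: ``# spring_constant_nN_per_nm K`` followed by
  ``# branch approach`` and ``# branch retract`` blocks of
  displacement_nm / force_nN pairs.
* tensile and spectrum: generic two-column x/y text with one column-naming
  header line and optional ``# key value`` metadata lines.
* manifest: CSV via pandas.

A minimal JCAMP-DX reader (``##XYDATA=(X++(Y..Y))``, fixed point, AFFN) covers
real instrument exports of transmittance spectra.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ForceDistanceCurve, Spectrum, TensileCurve, TopographyImage
from .errors import DataFormatError

__all__ = [
    "write_topography_txt",
    "read_topography_txt",
    "write_topography_tiff",
    "read_topography_tiff",
    "write_fd_txt",
    "read_fd_txt",
    "write_xy_txt",
    "read_xy_txt",
    "write_tensile_txt",
    "read_tensile_txt",
    "write_spectrum_txt",
    "read_spectrum_txt",
    "read_jcamp",
]


# ---------------------------------------------------------------- topography

def write_topography_txt(image: TopographyImage, path: str | Path) -> None:
    path = Path(path)
    rows, cols = image.shape
    pr, pc = image.pixel_size
    px = f"{pr!r}" if pr == pc else f"{pr!r} {pc!r}"
    header = f"# rows {rows}\n# cols {cols}\n# pixel_size_um {px}\n# units nm\n"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, image.heights, fmt="%.6f")


def read_topography_txt(path: str | Path) -> TopographyImage:
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            parts = line[1:].split(None, 1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1].strip()
    try:
        rows = int(meta["rows"])
        cols = int(meta["cols"])
        px = [float(v) for v in meta["pixel_size_um"].split()]
    except (KeyError, ValueError) as exc:
        raise DataFormatError(f"{path}: malformed topography header") from exc
    heights = np.loadtxt(path, comments="#", ndmin=2)
    if heights.shape != (rows, cols):
        raise DataFormatError(
            f"{path}: body shape {heights.shape} does not match header ({rows}, {cols})"
        )
    pixel_size = (px[0], px[0]) if len(px) == 1 else (px[0], px[1])
    return TopographyImage(heights, pixel_size, source_id=path.stem)


def write_topography_tiff(image: TopographyImage, path: str | Path) -> None:
    """32-bit float TIFF, heights in nm; pixel size kept in the description tag."""
    import tifffile

    desc = json.dumps({"pixel_size_um": list(image.pixel_size), "units": "nm"})
    tifffile.imwrite(path, image.heights.astype(np.float32), description=desc)


def read_topography_tiff(path: str | Path, pixel_size: float | None = None) -> TopographyImage:
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        heights = tif.pages[0].asarray().astype(float)
        desc = tif.pages[0].description or ""
    px: tuple[float, float] | None = None
    if desc:
        try:
            meta = json.loads(desc)
            px = tuple(meta["pixel_size_um"])  # type: ignore[assignment]
        except (json.JSONDecodeError, KeyError, TypeError):
            px = None
    if px is None:
        if pixel_size is None:
            raise DataFormatError(f"{path}: TIFF carries no pixel size; pass pixel_size=")
        px = (float(pixel_size), float(pixel_size))
    return TopographyImage(heights, px, source_id=path.stem)


# ------------------------------------------------------------ force-distance

def write_fd_txt(curve: ForceDistanceCurve, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# spring_constant_nN_per_nm {curve.spring_constant!r}\n")
        fh.write("# displacement_nm\tforce_nN\n")
        for name, branch in (("approach", curve.approach), ("retract", curve.retract)):
            fh.write(f"# branch {name}\n")
            np.savetxt(fh, branch, fmt="%.6f", delimiter="\t")


def read_fd_txt(path: str | Path) -> ForceDistanceCurve:
    path = Path(path)
    spring = None
    branches: dict[str, list[list[float]]] = {}
    current: list[list[float]] | None = None
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["spring_constant_nN_per_nm"]:
                    spring = float(parts[1])
                elif parts[:1] == ["branch"]:
                    current = branches.setdefault(parts[1], [])
                continue
            if current is None:
                raise DataFormatError(f"{path}: data before any '# branch' header")
            vals = line.split()
            if len(vals) != 2:
                raise DataFormatError(f"{path}: expected two columns, got {line!r}")
            current.append([float(vals[0]), float(vals[1])])
    if spring is None:
        raise DataFormatError(f"{path}: missing '# spring_constant_nN_per_nm'")
    if "approach" not in branches or "retract" not in branches:
        raise DataFormatError(f"{path}: both approach and retract branches are required")
    return ForceDistanceCurve(
        np.array(branches["approach"]),
        np.array(branches["retract"]),
        spring,
        source_id=path.stem,
    )


# ------------------------------------------------------------- generic x/y

def write_xy_txt(
    x: np.ndarray,
    y: np.ndarray,
    path: str | Path,
    columns: tuple[str, str],
    meta: dict[str, float] | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key} {value!r}\n")
        fh.write(f"# {columns[0]}\t{columns[1]}\n")
        np.savetxt(fh, np.column_stack([x, y]), fmt="%.8g", delimiter="\t")


def read_xy_txt(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split(None, 1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1].strip()
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 2:
        raise DataFormatError(f"{path}: expected two columns")
    return data[:, 0], data[:, 1], meta


def write_tensile_txt(curve: TensileCurve, force_mN: np.ndarray, path: str | Path) -> None:
    """Store the raw strain/force record; stress is recomputed on read."""
    write_xy_txt(
        curve.strain,
        force_mN,
        path,
        columns=("strain", "force_mN"),
        meta={"diameter_um": curve.diameter, "gauge_force_mN": curve.gauge_force},
    )


def read_tensile_txt(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Returns (strain, force_mN, diameter_um, gauge_force_mN)."""
    strain, force, meta = read_xy_txt(path)
    try:
        diameter = float(meta["diameter_um"])
    except (KeyError, ValueError) as exc:
        raise DataFormatError(f"{path}: missing '# diameter_um' header") from exc
    gauge = float(meta.get("gauge_force_mN", 0.0))
    return strain, force, diameter, gauge


def write_spectrum_txt(spectrum: Spectrum, path: str | Path) -> None:
    write_xy_txt(
        spectrum.wavenumbers,
        spectrum.transmittance,
        path,
        columns=("wavenumber_cm-1", "transmittance_pct"),
    )


def read_spectrum_txt(path: str | Path) -> Spectrum:
    path = Path(path)
    x, y, _ = read_xy_txt(path)
    order = np.argsort(x)
    return Spectrum(x[order], y[order], source_id=path.stem)


# ----------------------------------------------------------------- JCAMP-DX

def read_jcamp(path: str | Path) -> Spectrum:
    """Read a fixed-point JCAMP-DX ``##XYDATA=(X++(Y..Y))`` transmittance block.

    Supports the AFFN (plain-number) form with XFACTOR/YFACTOR scaling, which
    covers the common instrument-export case; compressed (SQZ/DIF/DUP) forms
    are out of scope.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
            fields[key] = value.strip()
            continue
        if in_data and line:
            data_lines.append(line)
    if not data_lines:
        raise DataFormatError(f"{path}: no ##XYDATA block found")
    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        vals = line.replace(",", " ").split()
        try:
            x0 = float(vals[0])
            yvals = [float(v) for v in vals[1:]]
        except ValueError as exc:
            raise DataFormatError(f"{path}: non-numeric JCAMP data line {line!r}") from exc
        if not yvals:
            continue
        # X of subsequent Y values on the line advances by the nominal deltax
        deltax = float(fields.get("DELTAX", 0.0))
        if deltax == 0.0 and "FIRSTX" in fields and "LASTX" in fields and "NPOINTS" in fields:
            npts = int(float(fields["NPOINTS"]))
            if npts > 1:
                deltax = (float(fields["LASTX"]) - float(fields["FIRSTX"])) / (npts - 1) / xfactor
        for i, yv in enumerate(yvals):
            xs.append((x0 + i * deltax) * xfactor)
            ys.append(yv * yfactor)
    x = np.array(xs)
    y = np.array(ys)
    order = np.argsort(x)
    return Spectrum(x[order], y[order], source_id=path.stem)


# ------------------------------------------------------------------ manifest

def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
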