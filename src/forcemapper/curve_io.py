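"""Reading, writing and normalisation of force-distance curves.

AFM force-volume experiments export one force-distance curve per grid
point, typically as a plain-text file with comment headers and two numeric
columns (tip-sample separation and vertical force).  This module parses
such exports into :class:`ForceCurve` objects in fixed working units
(separation in nm, force in nN), selects the approach segment, and
assembles rectangular grids of curves (:class:`ForceGrid`).
"""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CurveFormatError",
    "CurveValidationError",
    "Dialect",
    "ForceCurve",
    "ForceGrid",
    "read_force_curve",
    "write_force_curve",
    "read_force_grid",
    "write_force_grid",
    "grid_spacing",
]


class CurveFormatError(ValueError):
    """Raised when a curve file cannot be parsed at all."""


class CurveValidationError(ValueError):
    """Raised when parsed data violate basic physical sanity checks."""


# Values smaller than this in magnitude are taken to be SI (metres /
# newtons) rather than nm / nN; biologically meaningful separations and
# breakthrough forces are never below a micro-unit on the nm/nN scale.
_SI_MAGNITUDE_CUTOFF = 1e-3


@dataclass
class Dialect:
    """Text layout of an exported curve file.

    Parameters
    ----------
    comment_prefix : str
        Lines starting with this prefix are ignored.
    delimiter : str or None
        Column delimiter; ``None`` means any whitespace run.
    z_col, f_col : int
        Zero-based column indices of separation and force.
    """

    comment_prefix: str = "#"
    delimiter: str | None = None
    z_col: int = 0
    f_col: int = 1


@dataclass
class ForceCurve:
    """One force-distance curve in working units (z in nm, F in nN).

    ``z`` is ordered along the approach: it decreases (weakly) toward the
    support.  ``grid_index`` is ``(row, col)`` when the curve belongs to a
    force-volume grid.
    """

    z: np.ndarray
    F: np.ndarray
    grid_index: tuple[int, int] | None = None
    segment: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.z.ndim != 1 or self.F.ndim != 1:
            raise CurveValidationError("z and F must be one-dimensional")
        if len(self.z) != len(self.F):
            raise CurveValidationError(
                f"z and F lengths differ ({len(self.z)} vs {len(self.F)})"
            )
        if len(self.z) < 2:
            raise CurveValidationError("a force curve needs at least 2 samples")
        if not (np.isfinite(self.z).all() and np.isfinite(self.F).all()):
            raise CurveValidationError("non-finite values in force curve")

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class ForceGrid:
    """Rectangular grid of force curves over a square scan region.

    ``physical_size`` is ``(width, height)`` in µm.  Cells without a
    measured curve are simply absent from ``curves``; downstream maps flag
    them as missing.
    """

    n_rows: int
    n_cols: int
    physical_size: tuple[float, float]
    curves: dict[tuple[int, int], ForceCurve] = field(default_factory=dict)
    acquisition_order: str = "raster"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.acquisition_order not in ("raster", "serpentine"):
            raise ValueError(f"unknown acquisition order {self.acquisition_order!r}")
        w, h = self.physical_size
        if w <= 0 or h <= 0:
            raise ValueError("physical size must be positive")
        for (r, c) in self.curves:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"cell index {(r, c)} outside {self.n_rows}x{self.n_cols} grid")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_order(self) -> list[tuple[int, int]]:
        """Cell indices in acquisition order."""
        cells = []
        for r in range(self.n_rows):
            cols = range(self.n_cols)
            if self.acquisition_order == "serpentine" and r % 2 == 1:
                cols = reversed(cols)  # type: ignore[assignment]
            cells.extend((r, c) for c in cols)
        return cells


def grid_spacing(grid: ForceGrid) -> float:
    """Distance in µm between neighbouring measurement points.

    A 5 µm field divided into a 16-wide grid gives 0.3125 µm spacing.
    """
    if grid.n_cols == 0:
        raise ValueError("grid has zero columns")
    return grid.physical_size[0] / grid.n_cols


def _normalize_units(z: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Instrument software may export SI metres/newtons; auto-convert to
    # nm/nN when every magnitude sits below the SI cutoff.
    z = z.copy()
    F = F.copy()
    if np.max(np.abs(z)) < _SI_MAGNITUDE_CUTOFF:
        z *= 1e9
    if np.max(np.abs(F)) < _SI_MAGNITUDE_CUTOFF and np.any(F != 0):
        F *= 1e9
    return z, F


def _select_segment(z: np.ndarray, F: np.ndarray, segment: str) -> tuple[np.ndarray, np.ndarray, str]:
    """Isolate one segment of a curve that may contain extend + retract.

    The approach (extend) block is the one where z decreases toward the
    support; if the file stores approach in ascending z order it is
    reversed so downstream code can assume descending z.
    """
    n = len(z)
    i_min = int(np.argmin(z))
    z_span = float(np.max(z) - np.min(z))
    has_two = (
        0 < i_min < n - 1
        and z[0] - z[i_min] > 0.05 * z_span
        and z[-1] - z[i_min] > 0.05 * z_span
    )
    if segment == "retract":
        if has_two:
            z, F = z[i_min:], F[i_min:]
        if z[0] < z[-1]:  # store retract descending too, for symmetry
            z, F = z[::-1], F[::-1]
        return z, F, "retract"
    # approach (default)
    if has_two:
        z, F = z[: i_min + 1], F[: i_min + 1]
    if z[0] < z[-1]:
        z, F = z[::-1], F[::-1]
    return z, F, "approach"


def read_force_curve(
    source,
    dialect: Dialect | None = None,
    segment: str = "approach",
    source_id: str | None = None,
) -> ForceCurve:
    """Parse one exported force curve into working units.

    Parameters
    ----------
    source : path or text stream
        Plain-text export: comment headers plus two (or more) numeric
        columns.
    dialect : Dialect
        Column layout; default whitespace-separated, ``#`` comments,
        column 0 = separation, column 1 = force.
    segment : {"approach", "retract"}
        Segment to keep when the file contains both.
    """
    dialect = dialect or Dialect()
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        text = path.read_text()
        sid = source_id if source_id is not None else path.name
    else:
        text = source.read()
        sid = source_id or ""

    zs: list[float] = []
    fs: list[float] = []
    needed = max(dialect.z_col, dialect.f_col) + 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(dialect.comment_prefix):
            continue
        parts = stripped.split(dialect.delimiter)
        if len(parts) < needed:
            raise CurveFormatError(
                f"line {lineno}: expected at least {needed} columns, got {len(parts)}"
            )
        try:
            zval = float(parts[dialect.z_col])
            fval = float(parts[dialect.f_col])
        except ValueError as exc:
            raise CurveFormatError(f"line {lineno}: non-numeric value ({exc})") from exc
        if not (np.isfinite(zval) and np.isfinite(fval)):
            raise CurveValidationError(f"line {lineno}: non-finite value in curve data")
        zs.append(zval)
        fs.append(fval)

    if len(zs) < 2:
        raise CurveFormatError(f"fewer than 2 numeric rows in curve source {sid!r}")

    z, F = _normalize_units(np.array(zs), np.array(fs))
    z, F, seg = _select_segment(z, F, segment)
    return ForceCurve(z=z, F=F, segment=seg, source_id=sid)


def write_force_curve(curve: ForceCurve, target) -> None:
    """Write a curve as TSV (z_nm, F_nN) with a comment header."""
    header = (
        "# force-distance curve\n"
        f"# source_id: {curve.source_id}\n"
        f"# segment: {curve.segment}\n"
        "# columns: z_nm\tF_nN\n"
    )
    # shortest representation that round-trips the float exactly
    body = "\n".join(f"{float(z)!r}\t{float(f)!r}" for z, f in zip(curve.z, curve.F))
    text = header + body + "\n"
    if isinstance(target, (str, os.PathLike)):
        Path(target).write_text(text)
    else:
        target.write(text)


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def read_force_grid(
    path,
    n_rows: int,
    n_cols: int,
    physical_size: float | tuple[float, float],
    acquisition_order: str = "raster",
    manifest=None,
    dialect: Dialect | None = None,
    pattern: str = "*.txt",
) -> ForceGrid:
    """Load a directory of curve files into a :class:`ForceGrid`.

    Without a manifest, files matching ``pattern`` are sorted naturally
    and mapped to cells in acquisition order (row-major raster by
    default).  A manifest CSV with columns ``filename,row,col`` overrides
    the positional mapping.  Cells without a file stay empty.
    """
    if isinstance(physical_size, (int, float)):
        physical_size = (float(physical_size), float(physical_size))
    directory = Path(path)
    grid = ForceGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        physical_size=physical_size,
        acquisition_order=acquisition_order,
    )

    if manifest is not None:
        with open(manifest, newline="") as fh:
            rows = list(csv.DictReader(fh))
        seen: dict[tuple[int, int], str] = {}
        for rec in rows:
            cell = (int(rec["row"]), int(rec["col"]))
            if cell in seen:
                raise ValueError(
                    f"manifest maps both {seen[cell]!r} and {rec['filename']!r} to cell {cell}"
                )
            seen[cell] = rec["filename"]
            curve = read_force_curve(directory / rec["filename"], dialect=dialect)
            grid.curves[cell] = replace(curve, grid_index=cell)
        return grid

    files = sorted((p for p in directory.glob(pattern) if p.is_file()),
                   key=lambda p: _natural_key(p.name))
    cells = grid.cell_order()
    if len(files) > len(cells):
        raise ValueError(
            f"{len(files)} curve files for a {n_rows}x{n_cols} grid ({len(cells)} cells)"
        )
    for cell, fpath in zip(cells, files):
        curve = read_force_curve(fpath, dialect=dialect)
        grid.curves[cell] = replace(curve, grid_index=cell)
    return grid


def write_force_grid(grid: ForceGrid, directory) -> Path:
    """Write each curve as a TSV file plus a ``manifest.csv`` mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "row", "col"])
        for (r, c), curve in sorted(grid.curves.items()):
            fname = f"curve_r{r:03d}_c{c:03d}.txt"
            write_force_curve(curve, directory / fname)
            writer.writerow([fname, r, c])
    return manifest
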