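"""Spatial force and thickness maps.

Per-cell breakthrough events are assembled back onto the acquisition
grid, producing a matrix of force (nN) or thickness (nm) values with an
explicit per-cell status flag: ``ok``, ``missing`` (no surviving event —
rendered black, as rupture may not have occurred or not been detected)
or ``multiple`` (more than one event of the chosen rank).  Missing cells
are stored as flags plus NaN placeholders, never as sentinel numbers, so
map statistics stay uncontaminated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .curve_io import ForceGrid
from .events import BreakthroughEvent

__all__ = ["ForceMap", "assemble_map", "map_to_rgba", "map_to_image", "save_map", "load_map"]

FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_MULTIPLE = "multiple"


@dataclass
class ForceMap:
    """A per-cell scalar map over the force-volume grid."""

    values: np.ndarray  # float matrix, NaN where missing
    flags: np.ndarray  # str matrix: ok | missing | multiple
    channel: str  # force | thickness
    rank_used: str  # primary | secondary
    physical_size: tuple[float, float]  # µm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.flags = np.asarray(self.flags, dtype="<U8")
        if self.values.shape != self.flags.shape:
            raise ValueError("values and flags must have the same shape")
        missing = self.flags == FLAG_MISSING
        if not np.isnan(self.values[missing]).all():
            raise ValueError("missing cells must carry no numeric value")
        if np.isnan(self.values[~missing]).any():
            raise ValueError("non-missing cells must carry a numeric value")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def spacing(self) -> float:
        return self.physical_size[0] / self.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ForceMap):
            return NotImplemented
        return (
            self.channel == other.channel
            and self.rank_used == other.rank_used
            and self.physical_size == other.physical_size
            and np.array_equal(self.values, other.values, equal_nan=True)
            and np.array_equal(self.flags, other.flags)
        )


def assemble_map(
    grid: ForceGrid,
    events_by_cell: Mapping[tuple[int, int], Sequence[BreakthroughEvent]],
    channel: str = "force",
    rank_used: str = "primary",
) -> ForceMap:
    """Build a spatial map from per-cell event lists.

    Each cell takes the requested channel (force or thickness) of its
    first event of ``rank_used``; cells without such an event are flagged
    missing, cells with several are flagged multiple (first one wins).
    """
    if channel not in ("force", "thickness"):
        raise ValueError("channel must be 'force' or 'thickness'")
    if rank_used not in ("primary", "secondary"):
        raise ValueError("rank_used must be 'primary' or 'secondary'")
    values = np.full(grid.shape, np.nan)
    flags = np.full(grid.shape, FLAG_MISSING, dtype="<U8")
    for cell, events in events_by_cell.items():
        r, c = cell
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
            raise ValueError(f"event cell {cell} outside {grid.n_rows}x{grid.n_cols} grid")
        chosen = [e for e in events if e.rank == rank_used]
        if not chosen:
            continue
        values[r, c] = getattr(chosen[0], channel)
        flags[r, c] = FLAG_MULTIPLE if len(chosen) > 1 else FLAG_OK
    return ForceMap(values, flags, channel, rank_used, tuple(grid.physical_size))


def map_to_rgba(
    fmap: ForceMap,
    value_range: tuple[float, float] | None = None,
    cmap: str = "viridis",
) -> np.ndarray:
    """Per-cell RGBA colours; missing cells are black.

    ``value_range`` fixes the colour-bar limits (default: observed
    min/max of the non-missing cells).
    """
    if value_range is not None:
        vmin, vmax = value_range
        if vmin > vmax:
            raise ValueError(f"inverted value range {value_range}")
    else:
        finite = fmap.values[~np.isnan(fmap.values)]
        if finite.size:
            vmin, vmax = float(finite.min()), float(finite.max())
        else:
            vmin, vmax = 0.0, 1.0
    masked = np.ma.masked_invalid(fmap.values)
    colormap = plt.get_cmap(cmap).copy()
    colormap.set_bad(color="black")
    norm = matplotlib.colors.Normalize(vmin=vmin, vmax=vmax)
    return colormap(norm(masked))


def map_to_image(
    fmap: ForceMap,
    value_range: tuple[float, float] | None = None,
    cmap: str = "viridis",
    path: str | Path | None = None,
    formats: Sequence[str] = ("png",),
    title: str | None = None,
):
    """Render the map with matplotlib; optionally save as png/pdf/svg.

    Returns the figure.  When ``path`` is given (without extension) one
    file per requested format is written next to it.
    """
    rgba = map_to_rgba(fmap, value_range=value_range, cmap=cmap)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    w, h = fmap.physical_size
    ax.imshow(rgba, origin="upper", extent=(0, w, h, 0), interpolation="nearest")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    unit = "nN" if fmap.channel == "force" else "nm"
    ax.set_title(title or f"{fmap.channel} map ({fmap.rank_used}, {unit})")
    if path is not None:
        base = Path(path)
        base.parent.mkdir(parents=True, exist_ok=True)
        for fmt in formats:
            fig.savefig(base.with_suffix(f".{fmt}"), dpi=150)
    return fig


def save_map(fmap: ForceMap, basepath: str | Path) -> list[Path]:
    """Persist a map as <base>.values.csv, <base>.flags.csv, <base>.meta.json."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    vpath = base.with_suffix(".values.csv")
    fpath = base.with_suffix(".flags.csv")
    mpath = base.with_suffix(".meta.json")
    np.savetxt(vpath, fmap.values, delimiter=",", fmt="%.9g")
    np.savetxt(fpath, fmap.flags, delimiter=",", fmt="%s")
    mpath.write_text(
        json.dumps(
            {
                "channel": fmap.channel,
                "rank_used": fmap.rank_used,
                "physical_size": list(fmap.physical_size),
            },
            indent=2,
        )
    )
    return [vpath, fpath, mpath]


def load_map(basepath: str | Path) -> ForceMap:
    """Inverse of :func:`save_map`."""
    base = Path(basepath)
    values = np.loadtxt(base.with_suffix(".values.csv"), delimiter=",", ndmin=2)
    flags = np.loadtxt(base.with_suffix(".flags.csv"), delimiter=",", dtype="<U8", ndmin=2)
    meta = json.loads(base.with_suffix(".meta.json").read_text())
    return ForceMap(
        values, flags, meta["channel"], meta["rank_used"], tuple(meta["physical_size"])
    )
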