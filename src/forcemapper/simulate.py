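"""Synthetic force curves, force-volume grids and domain images.

Every stage of the analysis can be exercised without an instrument: the
generators here build approach curves with a known breakthrough, grids
with a known two-phase layout, and height images with analytically known
domain shapes, each alongside a ground-truth record sufficient to score
the downstream analysis.

A simulated approach curve follows the standard picture of bilayer
rupture: zero force until tip-membrane contact, a linear indentation ramp
until the load reaches the breakthrough force, then a discontinuity in
which the tip traverses the membrane — rendered as a z-jump at constant
force whose z-extent *is* the membrane thickness — and finally a steep
repulsive wall on the solid support.  Gaussian force noise is added on
top.  The model deliberately ignores contact mechanics (Hertz/DMT),
adhesion and hydration layers: it targets detector validation, not
force-curve physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curve_io import ForceCurve, ForceGrid
from .morphology import HeightImage

__all__ = [
    "CurveSimParams",
    "CurveTruth",
    "MapSimParams",
    "GridTruth",
    "simulate_force_curve",
    "simulate_force_grid",
    "simulate_domain_image",
    "ellipse_perimeter",
]

# Default per-phase breakthrough distributions for two-phase grids:
# Ld (DOPC-rich): soft and thin; Lo (SM/Chol-rich): stiffer and thicker,
# with a sub-nm mean thickness mismatch as seen for PC/SM/Chol bilayers.
LD_FORCE = (3.0, 0.3)  # nN (mean, SD)
LO_FORCE = (6.0, 0.3)
LD_THICKNESS = (2.2, 0.2)  # nm
LO_THICKNESS = (3.0, 0.2)


@dataclass
class CurveSimParams:
    """Parameters of one simulated approach curve.

    ``z_range`` is the total z travel in nm (400 nm is a typical piezo
    ramp for bilayer force volume); ``n_samples`` = 2000 keeps the
    z-quantisation near 0.2 nm, far below the 1.5 nm thickness floor of
    the event filter.  ``support_stiffness`` is the post-rupture slope on
    the hard support.
    """

    contact_z: float = 15.0  # nm, tip-membrane contact
    indentation_stiffness: float = 1.0  # nN/nm
    breakthrough_force: float = 3.0  # nN
    thickness: float = 4.0  # nm
    noise_sd: float = 0.02  # nN
    n_samples: int = 2000
    z_range: float = 400.0  # nm
    support_stiffness: float = 10.0  # nN/nm
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.breakthrough_force <= 0:
            raise ValueError("breakthrough_force must be positive")
        if not (0 < self.thickness < self.contact_z):
            raise ValueError("need 0 < thickness < contact_z")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.indentation_stiffness <= 0 or self.support_stiffness <= 0:
            raise ValueError("stiffnesses must be positive")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")
        if self.z_range <= self.contact_z:
            raise ValueError("z_range must exceed contact_z")
        ramp = self.breakthrough_force / self.indentation_stiffness
        if self.contact_z - ramp - self.thickness <= 0:
            raise ValueError(
                "breakthrough not reachable: contact_z too small for the "
                "requested force, stiffness and thickness"
            )


@dataclass(frozen=True)
class CurveTruth:
    """Ground truth of a simulated curve."""

    breakthrough_force: float  # nN
    thickness: float  # nm
    z_onset: float  # nm, rupture onset
    z_completion: float  # nm, tip reaches the support


def simulate_force_curve(params: CurveSimParams | None = None, **kwargs) -> tuple[ForceCurve, CurveTruth]:
    """Simulate one approach curve with a single breakthrough.

    The z grid is a descending linspace over [0, z_range] with the two
    samples nearest the rupture corners snapped onto the exact corner
    positions, so that in the noiseless case the detector can recover
    force and thickness exactly.  Deterministic given ``params.seed``.
    """
    if params is None:
        params = CurveSimParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword overrides, not both")

    k = params.indentation_stiffness
    z_onset = params.contact_z - params.breakthrough_force / k
    z_completion = z_onset - params.thickness

    z = np.linspace(params.z_range, 0.0, params.n_samples)
    # snap nearest grid samples onto the exact rupture corners
    for corner in (z_onset, z_completion):
        z[int(np.argmin(np.abs(z - corner)))] = corner
    z = np.sort(z)[::-1]

    F = np.zeros_like(z)
    ramp = (z <= params.contact_z) & (z >= z_onset)
    F[ramp] = k * (params.contact_z - z[ramp])
    plateau = (z < z_onset) & (z >= z_completion)
    F[plateau] = params.breakthrough_force
    wall = z < z_completion
    F[wall] = params.breakthrough_force + params.support_stiffness * (z_completion - z[wall])

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        F = F + rng.normal(0.0, params.noise_sd, size=F.shape)

    curve = ForceCurve(z=z, F=F, segment="approach", source_id=f"sim-seed{params.seed}")
    truth = CurveTruth(
        breakthrough_force=params.breakthrough_force,
        thickness=params.thickness,
        z_onset=z_onset,
        z_completion=z_completion,
    )
    return curve, truth


@dataclass
class MapSimParams:
    """Parameters of a simulated two-phase force-volume grid.

    The default layout places two non-overlapping circular Lo domains
    (radius 1.4 µm) on a 5 µm field sampled by a 16 x 16 grid, giving an
    Lo area fraction near one half — the regime where both phases are
    well represented.  ``discs`` are (centre_x, centre_y, radius) in µm.
    """

    n_rows: int = 16
    n_cols: int = 16
    physical_size: float = 5.0  # µm (square field)
    discs: tuple[tuple[float, float, float], ...] = ((1.5, 1.5, 1.4), (3.5, 3.5, 1.4))
    ld_force: tuple[float, float] = LD_FORCE
    lo_force: tuple[float, float] = LO_FORCE
    ld_thickness: tuple[float, float] = LD_THICKNESS
    lo_thickness: tuple[float, float] = LO_THICKNESS
    noise_sd: float = 0.02  # nN, per-sample force noise
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.physical_size <= 0:
            raise ValueError("physical_size must be positive")
        for cx, cy, r in self.discs:
            if r <= 0:
                raise ValueError("disc radius must be positive")
            if not (0 <= cx <= self.physical_size and 0 <= cy <= self.physical_size):
                raise ValueError("disc centre outside the field")
        for mean, sd in (self.ld_force, self.lo_force, self.ld_thickness, self.lo_thickness):
            if sd < 0 or mean <= 0:
                raise ValueError("phase distributions need positive mean and SD >= 0")


@dataclass
class GridTruth:
    """Ground truth of a simulated grid: per-cell phase and values."""

    lo_mask: np.ndarray  # bool (n_rows, n_cols), True = Lo
    force: np.ndarray  # nN per cell
    thickness: np.ndarray  # nm per cell

    @property
    def lo_fraction(self) -> float:
        return float(self.lo_mask.mean())


def cell_centres(n_rows: int, n_cols: int, physical_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates in µm of every cell centre."""
    sx = physical_size / n_cols
    sy = physical_size / n_rows
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    return (cols + 0.5) * sx, (rows + 0.5) * sy


def simulate_force_grid(params: MapSimParams | None = None, **kwargs) -> tuple[ForceGrid, GridTruth]:
    """Simulate a full force-volume grid over a two-phase layout.

    A cell is Lo when its centre falls inside any disc; its breakthrough
    force and thickness are drawn from that phase's normal distribution
    (truncated to stay physically valid) and a curve is synthesised per
    cell.  Per-cell seeds are spawned from ``params.seed``.
    """
    if params is None:
        params = MapSimParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword overrides, not both")

    xs, ys = cell_centres(params.n_rows, params.n_cols, params.physical_size)
    lo_mask = np.zeros((params.n_rows, params.n_cols), dtype=bool)
    for cx, cy, r in params.discs:
        lo_mask |= (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2

    rng = np.random.default_rng(params.seed)
    grid = ForceGrid(
        n_rows=params.n_rows,
        n_cols=params.n_cols,
        physical_size=(params.physical_size, params.physical_size),
    )
    force = np.zeros_like(xs)
    thickness = np.zeros_like(xs)
    child_seeds = np.random.SeedSequence(
        params.seed if params.seed is not None else None
    ).generate_state(params.n_rows * params.n_cols) % (2**31)
    for r in range(params.n_rows):
        for c in range(params.n_cols):
            fdist = params.lo_force if lo_mask[r, c] else params.ld_force
            tdist = params.lo_thickness if lo_mask[r, c] else params.ld_thickness
            # truncate draws so every cell stays simulable and passes the
            # physical-validity invariants of the curve generator
            f = float(np.clip(rng.normal(*fdist), 0.6, 8.5))
            t = float(np.clip(rng.normal(*tdist), 0.5, 8.0))
            force[r, c] = f
            thickness[r, c] = t
            curve, _ = simulate_force_curve(
                CurveSimParams(
                    breakthrough_force=f,
                    thickness=t,
                    noise_sd=params.noise_sd,
                    seed=int(child_seeds[r * params.n_cols + c]),
                )
            )
            curve.grid_index = (r, c)
            curve.source_id = f"sim-cell-r{r}c{c}"
            grid.curves[(r, c)] = curve
    return grid, GridTruth(lo_mask=lo_mask, force=force, thickness=thickness)


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation to the perimeter of an ellipse."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def simulate_domain_image(
    shapes: Sequence[tuple],
    image_size: float = 5.0,
    pixel_size: float = 0.02,
    step_height: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[HeightImage, np.ndarray, list[dict], bool]:
    """Render analytic shapes as an Lo/Ld height image.

    ``shapes`` are ``("disc", cx, cy, r)`` or ``("ellipse", cx, cy, a, b)``
    in µm.  Lo pixels (inside any shape) sit ``step_height`` nm above the
    Ld background; Gaussian height noise is optional.  Returns the image,
    the boolean ground-truth mask, per-shape analytic metrics (area,
    perimeter via Ramanujan for ellipses, circularity) and a flag that is
    True when shapes overlap (their rasterisations merge into one
    domain).
    """
    n_px = int(round(image_size / pixel_size))
    coords = (np.arange(n_px) + 0.5) * pixel_size
    X, Y = np.meshgrid(coords, coords)
    mask = np.zeros((n_px, n_px), dtype=bool)
    coverage = np.zeros((n_px, n_px), dtype=int)
    truths: list[dict] = []
    for shape in shapes:
        kind = shape[0]
        if kind == "disc":
            _, cx, cy, r = shape
            member = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
            area, perim = math.pi * r**2, 2 * math.pi * r
        elif kind == "ellipse":
            _, cx, cy, a, b = shape
            member = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
            area, perim = math.pi * a * b, ellipse_perimeter(a, b)
        else:
            raise ValueError(f"unknown shape kind {kind!r}")
        mask |= member
        coverage += member
        truths.append(
            {
                "kind": kind,
                "area": area,
                "perimeter": perim,
                "circularity": 4 * math.pi * area / perim**2,
            }
        )
    overlap = bool((coverage > 1).any())

    heights = np.where(mask, step_height, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heights = heights + rng.normal(0.0, noise_sd, size=heights.shape)
    image = HeightImage(heights=heights, pixel_size=pixel_size, mask=mask)
    return image, mask, truths, overlap
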