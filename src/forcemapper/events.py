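"""Validation and ranking of breakthrough events.

Kink pairs become breakthrough events once they pass plausibility
thresholds: the rupture force must be at least ``force_min`` and the
apparent membrane thickness must fall inside a physical window.  The
standard window is 1.5–9 nm thickness and at least 0.5 nN force; single
supported bilayers on mica fall well inside it, while noise kinks and
long-range artefacts fall outside.  When several events survive in one
curve, the one farthest from the support (largest z at onset) is the
primary event and deeper ones are secondary (e.g. rupture of a second,
stacked bilayer closer to the mica).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .kinks import KinkPair

__all__ = [
    "ThresholdConfig",
    "BreakthroughEvent",
    "extract_events",
    "peak_statistics",
]


@dataclass
class ThresholdConfig:
    """Plausibility bounds for breakthrough events (closed intervals)."""

    force_min: float = 0.5  # nN
    thickness_min: float = 1.5  # nm
    thickness_max: float = 9.0  # nm

    def __post_init__(self) -> None:
        if self.force_min <= 0:
            raise ValueError("force_min must be positive")
        if not (0 < self.thickness_min < self.thickness_max):
            raise ValueError("need 0 < thickness_min < thickness_max")


@dataclass(frozen=True)
class BreakthroughEvent:
    """A validated membrane rupture for one curve."""

    force: float  # nN, at rupture onset
    thickness: float  # nm
    z_start: float  # nm, separation at rupture onset
    rank: str  # "primary" | "secondary"
    curve_id: str = ""
    flags: tuple[str, ...] = ()


def extract_events(
    pairs: Iterable[KinkPair],
    thresholds: ThresholdConfig | None = None,
    curve_id: str = "",
) -> list[BreakthroughEvent]:
    """Filter kink pairs by the thresholds and rank the survivors.

    Bounds are inclusive: a 0.5 nN force or a 1.5 nm / 9 nm thickness
    passes.  Survivors are sorted by decreasing onset separation; the
    first is primary, the rest secondary.  More than two survivors is
    unusual, so events beyond the second carry an ``extra`` flag and
    every event in such a curve is flagged ``multiple``.
    """
    thresholds = thresholds or ThresholdConfig()
    surviving = [
        p
        for p in pairs
        if p.force >= thresholds.force_min
        and thresholds.thickness_min <= p.thickness <= thresholds.thickness_max
    ]
    surviving.sort(key=lambda p: -p.z_start)
    multiple = len(surviving) > 2
    events = []
    for i, p in enumerate(surviving):
        flags: list[str] = []
        if multiple:
            flags.append("multiple")
        if i >= 2:
            flags.append("extra")
        events.append(
            BreakthroughEvent(
                force=p.force,
                thickness=p.thickness,
                z_start=p.z_start,
                rank="primary" if i == 0 else "secondary",
                curve_id=curve_id,
                flags=tuple(flags),
            )
        )
    return events


def peak_statistics(
    events: Sequence[BreakthroughEvent], rank: str | None = "primary"
) -> dict:
    """Simple per-rank summary statistics of force and thickness.

    Returns count, mean and sample SD (ddof=1) of force (nN) and
    thickness (nm) over events of the requested rank (``None`` = all).
    Means and SDs are NaN when undefined (count 0, or count 1 for SD).
    """
    sel = [e for e in events if rank is None or e.rank == rank]
    out = {"rank": rank or "all", "count": len(sel)}
    for name in ("force", "thickness"):
        vals = np.array([getattr(e, name) for e in sel], dtype=float)
        out[f"{name}_mean"] = float(vals.mean()) if len(vals) else float("nan")
        out[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return out
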