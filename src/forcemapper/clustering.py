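"""Two-phase clustering of breakthrough data (Lo / Ld assignment).

In phase-separated PC/SM/cholesterol bilayers every grid point yields a
(breakthrough force, thickness) pair, and the liquid-ordered (Lo) phase
is both stiffer and thicker than the liquid-disordered (Ld) background.
KMeans with k = 2 on the standardised feature vectors separates the two
populations; the cluster with the lower mean breakthrough force is the
Ld phase.  The summary statistics mirror the usual cluster report for
such maps: per-phase point fractions, mean ± SD thickness, and the
maximum mismatch, i.e. the largest excess of any single Lo thickness
over the mean Ld thickness (the average Lo-Ld mismatch is also reported
for comparison with image-based height mismatch, though it is less
informative when the thickness distributions overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "PhaseSummary",
    "cluster_two",
    "assign_phases",
    "phase_summary",
    "cluster_map",
]

PHASE_MISSING = ""


@dataclass
class PhaseSummary:
    """Per-phase cluster statistics (Table-style summary)."""

    point_fraction: dict  # phase -> % of clustered points
    thickness_mean: dict  # phase -> nm
    thickness_sd: dict  # phase -> nm (sample SD)
    force_mean: dict  # phase -> nN
    force_sd: dict  # phase -> nN
    max_mismatch: float  # nm
    average_mismatch: float  # nm, Lo mean - Ld mean thickness
    n_points: int
    seed: int | None = None
    features: str = "both"
    scaling: dict = field(default_factory=dict)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, dict]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd_safe, {"mean": mean.tolist(), "sd": sd.tolist()}


def cluster_two(
    points: Sequence[tuple[float, float]],
    seed: int | None = 0,
    features: str = "both",
) -> np.ndarray:
    """KMeans (k=2) labels for (force, thickness) points.

    Features are z-score standardised first — nN and nm scales are not
    commensurate.  ``features="thickness"`` clusters on thickness alone
    (the force axis still decides which cluster is Ld afterwards).
    Deterministic for a given seed (10 restarts, best inertia kept).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (force, thickness)")
    if len(X) < 2:
        raise ValueError("need at least 2 points to form two clusters")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("degenerate input: all points identical")
    if features not in ("both", "thickness"):
        raise ValueError("features must be 'both' or 'thickness'")
    Xs, _ = _standardize(X)
    if features == "thickness":
        Xs = Xs[:, [1]]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(Xs)


def assign_phases(labels: Sequence[int], points: Sequence[tuple[float, float]]) -> np.ndarray:
    """Map 0/1 cluster labels to phase names by mean breakthrough force.

    The cluster with the lower mean force is Ld; ties are degenerate and
    raise.  The result is invariant under permutation of the input label
    values.
    """
    labels = np.asarray(labels)
    X = np.asarray(points, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(uniq)}")
    means = {lab: X[labels == lab, 0].mean() for lab in uniq}
    if means[uniq[0]] == means[uniq[1]]:
        raise ValueError("degenerate clustering: clusters have equal mean force")
    ld_label = min(uniq, key=lambda lab: means[lab])
    return np.where(labels == ld_label, "Ld", "Lo")


def phase_summary(
    phases: Sequence[str],
    points: Sequence[tuple[float, float]],
    seed: int | None = None,
    features: str = "both",
) -> PhaseSummary:
    """Per-phase fractions, force/thickness statistics and mismatch."""
    phases = np.asarray(phases)
    X = np.asarray(points, dtype=float)
    out: dict[str, dict] = {k: {} for k in ("frac", "tmean", "tsd", "fmean", "fsd")}
    for phase in ("Ld", "Lo"):
        mask = phases == phase
        if not mask.any():
            raise ValueError(f"phase {phase} is empty")
        out["frac"][phase] = 100.0 * mask.sum() / len(phases)
        t = X[mask, 1]
        f = X[mask, 0]
        out["tmean"][phase] = float(t.mean())
        out["tsd"][phase] = float(t.std(ddof=1)) if len(t) > 1 else float("nan")
        out["fmean"][phase] = float(f.mean())
        out["fsd"][phase] = float(f.std(ddof=1)) if len(f) > 1 else float("nan")
    lo_t = X[phases == "Lo", 1]
    ld_mean = out["tmean"]["Ld"]
    return PhaseSummary(
        point_fraction=out["frac"],
        thickness_mean=out["tmean"],
        thickness_sd=out["tsd"],
        force_mean=out["fmean"],
        force_sd=out["fsd"],
        max_mismatch=float(np.max(lo_t - ld_mean)),
        average_mismatch=float(out["tmean"]["Lo"] - ld_mean),
        n_points=len(phases),
        seed=seed,
        features=features,
    )


def cluster_map(
    grid_shape: tuple[int, int],
    phases_by_cell: Mapping[tuple[int, int], str],
) -> np.ndarray:
    """Spatial phase raster: "Ld"/"Lo" per cell, "" where missing."""
    n_rows, n_cols = grid_shape
    out = np.full((n_rows, n_cols), PHASE_MISSING, dtype="<U2")
    for (r, c), phase in phases_by_cell.items():
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"cell {(r, c)} outside grid {grid_shape}")
        out[r, c] = phase
    return out
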