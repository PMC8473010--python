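"""Breakthrough-kink detection by peak search under coordinate rotation.

A bilayer rupture shows up in an approach force-distance curve as a pair
of "kinks": a concave corner where the force stops rising (rupture onset)
and, one bilayer thickness deeper in z, a convex corner where the tip
lands on the hard support (rupture completion).  Sharp ruptures are local
force maxima and are found directly by local-maximum peak detection; soft
kinks that never form a local maximum are recovered by rotating the
(F, z) curve by a small angle, which shears a slope change into a local
maximum.  Detections from all rotation angles are pooled, redundant
detections of the same kink are merged (keeping the smallest angle, which
distorts the coordinates least), and opposite-curvature kinks are paired
into thickness measurements.

Rotation is applied to the raw (nN, nm) coordinates.  With separation in
nm and force in nN the contact-region slope of a lipid bilayer indent is
of order 1, so the degree-scale angle set {0, 4.5, 9, 13.5, 18} spans the
useful shear range.  Min-max normalisation to the unit square is
available as an option but is a poor default for force-volume ramps whose
z travel (hundreds of nm) dwarfs the bilayer thickness: normalising z by
the full travel shrinks the rotated signature of a plateau below any
noise-robust prominence threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .curve_io import ForceCurve

__all__ = [
    "KinkDetection",
    "KinkPair",
    "DetectionConfig",
    "peakdet",
    "rotate_curve",
    "detect_kinks",
    "merge_redundant",
    "pair_opposite_kinks",
    "detect_breakthrough_pairs",
]


@dataclass(frozen=True)
class KinkDetection:
    """One candidate kink, reported in the original curve frame.

    ``F_hat``/``z_hat`` are the curve's force (nN) and separation (nm) at
    ``sample_index``; ``angle`` is the smallest rotation angle (degrees)
    at which the kink appeared as a local maximum; ``curvature_sign`` is
    +1 for kinks detected on F(z) (rupture onsets) and -1 for kinks
    detected on -F(z) (rupture completions / contact points).
    """

    F_hat: float
    z_hat: float
    angle: float
    curvature_sign: int
    sample_index: int


@dataclass(frozen=True)
class KinkPair:
    """An opposite-curvature kink pair bracketing one membrane rupture."""

    start: KinkDetection
    end: KinkDetection

    @property
    def force(self) -> float:
        """Breakthrough force = force at rupture onset (nN)."""
        return self.start.F_hat

    @property
    def thickness(self) -> float:
        """z-distance between the two kinks (nm)."""
        return abs(self.start.z_hat - self.end.z_hat)

    @property
    def z_start(self) -> float:
        return self.start.z_hat


@dataclass
class DetectionConfig:
    """Tunable parameters of the kink detector.

    ``angles`` are the rotation angles in degrees (ascending, starting at
    0).  ``delta`` is the peak prominence passed to :func:`peakdet` and
    ``merge_threshold`` the Euclidean distance below which two detections
    are considered the same kink; both live in the detection coordinate
    frame selected by ``coordinates`` ("raw" nN/nm or min-max "unit").
    """

    angles: tuple[float, ...] = (0.0, 4.5, 9.0, 13.5, 18.0)
    delta: float = 0.2
    merge_threshold: float = 0.5
    coordinates: str = "raw"

    def __post_init__(self) -> None:
        self.angles = tuple(float(a) for a in self.angles)
        if len(self.angles) == 0 or self.angles[0] != 0.0:
            raise ValueError("angle set must start at 0 degrees")
        if any(b <= a for a, b in zip(self.angles, self.angles[1:])):
            raise ValueError("angles must be strictly ascending")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.merge_threshold <= 0:
            raise ValueError("merge_threshold must be positive")
        if self.coordinates not in ("raw", "unit"):
            raise ValueError("coordinates must be 'raw' or 'unit'")


def peakdet(values: Sequence[float], delta: float) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Local-extremum detection with prominence ``delta`` (Billauer style).

    Scans the sequence once, alternating between searching for a maximum
    and a minimum; a running maximum is confirmed as a peak when the
    signal subsequently drops at least ``delta`` below it, and vice versa
    for minima.  Returns ``(maxima, minima)`` as lists of
    ``(index, value)`` in order of appearance.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("peakdet expects a one-dimensional sequence")
    if not np.isfinite(v).all():
        raise ValueError("peakdet input contains non-finite values")

    maxima: list[tuple[int, float]] = []
    minima: list[tuple[int, float]] = []
    mn, mx = math.inf, -math.inf
    mnpos = mxpos = -1
    look_for_max = True
    for i, this in enumerate(v):
        if this > mx:
            mx, mxpos = this, i
        if this < mn:
            mn, mnpos = this, i
        if look_for_max:
            if this < mx - delta:
                maxima.append((mxpos, mx))
                mn, mnpos = this, i
                look_for_max = False
        else:
            if this > mn + delta:
                minima.append((mnpos, mn))
                mx, mxpos = this, i
                look_for_max = True
    return maxima, minima


def rotate_curve(curve_matrix: np.ndarray, phi_degrees: float) -> np.ndarray:
    """Rotate an N x 2 matrix of [F, z] rows by ``phi_degrees``.

    Row [F, z] maps to [F cos(phi) - z sin(phi), F sin(phi) + z cos(phi)];
    phi = 0 is the identity.
    """
    C = np.asarray(curve_matrix, dtype=float)
    if C.ndim != 2 or C.shape[1] != 2:
        raise ValueError("curve matrix must be N x 2")
    if not np.isfinite(C).all():
        raise ValueError("curve matrix contains non-finite values")
    phi = math.radians(phi_degrees)
    R = np.array([[math.cos(phi), math.sin(phi)], [-math.sin(phi), math.cos(phi)]])
    return C @ R


def _minmax(x: np.ndarray) -> np.ndarray:
    span = np.ptp(x)
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def _detection_coords(curve: ForceCurve, coordinates: str) -> tuple[np.ndarray, np.ndarray]:
    """(F, z) in the frame where delta / merge_threshold are defined."""
    if coordinates == "unit":
        return _minmax(curve.F), _minmax(curve.z)
    return curve.F, curve.z


def detect_kinks(curve: ForceCurve, config: DetectionConfig | None = None, sign: int = 1) -> list[KinkDetection]:
    """Detect kinks of one curvature sign at every configured angle.

    ``sign = +1`` runs the detector on F(z) (concave kinks: rupture
    onsets), ``sign = -1`` on -F(z) (convex kinks: rupture completions).
    The union of the per-angle detection sets is returned; a sample index
    detected at several angles is reported once, tagged with the smallest
    angle.  The union is *not* distance-merged here — see
    :func:`merge_redundant`.
    """
    config = config or DetectionConfig()
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    if len(curve) < 3:
        return []

    if config.coordinates == "unit":
        z_det = _minmax(curve.z)
        F_base = _minmax(sign * curve.F)
    else:
        z_det = curve.z
        F_base = sign * curve.F

    detections: dict[int, KinkDetection] = {}
    for angle in config.angles:
        # The rotation sign is chosen per curvature branch so that the
        # shear turns a slope-decrease kink of that branch into a local
        # maximum on the approach (z descending along the sample order).
        rotated = rotate_curve(np.column_stack([F_base, sign * z_det]), -angle)
        maxima, _ = peakdet(rotated[:, 0], config.delta)
        for idx, _val in maxima:
            # a kink needs neighbours on both sides; a "maximum" at the
            # first or last sample is a scan boundary artifact (e.g. the
            # start of a monotone-falling rotated line)
            if idx == 0 or idx == len(curve) - 1:
                continue
            if idx not in detections:  # angles ascend: first hit = smallest angle
                detections[idx] = KinkDetection(
                    F_hat=float(curve.F[idx]),
                    z_hat=float(curve.z[idx]),
                    angle=angle,
                    curvature_sign=sign,
                    sample_index=int(idx),
                )
    return [detections[i] for i in sorted(detections)]


def merge_redundant(
    detections: Iterable[KinkDetection],
    merge_threshold: float,
    coords: dict[int, tuple[float, float]] | None = None,
) -> list[KinkDetection]:
    """Collapse groups of detections that originate from the same kink.

    Two detections closer than ``merge_threshold`` (Euclidean distance in
    the detection frame) are the same kink; closeness is applied
    transitively, and each group keeps only its smallest-angle member
    (ties broken by sample index).  Idempotent.

    ``coords`` optionally maps sample index to the (F, z) pair used for
    the distance computation (e.g. unit-normalised coordinates); by
    default the detections' own raw coordinates are used.
    """
    dets = sorted(detections, key=lambda d: (d.sample_index, d.angle))
    n = len(dets)
    if n <= 1:
        return dets

    def xy(d: KinkDetection) -> tuple[float, float]:
        if coords is not None:
            return coords[d.sample_index]
        return (d.F_hat, d.z_hat)

    pts = np.array([xy(d) for d in dets])
    diff = pts[:, None, :] - pts[None, :, :]
    close = np.sqrt((diff ** 2).sum(axis=2)) < merge_threshold

    # union-find over the "same kink" relation
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if close[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    groups: dict[int, list[KinkDetection]] = {}
    for i, d in enumerate(dets):
        groups.setdefault(find(i), []).append(d)
    kept = [min(g, key=lambda d: (d.angle, d.sample_index)) for g in groups.values()]
    return sorted(kept, key=lambda d: d.sample_index)


def pair_opposite_kinks(
    pos_kinks: Iterable[KinkDetection],
    neg_kinks: Iterable[KinkDetection],
) -> tuple[list[KinkPair], list[KinkDetection]]:
    """Pair each onset kink with the nearest subsequent completion kink.

    Kinks are ordered along the approach (increasing sample index, i.e.
    decreasing z).  Each positive-curvature kink takes the first unused
    negative-curvature kink that lies strictly deeper (smaller z); the
    z-distance of the pair is the membrane thickness.  Kinks left without
    a partner are returned separately.
    """
    pos = sorted(pos_kinks, key=lambda d: d.sample_index)
    neg = sorted(neg_kinks, key=lambda d: d.sample_index)
    used = [False] * len(neg)
    pairs: list[KinkPair] = []
    unpaired: list[KinkDetection] = []
    for p in pos:
        match = None
        for j, q in enumerate(neg):
            if used[j] or q.sample_index <= p.sample_index:
                continue
            if q.z_hat >= p.z_hat:  # must be strictly deeper in z
                continue
            match = j
            break
        if match is None:
            unpaired.append(p)
        else:
            used[match] = True
            pairs.append(KinkPair(start=p, end=neg[match]))
    unpaired.extend(q for j, q in enumerate(neg) if not used[j])
    return pairs, unpaired


def detect_breakthrough_pairs(
    curve: ForceCurve, config: DetectionConfig | None = None
) -> tuple[list[KinkPair], list[KinkDetection]]:
    """Full per-curve detection: both curvature signs, merge, pair."""
    config = config or DetectionConfig()
    Fd, zd = _detection_coords(curve, config.coordinates)
    coords = {i: (float(Fd[i]), float(zd[i])) for i in range(len(curve))}
    pos = merge_redundant(detect_kinks(curve, config, sign=1), config.merge_threshold, coords)
    neg = merge_redundant(detect_kinks(curve, config, sign=-1), config.merge_threshold, coords)
    return pair_opposite_kinks(pos, neg)
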