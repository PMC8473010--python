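import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forcemapper import (
    DetectionConfig,
    KinkDetection,
    detect_breakthrough_pairs,
    detect_kinks,
    merge_redundant,
    pair_opposite_kinks,
    peakdet,
    rotate_curve,
)
from forcemapper.simulate import CurveSimParams, simulate_force_curve
from tests.conftest import make_curve


def peakdet_oracle(values, delta):
    """Reference extremum scan, coded independently of the streaming pass.

    Repeatedly scans the remaining suffix with cumulative extrema: the
    next maximum is the (first) argmax of the prefix up to the first
    sample lying delta below the running maximum, and symmetrically for
    minima.
    """
    v = np.asarray(values, float)
    maxima, minima = [], []
    start = 0
    look_for_max = True
    while True:
        seg = v[start:]
        if look_for_max:
            run = np.maximum.accumulate(seg)
            hits = np.flatnonzero(seg < run - delta)
        else:
            run = np.minimum.accumulate(seg)
            hits = np.flatnonzero(seg > run + delta)
        if hits.size == 0:
            return maxima, minima
        j = int(hits[0])
        if look_for_max:
            k = int(np.argmax(seg[: j + 1]))
            maxima.append((start + k, float(seg[k])))
        else:
            k = int(np.argmin(seg[: j + 1]))
            minima.append((start + k, float(seg[k])))
        start += j
        look_for_max = not look_for_max


class TestPeakdet:
    def test_single_triangle_peak(self):
        maxima, minima = peakdet([0, 1, 0], delta=0.5)
        assert maxima == [(1, 1.0)]
        assert minima == []

    @pytest.mark.parametrize("delta", [0.1, 1.0, 10.0])
    def test_monotone_has_no_interior_peak(self, delta):
        maxima, _ = peakdet([0, 1, 2, 3], delta=delta)
        assert [m for m in maxima if m[0] != 0] == []

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.normal(0, 0.2, size=200))
        assert peakdet(walk, 0.3) == peakdet_oracle(walk, 0.3)

    def test_alternation_and_prominence(self):
        rng = np.random.default_rng(7)
        walk = np.cumsum(rng.normal(0, 0.3, size=500))
        maxima, minima = peakdet(walk, 0.5)
        merged = sorted(
            [(i, v, "max") for i, v in maxima] + [(i, v, "min") for i, v in minima]
        )
        kinds = [m[2] for m in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternating
        for (i1, v1, k1), (i2, v2, k2) in zip(merged, merged[1:]):
            assert abs(v1 - v2) >= 0.5

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            peakdet([0, np.nan, 1], 0.1)

    def test_delta_must_be_positive(self):
        with pytest.raises(ValueError):
            peakdet([0, 1, 0], 0.0)


class TestRotateCurve:
    def test_unit_vector_90_degrees(self):
        assert np.allclose(rotate_curve([[1.0, 0.0]], 90.0), [[0.0, 1.0]])

    def test_zero_angle_is_identity(self):
        rng = np.random.default_rng(0)
        C = rng.normal(size=(20, 2))
        assert np.allclose(rotate_curve(C, 0.0), C)

    @given(
        st.floats(-45, 45),
        st.floats(-45, 45),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rotations_compose(self, a, b, seed):
        C = np.random.default_rng(seed).normal(size=(10, 2))
        both = rotate_curve(rotate_curve(C, a), b)
        assert np.allclose(both, rotate_curve(C, a + b), atol=1e-12)

    def test_example_composition(self):
        C = np.random.default_rng(1).normal(size=(15, 2))
        assert np.allclose(
            rotate_curve(rotate_curve(C, 4.5), 13.5), rotate_curve(C, 18.0), atol=1e-12
        )


class TestDetectKinks:
    def test_sharp_breakthrough_found_at_zero_degrees(self, sharp_breakthrough_curve):
        curve, truth = sharp_breakthrough_curve
        config = DetectionConfig()
        kinks = detect_kinks(curve, config, sign=1)
        onset = [k for k in kinks if abs(k.z_hat - truth["z_onset"]) < 0.2]
        assert onset and min(k.angle for k in onset) == 0.0
        merged = merge_redundant(kinks, config.merge_threshold)
        assert sum(1 for k in merged if abs(k.z_hat - truth["z_onset"]) < 0.2) == 1

    @pytest.mark.parametrize("slope,intercept", [(1.0, 0.0), (0.05, 2.0), (-0.3, 5.0)])
    def test_straight_line_yields_nothing_at_any_angle(self, slope, intercept):
        z = np.linspace(50.0, 0.0, 400)
        curve = make_curve(z, slope * (50 - z) + intercept)
        for sign in (1, -1):
            assert detect_kinks(curve, DetectionConfig(), sign=sign) == []

    def test_hidden_slope_change_recovered_by_rotation(self):
        # F climbs at 1 nN/nm then at 0.2 nN/nm: monotone, no local
        # maximum in the unrotated curve, but tan(13.5 deg) > 0.2 so the
        # kink appears as a peak at the larger angles.
        z = np.linspace(20.0, 0.0, 401)
        F = np.where(z >= 10, 1.0 * (20 - z), 10.0 + 0.2 * (10 - z))
        curve = make_curve(z, F)
        assert detect_kinks(curve, DetectionConfig(angles=(0.0,)), sign=1) == []
        kinks = detect_kinks(curve, DetectionConfig(), sign=1)
        assert any(abs(k.z_hat - 10.0) < 0.2 and k.angle > 0 for k in kinks)
        # independent check: peakdet on the hand-sheared coordinate
        for angle in (13.5, 18.0):
            phi = math.radians(angle)
            sheared = F * math.cos(phi) + z * math.sin(phi)
            maxima, _ = peakdet(sheared, 0.2)
            assert any(abs(z[i] - 10.0) < 0.2 for i, _ in maxima)

    def test_union_is_superset_of_zero_angle_detections(self, sharp_breakthrough_curve):
        curve, _ = sharp_breakthrough_curve
        at_zero = {k.sample_index for k in detect_kinks(curve, DetectionConfig(angles=(0.0,)), 1)}
        full = {k.sample_index for k in detect_kinks(curve, DetectionConfig(), 1)}
        assert at_zero <= full

    def test_short_curve_gives_empty_set(self):
        assert detect_kinks(make_curve([1.0, 0.0], [0.0, 1.0]), DetectionConfig(), 1) == []

    def test_unit_mode_invariant_to_uniform_rescaling(self, sharp_breakthrough_curve):
        curve, _ = sharp_breakthrough_curve
        config = DetectionConfig(coordinates="unit", delta=0.05, merge_threshold=0.02)
        base = detect_kinks(curve, config, sign=1)
        scaled = make_curve(curve.z * 1e3, curve.F * 1e3)
        rescaled = detect_kinks(scaled, config, sign=1)
        assert [k.sample_index for k in base] == [k.sample_index for k in rescaled]
        assert [k.angle for k in base] == [k.angle for k in rescaled]


def _det(F, z, angle=0.0, sign=1, index=0):
    return KinkDetection(F_hat=F, z_hat=z, angle=angle, curvature_sign=sign, sample_index=index)


class TestMergeRedundant:
    def test_close_pair_keeps_smaller_angle(self):
        a = _det(1.0, 5.0, angle=4.5, index=10)
        b = _det(1.01, 5.01, angle=9.0, index=11)
        kept = merge_redundant([a, b], merge_threshold=0.1)
        assert kept == [a]

    def test_distant_pair_untouched(self):
        a = _det(1.0, 5.0, angle=4.5, index=10)
        b = _det(3.0, 2.0, angle=9.0, index=50)
        assert merge_redundant([a, b], merge_threshold=0.1) == [a, b]

    def test_chain_matches_transitive_merge_oracle(self):
        # a-b and b-c are close, a-c is not: the whole chain is one kink
        a = _det(1.0, 5.00, angle=4.5, index=10)
        b = _det(1.0, 5.08, angle=9.0, index=11)
        c = _det(1.0, 5.16, angle=13.5, index=12)
        kept = merge_redundant([c, a, b], merge_threshold=0.1)
        # oracle: connected components of the within-threshold graph
        assert kept == [a]

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_and_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        dets = [
            _det(rng.uniform(0, 3), rng.uniform(0, 10), angle=float(rng.choice([0, 4.5, 9])), index=i)
            for i in range(12)
        ]
        once = merge_redundant(dets, 1.0)
        assert merge_redundant(once, 1.0) == once
        shuffled = list(dets)
        rng.shuffle(shuffled)
        assert merge_redundant(shuffled, 1.0) == once

    def test_no_surviving_pair_within_threshold(self):
        rng = np.random.default_rng(4)
        dets = [_det(rng.uniform(0, 2), rng.uniform(0, 6), index=i) for i in range(20)]
        kept = merge_redundant(dets, 0.8)
        pts = np.array([[d.F_hat, d.z_hat] for d in kept])
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert (np.sqrt(d2) >= 0.8).all()


class TestPairing:
    def test_single_pair_thickness(self):
        pos = [_det(2.0, 5.0, sign=1, index=10)]
        neg = [_det(2.0, 2.5, sign=-1, index=20)]
        pairs, unpaired = pair_opposite_kinks(pos, neg)
        assert len(pairs) == 1 and unpaired == []
        assert pairs[0].thickness == pytest.approx(2.5)
        assert pairs[0].force == pytest.approx(2.0)

    def test_unpaired_positive_kink_reported(self):
        pos = [_det(2.0, 5.0, sign=1, index=10)]
        pairs, unpaired = pair_opposite_kinks(pos, [])
        assert pairs == [] and unpaired == pos

    def test_subsequent_means_deeper_in_z(self):
        pos = [_det(2.0, 5.0, sign=1, index=10)]
        neg_before = [_det(1.0, 7.0, sign=-1, index=5)]
        pairs, unpaired = pair_opposite_kinks(pos, neg_before)
        assert pairs == [] and set(unpaired) == set(pos + neg_before)

    def test_generator_thickness_recovered_with_noise(self):
        errors = []
        for seed in range(20):
            curve, truth = simulate_force_curve(
                CurveSimParams(thickness=4.0, noise_sd=0.02, seed=seed)
            )
            pairs, _ = detect_breakthrough_pairs(curve)
            best = min(pairs, key=lambda p: abs(p.z_start - truth.z_onset))
            errors.append(abs(best.thickness - truth.thickness))
        assert np.mean(errors) < 0.3


class TestConfigValidation:
    def test_angles_must_start_at_zero(self):
        with pytest.raises(ValueError):
            DetectionConfig(angles=(4.5, 9.0))

    def test_angles_must_ascend(self):
        with pytest.raises(ValueError):
            DetectionConfig(angles=(0.0, 9.0, 4.5))

    def test_positive_thresholds(self):
        with pytest.raises(ValueError):
            DetectionConfig(delta=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(merge_threshold=-1.0)
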