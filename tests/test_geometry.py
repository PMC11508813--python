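import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whealmeter import geometry as geo
from whealmeter import synthetic as syn
from whealmeter.palette import CLASS_RT, CLASS_WHEAL

from .conftest import random_label_mask


def flood_fill_components(binary: np.ndarray) -> list[frozenset]:
    """Independent 8-connected labeling oracle (BFS flood fill)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    cr, cc = q.popleft()
                    comp.add((cr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = cr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                q.append((nr, nc))
                comps.append(frozenset(comp))
    return comps


def make_mask_with_blobs(blobs, shape=(60, 60)):
    mask = np.zeros(shape, dtype=np.uint8)
    for r0, c0, h, w in blobs:
        mask[r0 : r0 + h, c0 : c0 + w] = CLASS_WHEAL
    return mask


class TestClusterPixels:
    def test_two_blobs_counted(self):
        mask = make_mask_with_blobs([(5, 5, 10, 10), (30, 30, 10, 20)])
        clusters = geo.cluster_pixels(mask, min_size=10)
        assert sorted(c.pixel_count for c in clusters) == [100, 200]

    def test_min_size_filters_speck(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[3, 3] = CLASS_WHEAL
        assert geo.cluster_pixels(mask, min_size=10) == []

    def test_ids_row_major_by_centroid(self):
        mask = make_mask_with_blobs([(40, 5, 5, 5), (5, 40, 5, 5)])
        clusters = geo.cluster_pixels(mask, min_size=5)
        assert [c.id for c in clusters] == [1, 2]
        assert clusters[0].centroid[0] < clusters[1].centroid[0]

    def test_centroid_is_pixel_mean(self):
        mask = make_mask_with_blobs([(4, 6, 3, 5)])
        (cluster,) = geo.cluster_pixels(mask, min_size=1)
        assert cluster.centroid == (5.0, 8.0)

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mask = random_label_mask(rng)
            got = {
                frozenset((int(r), int(c)) for r, c in cl.pixels)
                for cl in geo.cluster_pixels(mask, min_size=1)
            }
            assert got == set(flood_fill_components(mask == CLASS_WHEAL))


class TestCalibration:
    def test_simple_proportion(self):
        mask = np.zeros((120, 120), dtype=np.uint8)
        mask[:100, :100] = CLASS_RT
        cal = geo.calibrate(mask)
        assert cal.rt_pixel_count == 10000
        assert cal.cm2_per_pixel == pytest.approx(9e-4)

    def test_rendered_scene_scale(self, small_scene):
        _, mask, _ = small_scene  # 20 px/cm
        cal = geo.calibrate(mask)
        assert cal.cm2_per_pixel == pytest.approx((1 / 20.0) ** 2, rel=0.02)

    def test_largest_component_wins(self):
        mask = np.zeros((200, 200), dtype=np.uint8)
        mask[:100, :100] = CLASS_RT
        mask[150:153, 150:154] = CLASS_RT  # 12-px mole misclassified as tag
        assert geo.calibrate(mask).rt_pixel_count == 10000

    def test_no_rt_raises(self):
        with pytest.raises(geo.CalibrationError):
            geo.calibrate(np.zeros((10, 10), dtype=np.uint8))

    def test_nonpositive_count_rejected(self):
        with pytest.raises(geo.CalibrationError):
            geo.Calibration(rt_pixel_count=0)


class TestClusterArea:
    def test_arithmetic(self):
        mask = make_mask_with_blobs([(5, 5, 40, 25)])  # 1000 px
        (cluster,) = geo.cluster_pixels(mask, min_size=1)
        cal = geo.Calibration(rt_pixel_count=10000)
        assert geo.cluster_area_cm2(cluster, cal) == pytest.approx(0.9)

    def test_rt_measured_against_itself_is_9cm2(self):
        mask = np.zeros((120, 120), dtype=np.uint8)
        mask[:100, :100] = CLASS_RT
        cal = geo.calibrate(mask)
        (rt_cluster,) = geo.cluster_pixels(mask, target_class=CLASS_RT, min_size=1)
        assert geo.cluster_area_cm2(rt_cluster, cal) == pytest.approx(9.0)

    def test_circle_area_within_one_percent(self):
        spec = syn.ShapeSpec("circle", (3.0, 3.0), 1.0, 1.0)
        m = syn.rasterize_shape(spec, 50.0, (300, 300))
        mask = np.where(m, CLASS_WHEAL, 0).astype(np.uint8)
        (cluster,) = geo.cluster_pixels(mask)
        cal = geo.Calibration.from_pixels_per_cm(50.0)
        assert geo.cluster_area_cm2(cluster, cal) == pytest.approx(math.pi, rel=0.01)

    def test_area_invariant_to_contour(self):
        # equal pixel counts => equal areas, whatever the shape
        cal = geo.Calibration(rt_pixel_count=5000)
        blob = make_mask_with_blobs([(5, 5, 10, 10)])
        line = make_mask_with_blobs([(5, 5, 2, 50)])
        (c1,) = geo.cluster_pixels(blob, min_size=1)
        (c2,) = geo.cluster_pixels(line, min_size=1)
        assert c1.pixel_count == c2.pixel_count
        assert geo.cluster_area_cm2(c1, cal) == geo.cluster_area_cm2(c2, cal)


def _cluster_from_shape(spec, ppcm, canvas):
    m = syn.rasterize_shape(spec, ppcm, canvas)
    mask = np.where(m, CLASS_WHEAL, 0).astype(np.uint8)
    (cluster,) = geo.cluster_pixels(mask)
    return cluster


def sampling_sweep_oracle(cluster, cal, angle_step_deg=0.1):
    """Independent chord oracle: walk each centroid ray in 0.05-px steps with
    nearest-pixel membership; chord = last in-region distances on both sides."""
    region = cluster.to_mask()
    h, w = region.shape
    r0, c0 = cluster.centroid
    rel = cluster.pixels - np.array([r0, c0])
    t_max = float(np.hypot(rel[:, 0], rel[:, 1]).max()) + 2.0
    ts = np.arange(0.0, t_max, 0.05)
    best = 0.0
    for theta in np.deg2rad(np.arange(0.0, 180.0, angle_step_deg)):
        total = 0.0
        for sign in (1.0, -1.0):
            rr = np.rint(r0 + sign * ts * math.sin(theta)).astype(int)
            cc = np.rint(c0 + sign * ts * math.cos(theta)).astype(int)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            inside = np.zeros(ts.size, dtype=bool)
            inside[ok] = region[rr[ok], cc[ok]]
            total += float(ts[inside][-1]) if inside.any() else 0.0
        best = max(best, total)
    return best * cal.cm_per_pixel


class TestComputationalDiameters:
    def test_circle_ld_equals_pd(self):
        cluster = _cluster_from_shape(syn.ShapeSpec("circle", (3, 3), 1.0, 1.0), 50.0, (300, 300))
        cal = geo.Calibration.from_pixels_per_cm(50.0)
        ld, pd = geo.computational_diameters(cluster, cal)
        assert abs(ld - pd) / ld < 0.01
        assert ld == pytest.approx(2.0, rel=0.02)

    def test_axis_aligned_ellipse_reference_values(self):
        # a=2 cm, b=1 cm at 100 px/cm: LD/PD within 0.6% of 4 and 2 cm
        cluster = _cluster_from_shape(
            syn.ShapeSpec("ellipse", (2.5, 1.5), 2.0, 1.0, 0.0), 100.0, (500, 300)
        )
        cal = geo.Calibration.from_pixels_per_cm(100.0)
        ld, pd = geo.computational_diameters(cluster, cal, angle_step_deg=0.5)
        assert ld == pytest.approx(4.0, rel=0.006)
        assert pd == pytest.approx(2.0, rel=0.006)

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(5)
        cal = geo.Calibration.from_pixels_per_cm(40.0)
        for _ in range(3):
            a = rng.uniform(0.8, 1.4)
            b = rng.uniform(0.5, a)
            spec = syn.ShapeSpec("ellipse", (3, 3), a, b, rng.uniform(0, 180))
            cluster = _cluster_from_shape(spec, 40.0, (300, 300))
            ld, _ = geo.computational_diameters(cluster, cal, angle_step_deg=1.0)
            oracle_ld = sampling_sweep_oracle(cluster, cal, angle_step_deg=0.1)
            assert abs(ld - oracle_ld) <= 1.0 * cal.cm_per_pixel  # one pixel-equivalent

    def test_ld_at_least_pd(self):
        rng = np.random.default_rng(6)
        cal = geo.Calibration.from_pixels_per_cm(30.0)
        for _ in range(4):
            spec = syn._random_pseudopod_spec(rng, (0.6, 1.0))
            spec = syn.ShapeSpec(
                spec.kind, (4.0, 4.0), spec.semi_major_cm, spec.semi_minor_cm,
                spec.rotation_deg, spec.lobes,
            )
            m = syn.rasterize_shape(spec, 30.0, (300, 300))
            mask = np.where(m, CLASS_WHEAL, 0).astype(np.uint8)
            clusters = geo.cluster_pixels(mask)
            ld, pd = geo.computational_diameters(clusters[0], cal)
            assert ld >= pd > 0

    def test_empty_cluster_rejected(self):
        cal = geo.Calibration(rt_pixel_count=100)
        cluster = geo.WhealCluster(1, np.empty((0, 2), int), (0.0, 0.0), (5, 5))
        with pytest.raises(ValueError):
            geo.computational_diameters(cluster, cal)

    def test_coarse_angle_step_rejected(self):
        cal = geo.Calibration(rt_pixel_count=100)
        mask = make_mask_with_blobs([(2, 2, 5, 5)], shape=(10, 10))
        (cluster,) = geo.cluster_pixels(mask, min_size=1)
        with pytest.raises(ValueError):
            geo.computational_diameters(cluster, cal, angle_step_deg=2.0)


class TestDiameterAreas:
    def test_circle_identity(self):
        assert geo.ma1_area(1.0, 1.0) == pytest.approx(math.pi / 4)
        assert geo.ma2_area(1.0, 1.0) == pytest.approx(math.pi / 4)

    def test_worked_example(self):
        assert geo.ma1_area(0.5, 0.3) == pytest.approx(math.pi * 0.04)
        assert geo.ma2_area(0.5, 0.3) == pytest.approx(math.pi * 0.0375)

    @given(
        ld=st.floats(0.1, 5.0),
        ratio=st.floats(0.1, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_ma1_at_least_ma2(self, ld, ratio):
        pd = ld * ratio
        ma1, ma2 = geo.ma1_area(ld, pd), geo.ma2_area(ld, pd)
        assert ma1 >= ma2 - 1e-12  # AM-GM on the radii
        if ratio < 0.99:  # strict once the axes are meaningfully distinct
            assert ma1 > ma2

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            geo.ma1_area(0.0, 0.0)
        with pytest.raises(ValueError):
            geo.ma2_area(1.0, 2.0)  # PD > LD


def test_measure_cluster_consistency():
    spec = syn.ShapeSpec("circle", (3, 3), 1.0, 1.0)
    cluster = _cluster_from_shape(spec, 40.0, (250, 250))
    cal = geo.Calibration.from_pixels_per_cm(40.0)
    m = geo.measure_cluster(cluster, cal)
    assert m.area_cm2 == geo.cluster_area_cm2(cluster, cal)
    assert m.ma1_cm2 == geo.ma1_area(m.ld_cm, m.pd_cm)
    assert m.ma2_cm2 == geo.ma2_area(m.ld_cm, m.pd_cm)
    assert m.ld_cm >= m.pd_cm
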