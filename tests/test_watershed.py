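"""Marker-controlled watershed: gradient, markers, imposition, flooding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diskseg import (
    EmptyMarkerError,
    MarkerSet,
    SegmentationParams,
    SliceImage,
    extract_external_markers,
    extract_internal_markers,
    flood_watershed,
    impose_minima,
    morphological_gradient,
    segment_slice,
    watershed_segment,
)
from conftest import flood_oracle, regional_minima


def _slice(pixels, spacing=(1.0, 1.0)):
    return SliceImage(pixels=np.asarray(pixels, dtype=float), spacing_mm=spacing)


def _ellipse(shape, center, semi, value=1.0, base=0.0):
    img = np.full(shape, base, dtype=float)
    rr, cc = np.indices(shape)
    inside = ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1
    img[inside] = value
    return img, inside


class TestMorphologicalGradient:
    def test_constant_image_gives_zero(self):
        g = morphological_gradient(_slice(np.full((20, 20), 3.7)), 1)
        assert np.all(g == 0)

    def test_step_edge_band_width(self):
        # vertical step at column 10: with radius 1 the nonzero band spans
        # the two columns adjacent to the edge (enumerating dilation/erosion
        # on a 1D step: only pixels whose neighbourhood straddles the step).
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        g = morphological_gradient(_slice(img), 1)
        nonzero_cols = np.unique(np.nonzero(g)[1])
        assert set(nonzero_cols) <= {9, 10, 11}
        assert len(nonzero_cols) >= 2

    def test_invariant_to_additive_constant(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(24, 24))
        g1 = morphological_gradient(_slice(img), 2)
        g2 = morphological_gradient(_slice(img + 57.0), 2)
        assert np.allclose(g1, g2)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(1)
        g = morphological_gradient(_slice(rng.normal(size=(30, 30))), 1)
        assert np.all(g >= 0)


class TestInternalMarkers:
    def test_two_bright_ellipses_give_two_contained_components(self):
        from scipy import ndimage as ndi

        img, e1 = _ellipse((64, 64), (18, 32), (7, 12), value=1.0)
        img2, e2 = _ellipse((64, 64), (46, 32), (7, 12), value=1.0)
        img = np.maximum(img, img2)
        markers = extract_internal_markers(_slice(img), SegmentationParams())
        lbl, n = ndi.label(markers, structure=np.ones((3, 3)))
        assert n == 2
        for l in range(1, n + 1):
            comp = lbl == l
            # each marker component lies entirely inside one ellipse
            assert np.all(e1[comp]) or np.all(e2[comp])

    def test_constant_image_gives_empty_mask(self):
        markers = extract_internal_markers(_slice(np.full((32, 32), 5.0)), SegmentationParams())
        assert not markers.any()

    def test_below_minimum_area_removed(self):
        img, _ = _ellipse((32, 32), (16, 16), (2, 2), value=1.0)  # ~12 px
        params = SegmentationParams(min_area_mm2=30.0)
        markers = extract_internal_markers(_slice(img), params)
        assert not markers.any()


class TestExternalMarkers:
    def test_two_point_markers_bisector_column(self):
        internal = np.zeros((21, 31), dtype=bool)
        internal[10, 5] = True
        internal[10, 25] = True
        external = extract_external_markers(internal)
        mid = (5 + 25) // 2
        # the separating line contains the perpendicular bisector column
        hit_cols = np.unique(np.nonzero(external)[1])
        assert any(abs(c - mid) <= 1 for c in hit_cols)
        # brute-force nearest-marker partition: the bisector column is
        # exactly equidistant, so no basin-interior pixel may sit there
        assert external[:, mid].sum() >= external.shape[0] - 2

    def test_single_component_returns_border_frame(self):
        internal = np.zeros((16, 16), dtype=bool)
        internal[8, 8] = True
        external = extract_external_markers(internal)
        assert external[0, :].all() and external[-1, :].all()
        assert external[:, 0].all() and external[:, -1].all()

    def test_disjoint_from_internal(self):
        rng = np.random.default_rng(3)
        internal = rng.random((32, 32)) > 0.93
        external = extract_external_markers(internal)
        assert not (external & internal).any()


class TestImposeMinima:
    def test_markers_everywhere_give_constant_image(self):
        rng = np.random.default_rng(0)
        grad = rng.random((16, 16))
        out = impose_minima(grad, np.ones((16, 16), dtype=bool))
        assert np.allclose(out, out.flat[0])

    def test_minima_exactly_at_marker_blobs(self):
        rng = np.random.default_rng(7)
        grad = rng.integers(0, 200, size=(32, 32)).astype(float)
        markers = np.zeros((32, 32), dtype=bool)
        markers[4:7, 4:7] = True
        markers[20:23, 10:13] = True
        markers[12:14, 25:28] = True
        out = impose_minima(grad, markers)
        minima = regional_minima(out) > 0
        from scipy import ndimage as ndi

        lbl, n = ndi.label(minima, structure=np.ones((3, 3)))
        assert n == 3
        assert np.array_equal(minima, markers)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        grad = rng.random((24, 24))
        markers = np.zeros((24, 24), dtype=bool)
        markers[5:8, 5:8] = True
        markers[15:18, 15:18] = True
        once = impose_minima(grad, markers)
        twice = impose_minima(once, markers)
        assert np.allclose(once, twice)

    def test_empty_markers_raise(self):
        with pytest.raises(EmptyMarkerError):
            impose_minima(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))


class TestFlooding:
    def _random_case(self, rng, size=16, n_markers=3):
        img = rng.integers(0, 8, size=(size, size)).astype(float)
        markers = np.zeros((size, size), dtype=np.int64)
        placed = 0
        while placed < n_markers:
            r, c = rng.integers(0, size, 2)
            if markers[r, c] == 0:
                placed += 1
                markers[r, c] = placed
        return img, markers

    def test_matches_brute_force_oracle_small_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            img, markers = self._random_case(rng)
            assert np.array_equal(flood_watershed(img, markers), flood_oracle(img, markers))

    def test_output_is_partition(self):
        rng = np.random.default_rng(5)
        img, markers = self._random_case(rng, size=24, n_markers=4)
        out = flood_watershed(img, markers)
        assert np.all(out != 0)  # every pixel decided
        assert set(np.unique(out)) <= {-1, 1, 2, 3, 4}

    def test_basins_are_4_connected(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(6)
        img, markers = self._random_case(rng, size=24, n_markers=4)
        out = flood_watershed(img, markers)
        for l in range(1, 5):
            _, n = ndi.label(out == l, structure=ndi.generate_binary_structure(2, 1))
            assert n == 1


class TestWatershedSegment:
    def test_single_marked_ellipse_yields_one_candidate(self):
        img, inside = _ellipse((48, 48), (24, 24), (8, 14), value=1.0)
        internal = np.zeros((48, 48), dtype=bool)
        internal[22:27, 20:29] = True
        external = extract_external_markers(internal)
        markers = MarkerSet(internal=internal, external=external)
        sl = _slice(img)
        grad = morphological_gradient(sl, 1)
        regions = watershed_segment(impose_minima(grad, markers.combined), markers, sl)
        assert len(regions) == 1
        mask = regions[0].mask((48, 48))
        overlap = (mask & inside).sum()
        assert 2 * overlap / (mask.sum() + inside.sum()) > 0.8

    def test_candidates_pairwise_disjoint(self, small_phantom):
        sl = small_phantom.volume.sagittal_slice(small_phantom.volume.shape[0] // 2)
        regions = segment_slice(sl)
        total = np.zeros(sl.pixels.shape, dtype=int)
        for r in regions:
            total += r.mask(sl.pixels.shape).astype(int)
        assert total.max() <= 1

    def test_contours_are_closed(self, small_phantom):
        sl = small_phantom.volume.sagittal_slice(small_phantom.volume.shape[0] // 2)
        for r in segment_slice(sl):
            assert len(r.contour) >= 4
            assert np.allclose(r.contour[0], r.contour[-1])


class TestSegmentSlice:
    def test_constant_slice_returns_empty_list(self):
        assert segment_slice(_slice(np.full((32, 32), 1.0))) == []

    def test_phantom_mid_sagittal_nonempty(self, small_phantom):
        sl = small_phantom.volume.sagittal_slice(small_phantom.volume.shape[0] // 2)
        assert len(segment_slice(sl)) > 0

    def test_deterministic(self, small_phantom):
        sl = small_phantom.volume.sagittal_slice(small_phantom.volume.shape[0] // 2)
        a = segment_slice(sl)
        b = segment_slice(sl)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pixels, rb.pixels)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10)
    def test_candidates_never_touch_border(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((24, 24))
        img[8:14, 8:16] += 2.0  # one bright block
        for r in segment_slice(_slice(img)):
            rows, cols = r.pixels[:, 0], r.pixels[:, 1]
            assert rows.min() > 0 and cols.min() > 0
            assert rows.max() < 23 and cols.max() < 23
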