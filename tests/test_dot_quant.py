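"""Dot-detection chain tests: every measurement is checked against an
independent brute-force oracle (per-pixel loops, flood fill), plus the
threshold-monotonicity property and ground-truth comparisons on clean
synthetic fibres."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from musclefish import QuantProfile, packaged_config, quantify_fibre, simulate_fibre
from musclefish.dot_quant import (
    DotRegion,
    intersect_with_muscle,
    label_particles,
    measure_intden,
    measure_muscle_mean,
    project,
    threshold_dots,
    z_filter,
)


def flood_fill_components(mask):
    """Independent 8-connected component oracle (BFS)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        stack, comp = [(sy, sx)], []
        seen[sy, sx] = True
        while stack:
            y, x = stack.pop()
            comp.append((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]
                            and mask[yy, xx] and not seen[yy, xx]):
                        seen[yy, xx] = True
                        stack.append((yy, xx))
        comps.append(comp)
    return comps


class TestProject:
    def test_single_slice_sum_is_identity(self, rng):
        img = rng.random((6, 7))
        np.testing.assert_array_equal(project(img[None], "sum"), img)

    def test_constant_slices_arithmetic(self):
        stack = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 2.0)])
        assert (project(stack, "sum") == 3).all()
        assert (project(stack, "max") == 2).all()

    def test_matches_per_pixel_loop_oracle(self, rng):
        stack = rng.random((5, 8, 9))
        for kind, op in (("sum", sum), ("max", max)):
            got = project(stack, kind)
            for y in range(8):
                for x in range(9):
                    assert got[y, x] == pytest.approx(op(stack[:, y, x]))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            project(np.empty((0, 4, 4)))


class TestThreshold:
    def test_constant_zero_image_yields_empty_mask(self):
        mask, t = threshold_dots(np.zeros((5, 5)), 10.0)
        assert not mask.any() and t == 10.0

    def test_plateau_separates_from_background(self):
        img = np.zeros((10, 10))
        img[3:6, 3:6] = 100.0
        mask, _ = threshold_dots(img, 10.0)
        np.testing.assert_array_equal(mask, img > 10)

    def test_strict_inequality_at_threshold(self):
        img = np.full((3, 3), 10.0)
        img[1, 1] = 10.0001
        mask, _ = threshold_dots(img, 10.0)
        assert mask.sum() == 1

    def test_otsu_on_constant_image_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_dots(np.full((5, 5), 3.0), "otsu")

    @settings(derandomize=True, max_examples=30)
    @given(hnp.arrays(float, (12, 12), elements=st.floats(0, 100)),
           st.floats(0, 50), st.floats(0, 50))
    def test_raising_threshold_nests_foreground(self, img, t1, dt):
        low, _ = threshold_dots(img, t1)
        high, _ = threshold_dots(img, t1 + dt)
        assert (low | high == low).all()  # high-threshold mask nested in low

    def test_raising_threshold_never_increases_dot_count(self, rng):
        # on fibre images with isolated single-peak spots, a higher
        # threshold can only shrink or lose particles, never add them
        cfg = packaged_config("dt1_s59_stage15")
        cfg.min_separation = 16.0  # keep even far Gaussian tails disjoint
        cfg.genes[0].p_on_by_stage[13] = 1.0
        fibre = simulate_fibre(cfg, 13, rng)  # 4 nuclei fit at this spacing
        proj = project(fibre.channels["fish_S59"], "sum")
        counts = []
        for t in np.linspace(1.0, 1.1 * proj.max(), 40):
            mask, _ = threshold_dots(proj, float(t))
            counts.append(len(label_particles(mask, min_area=1)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestParticles:
    def test_empty_mask_gives_empty_list(self):
        assert label_particles(np.zeros((5, 5), bool)) == []

    def test_two_disjoint_squares(self):
        mask = np.zeros((12, 12), bool)
        mask[1:4, 1:4] = True
        mask[7:10, 7:10] = True
        regions = label_particles(mask, min_area=2)
        assert len(regions) == 2 and all(r.area == 9 for r in regions)

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(100):
            mask = rng.random((15, 15)) < 0.25
            got = label_particles(mask, min_area=1)
            oracle = flood_fill_components(mask)
            assert len(got) == len(oracle)
            assert sorted(r.area for r in got) == sorted(len(c) for c in oracle)

    def test_min_area_filters_and_ordering_is_scanline(self):
        mask = np.zeros((10, 10), bool)
        mask[8, 1:4] = True   # lower region, added first
        mask[0, 5:8] = True   # top region
        mask[4, 4] = True     # single pixel, filtered at min_area 2
        regions = label_particles(mask, min_area=2)
        assert [r.pixels[0, 0] for r in regions] == [0, 8]


class TestIntersectAndZ:
    def test_centroid_rule_matches_membership_oracle(self, rng):
        muscle = np.zeros((40, 60), np.uint16)
        muscle[10:30, 15:45] = 1
        kept_oracle = 0
        regions = []
        for _ in range(500):
            cx, cy = rng.uniform(0, 59), rng.uniform(0, 39)
            regions.append(DotRegion(
                pixels=np.array([[int(round(cy)), int(round(cx))]]),
                centroid=(cx, cy), area=1))
            if muscle[int(round(cy)), int(round(cx))]:
                kept_oracle += 1
        kept = intersect_with_muscle(regions, muscle)
        assert len(kept) == kept_oracle
        assert all(r.muscle_label == 1 for r in kept)

    def test_shape_mismatch_is_an_error(self):
        r = DotRegion(pixels=np.array([[50, 50]]), centroid=(50.0, 50.0), area=1)
        with pytest.raises(ValueError):
            intersect_with_muscle([r], np.ones((10, 10), np.uint16))

    def test_z_filter_drops_out_of_plane_decoys(self, rng):
        from musclefish.synthetic import build_fibre_geometry, render_stack, \
            make_label_masks, sample_transcription_states

        cfg = packaged_config("dt1_s59_stage15")
        cfg.min_separation = 12.0  # keep true-dot footprints disjoint
        cfg.genes[0].p_on_by_stage[14] = 0.45
        geo = build_fibre_geometry(cfg, 14, rng)
        states = sample_transcription_states(geo, cfg.genes, rng)
        # plant the decoy inside the muscle but clear of every nucleus, so
        # its footprint cannot fuse with a true dot's in the projection
        x, y = next((x, y) for y in range(56, 73, 2) for x in range(30, 160)
                    if min(np.hypot(x - geo.centres[:, 0],
                                    y - geo.centres[:, 1])) > 12)
        channels, truth = render_stack(geo, states, cfg.genes, rng,
                                       decoys=[("S59", float(x), float(y), 0, 5000.0)])
        muscle_mask, nuclei_mask = make_label_masks(geo)
        meas, dots = quantify_fibre(channels["fish_S59"], muscle_mask,
                                    nuclei_mask, z_extent=geo.z_extent,
                                    gene="S59", stage=15)
        assert meas.n_dots == int(states["S59"].sum())  # decoy at slice 0 removed
        z0, z1 = geo.z_extent
        assert all(z0 - 1 <= d.z_peak <= z1 for d in dots)

    def test_z_filter_keeps_in_plane_dots(self):
        stack = np.zeros((6, 10, 10))
        stack[3, 5, 5] = 10.0
        r = DotRegion(pixels=np.array([[5, 5]]), centroid=(5.0, 5.0), area=1)
        assert len(z_filter([r], (2, 5), stack)) == 1
        assert len(z_filter([r], (0, 1), stack, tolerance=1)) == 0


class TestMeasurement:
    def test_uniform_region_intden(self):
        img = np.ones((8, 8))
        r = DotRegion(pixels=np.array([[0, 0], [1, 1], [2, 2], [3, 3], [4, 4]]),
                      centroid=(2.0, 2.0), area=5)
        assert measure_intden(img, r) == 5.0
        assert measure_intden(np.zeros((8, 8)), r) == 0.0

    def test_intden_and_mean_match_loop_oracles(self, rng):
        for _ in range(100):
            img = rng.random((10, 12))
            k = rng.integers(1, 20)
            ys = rng.integers(0, 10, k)
            xs = rng.integers(0, 12, k)
            pix = np.unique(np.stack([ys, xs], 1), axis=0)
            r = DotRegion(pixels=pix, centroid=(0.0, 0.0), area=len(pix))
            oracle = sum(img[y, x] for y, x in pix)
            assert measure_intden(img, r) == pytest.approx(oracle, abs=1e-12)
            mask = np.zeros((10, 12), bool)
            mask[pix[:, 0], pix[:, 1]] = True
            assert measure_muscle_mean(img, mask) == pytest.approx(oracle / len(pix))

    def test_empty_region_is_an_error(self):
        with pytest.raises(ValueError):
            measure_intden(np.ones((4, 4)),
                           DotRegion(pixels=np.empty((0, 2), int), centroid=(0, 0), area=0))
        with pytest.raises(ValueError):
            measure_muscle_mean(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestQuantifyFibre:
    def test_detects_exactly_the_true_dots(self, s59_fibre):
        meas, dots = quantify_fibre(
            s59_fibre.channels["fish_S59"], s59_fibre.muscle_mask,
            s59_fibre.nuclei_mask, z_extent=s59_fibre.geometry.z_extent,
            gene="S59", stage=15)
        assert meas.n_dots == int(s59_fibre.states["S59"].sum())
        assert meas.n_nuclei == s59_fibre.geometry.n_nuclei

    def test_intden_within_5pct_of_injected_intensity(self, s59_fibre):
        _, dots = quantify_fibre(
            s59_fibre.channels["fish_S59"], s59_fibre.muscle_mask,
            profile=QuantProfile.standard(), gene="S59", stage=15)
        truth = s59_fibre.truth.dots
        for d in dots:
            i = (np.hypot(truth["x"] - d.x, truth["y"] - d.y)).idxmin()
            assert d.intden == pytest.approx(truth.loc[i, "intensity"], rel=0.05)

    def test_total_intden_is_sum_of_dot_intdens(self, s59_fibre):
        meas, dots = quantify_fibre(
            s59_fibre.channels["fish_S59"], s59_fibre.muscle_mask,
            gene="S59", stage=15)
        assert meas.total_intden == sum(d.intden for d in dots)
        assert meas.n_dots == len(meas.dot_intdens)

    def test_zero_on_nuclei_means_zero_dots(self, rng):
        cfg = packaged_config("dt1_s59_stage15")
        cfg.genes[0].p_on_by_stage[15] = 0.0
        fibre = simulate_fibre(cfg, 15, rng)
        meas, _ = quantify_fibre(fibre.channels["fish_S59"], fibre.muscle_mask,
                                 gene="S59", stage=15)
        assert meas.n_dots == 0 and meas.total_intden == 0.0

    def test_fc_restricted_gene_yields_single_dot(self, kr_fibre):
        meas, _ = quantify_fibre(kr_fibre.channels["fish_Kr"], kr_fibre.muscle_mask,
                                 gene="Kr", stage=13)
        assert meas.n_dots == 1

    def test_every_retained_dot_centroid_inside_muscle(self, s59_fibre):
        _, dots = quantify_fibre(
            s59_fibre.channels["fish_S59"], s59_fibre.muscle_mask,
            gene="S59", stage=15)
        for d in dots:
            assert s59_fibre.muscle_mask[int(round(d.y)), int(round(d.x))] == 1

    def test_grid_mismatch_is_an_error(self, s59_fibre):
        with pytest.raises(ValueError, match="grid"):
            quantify_fibre(s59_fibre.channels["fish_S59"], np.ones((4, 4)))
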