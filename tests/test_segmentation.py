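"""Nucleus/foci segmentation, sphericity geometry, tracking, displacement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frapsr.phantom import (
    FocusSpec,
    SceneSpec,
    SubcompartmentSpec,
    simulate_frap_movie,
)
from frapsr.segmentation import (
    LabeledFocus,
    boundary_polygon,
    count_foci,
    focus_displacement,
    polygon_perimeter,
    segment_foci,
    segment_nucleus,
    sphericity_from_polygon,
    sphericity_index,
    sum_project_z,
    track_foci,
)

from conftest import bleach_for, disk_polygon, noiseless_imaging


def multi_focus_scene(n_foci, radius=350.0):
    """Nucleus with n compact foci on a grid, for counting tests."""
    center = (4000.0, 3200.0)
    ax, ay = 3400.0, 2600.0
    positions = []
    for gy in (-0.55, 0.0, 0.55):
        for gx in (-0.7, -0.35, 0.0, 0.35, 0.7):
            positions.append((center[0] + gx * ax, center[1] + gy * ay * 0.9))
    foci = []
    for (x, y) in positions[:n_foci]:
        sc = SubcompartmentSpec(disk_polygon((x, y), radius * 1.5), 0.05, 1.0, 5.0)
        foci.append(
            FocusSpec(centroid=(x, y), contour_class="compact",
                      subcompartments=(sc,), radius=radius)
        )
    return SceneSpec(nucleus_center=center, nucleus_semi_axes=(ax, ay), foci=tuple(foci))


def render_prebleach(scene, **imaging_overrides):
    imaging = noiseless_imaging(n_pre_frames=2, n_post_frames=0, **imaging_overrides)
    movie, truth = simulate_frap_movie(
        scene, imaging, bleach_for(scene, radius=scene.foci[0].radius + 200.0)
    )
    return sum_project_z(movie.frames[0]), movie, truth


class TestProjection:
    def test_sum_projection(self):
        stack = np.stack([np.full((4, 4), v) for v in (1.0, 2.0, 3.0)])
        assert np.all(sum_project_z(stack) == 6.0)
        single = np.random.default_rng(0).random((5, 5))
        assert np.array_equal(sum_project_z(single), single)


class TestNucleus:
    def test_recovers_known_ellipse(self):
        frame, movie, truth = render_prebleach(multi_focus_scene(3))
        mask, area_px = segment_nucleus(frame)
        inter = (mask & truth.nucleus_mask).sum()
        union = (mask | truth.nucleus_mask).sum()
        assert inter / union >= 0.95
        assert area_px == mask.sum()

    def test_blank_frame_gives_empty_mask(self):
        mask, area = segment_nucleus(np.zeros((32, 32)))
        assert area == 0 and not mask.any()

    def test_two_nuclei_keeps_larger_with_warning(self):
        frame = np.zeros((60, 90))
        frame[10:50, 5:40] = 10.0  # larger
        frame[20:40, 55:80] = 10.0  # smaller
        with pytest.warns(UserWarning, match="largest"):
            mask, _ = segment_nucleus(frame)
        assert mask[30, 20] and not mask[30, 65]


class TestFoci:
    def test_finds_three_disjoint_foci_at_true_centroids(self):
        scene = multi_focus_scene(3)
        frame, movie, truth = render_prebleach(scene)
        nucleus, _ = segment_nucleus(frame)
        foci = segment_foci(frame, nucleus, pixel_size_um=0.1, min_area_px=4)
        assert len(foci) == 3
        found = sorted(f.centroid_um for f in foci)
        expected = sorted((f.centroid[0] / 1000.0, f.centroid[1] / 1000.0) for f in scene.foci)
        for (fx, fy), (ex, ey) in zip(found, expected):
            assert math.hypot(fx - ex, fy - ey) <= 0.1  # one pixel

    def test_counts_twelve_foci(self):
        scene = multi_focus_scene(12)
        frame, movie, truth = render_prebleach(scene)
        nucleus, _ = segment_nucleus(frame)
        assert count_foci(frame, nucleus, pixel_size_um=0.1, min_area_px=4) == 12

    def test_blur_merges_subresolution_pair(self):
        """Two foci closer than the PSF FWHM segment as one."""
        center = (3000.0, 2400.0)
        foci = []
        for dx in (-100.0, 100.0):  # 200 nm apart, FWHM 250 nm
            pos = (center[0] + dx, center[1])
            sc = SubcompartmentSpec(disk_polygon(pos, 200.0), 0.05, 1.0, 5.0)
            foci.append(FocusSpec(centroid=pos, contour_class="compact",
                                  subcompartments=(sc,), radius=120.0))
        scene = SceneSpec(nucleus_center=center, nucleus_semi_axes=(2400.0, 1900.0),
                          foci=tuple(foci))
        frame, _, _ = render_prebleach(scene)
        nucleus, _ = segment_nucleus(frame)
        assert count_foci(frame, nucleus, pixel_size_um=0.1, min_area_px=4) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_count_exact_for_well_separated_foci_under_noise(self, seed):
        """Noisy renders of 6 foci separated by > 3 PSF FWHM count exactly."""
        scene = multi_focus_scene(6)
        imaging = noiseless_imaging(
            n_pre_frames=2, n_post_frames=0, shot_noise=True, read_noise_sd=2.0,
            seed=seed,
        )
        movie, _ = simulate_frap_movie(
            scene, imaging, bleach_for(scene, radius=scene.foci[0].radius + 200.0)
        )
        frame = sum_project_z(movie.frames[0])
        nucleus, _ = segment_nucleus(frame)
        assert count_foci(frame, nucleus, pixel_size_um=0.1, min_area_px=4) == 6

    def test_all_background_frame_yields_no_foci(self):
        nucleus = np.zeros((20, 20), bool)
        nucleus[5:15, 5:15] = True
        assert segment_foci(np.ones((20, 20)), nucleus) == []

    def test_mean_intensity_filter_excludes_dim_focus(self):
        frame = np.zeros((30, 30))
        nucleus = np.ones((30, 30), bool)
        frame[10:14, 10:14] = 5.0
        kept = segment_foci(frame, nucleus, intensity_threshold=1.0,
                            min_area_px=4, mean_intensity_min=10.0)
        assert kept == []

    def test_area_invariant_under_translation_and_rotation(self):
        frame = np.zeros((40, 40))
        frame[8:14, 5:17] = 9.0
        nucleus = np.ones((40, 40), bool)
        base = segment_foci(frame, nucleus, intensity_threshold=1.0)[0].area_um2
        shifted = segment_foci(np.roll(frame, (7, 11), (0, 1)), nucleus,
                               intensity_threshold=1.0)[0].area_um2
        rotated = segment_foci(np.rot90(frame), nucleus, intensity_threshold=1.0)[0].area_um2
        assert base == shifted == rotated


class TestSphericity:
    def test_plus_pentomino_polygon_exact(self):
        """Plus pentomino: perimeter 12, hull perimeter 4 + 4*sqrt(2)."""
        poly = np.array([
            (1, 0), (2, 0), (2, 1), (3, 1), (3, 2), (2, 2),
            (2, 3), (1, 3), (1, 2), (0, 2), (0, 1), (1, 1),
        ], dtype=float)
        assert polygon_perimeter(poly) == pytest.approx(12.0, abs=1e-12)
        expected = (4 + 4 * math.sqrt(2)) / 12.0
        assert sphericity_from_polygon(poly) == pytest.approx(expected, abs=1e-12)

    def test_square_polygon_is_exactly_one(self):
        square = np.array([(0, 0), (4, 0), (4, 4), (0, 4)], dtype=float)
        assert sphericity_from_polygon(square) == pytest.approx(1.0, abs=1e-12)

    def test_rasterized_disk_close_to_one(self):
        rr, cc = np.mgrid[0:60, 0:60]
        disk = (rr - 30) ** 2 + (cc - 30) ** 2 <= 20**2
        assert sphericity_index(disk) == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("n_spikes", [2, 4, 8])
    def test_spikes_reduce_sphericity_monotonically(self, n_spikes):
        """Adding boundary spikes to a disk never raises the index."""
        def spiky(n):
            rr, cc = np.mgrid[0:120, 0:120]
            mask = (rr - 60) ** 2 + (cc - 60) ** 2 <= 30**2
            ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
            for a in ang:
                for t in np.linspace(0, 24, 60):
                    r = int(round(60 + (30 + t) * math.sin(a)))
                    c = int(round(60 + (30 + t) * math.cos(a)))
                    mask[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2] = True
            return mask

        base = sphericity_index(spiky(0) if n_spikes == 0 else spiky(n_spikes))
        smoother = sphericity_index(spiky(max(n_spikes // 2, 0))) if n_spikes > 2 else None
        rr, cc = np.mgrid[0:120, 0:120]
        disk = (rr - 60) ** 2 + (cc - 60) ** 2 <= 30**2
        assert base <= sphericity_index(disk) + 1e-9
        if smoother is not None:
            assert base <= smoother + 1e-9

    def test_bounded_by_one_on_large_masks(self):
        rng = np.random.default_rng(3)
        rr, cc = np.mgrid[0:80, 0:80]
        blob = (rr - 40) ** 2 / 900 + (cc - 40) ** 2 / 400 <= 1
        assert sphericity_index(blob) <= 1 + 0.03

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n=st.integers(3, 40),
        scale=st.floats(0.1, 1e3),
        phase=st.floats(0, 2 * math.pi),
    )
    def test_convex_polygon_sphericity_is_one(self, n, scale, phase):
        """Any regular polygon is its own convex hull: index exactly 1."""
        ang = np.linspace(0, 2 * math.pi, n, endpoint=False) + phase
        poly = np.column_stack([scale * np.cos(ang), scale * np.sin(ang)])
        assert sphericity_from_polygon(poly) == pytest.approx(1.0, abs=1e-9)

    def test_small_mask_rejected(self):
        tiny = np.zeros((5, 5), bool)
        tiny[2, 2] = True
        with pytest.raises(ValueError, match="small"):
            sphericity_index(tiny)


def _focus(frame_index, x_um, y_um, mask=None):
    if mask is None:
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:4] = True
    return LabeledFocus(
        focus_id=0, frame_index=frame_index, mask=mask, area_um2=0.04,
        centroid_um=(x_um, y_um), perimeter_um=0.8, hull_perimeter_um=0.8,
        sphericity=1.0, mean_intensity=10.0,
    )


class TestTracking:
    def test_stationary_focus_single_track(self):
        frames = [[_focus(i, 1.0, 1.0)] for i in range(10)]
        tracks = track_foci(frames)
        assert len(tracks) == 1 and len(tracks[0].foci) == 10

    def test_drifting_focus_links_within_gate(self):
        frames = [[_focus(i, 1.0 + 0.1 * i, 1.0)] for i in range(8)]
        tracks = track_foci(frames, max_jump_um=0.5)
        assert len(tracks) == 1

    def test_jump_beyond_gate_starts_new_track(self):
        frames = [[_focus(0, 1.0, 1.0)], [_focus(1, 5.0, 5.0)]]
        tracks = track_foci(frames, max_jump_um=1.0)
        assert len(tracks) == 2

    def test_displacement_345_triangle(self):
        times = np.array([-5.0, 0.0, 40.0])
        track = track_foci(
            [[_focus(0, 10.0, 10.0)], [_focus(1, 10.1, 10.1)], [_focus(2, 10.3, 10.4)]],
            max_jump_um=1.0,
        )[0]
        assert focus_displacement(track, times) == pytest.approx(0.5, abs=1e-9)

    def test_displacement_zero_for_stationary(self):
        times = np.array([-5.0, 0.0, 40.0])
        track = track_foci([[_focus(i, 2.0, 2.0)] for i in range(3)])[0]
        assert focus_displacement(track, times) == pytest.approx(0.0, abs=1e-12)

    def test_displacement_requires_pre_and_post(self):
        times = np.array([-10.0, -5.0])
        track = track_foci([[_focus(0, 1.0, 1.0)], [_focus(1, 1.0, 1.0)]])[0]
        with pytest.raises(ValueError, match="displacement"):
            focus_displacement(track, times)

    def test_drifting_phantom_displacement_matches_truth(self):
        """A focus drifting 10 nm/s covers 0.45 µm between the -5 s and
        +40 s reference frames."""
        center = (2600.0, 2100.0)
        sc = SubcompartmentSpec(disk_polygon(center, 800.0), 0.2, 1.0, 5.0)
        focus = FocusSpec(centroid=center, contour_class="compact",
                          subcompartments=(sc,), radius=450.0,
                          drift_velocity=(10.0, 0.0))
        scene = SceneSpec(nucleus_center=center, nucleus_semi_axes=(2200.0, 1700.0),
                          foci=(focus,))
        imaging = noiseless_imaging(n_pre_frames=2, n_post_frames=10)
        movie, truth = simulate_frap_movie(
            scene, imaging, bleach_for(scene, depth=0.3, radius=1500.0)
        )
        frames2d = [sum_project_z(f) for f in movie.frames]
        nucleus, _ = segment_nucleus(frames2d[0])
        per_frame = [
            segment_foci(frames2d[i], nucleus, pixel_size_um=0.1, min_area_px=4,
                         frame_index=i)
            for i in range(movie.n_frames)
        ]
        tracks = track_foci(per_frame, max_jump_um=1.0)
        track = max(tracks, key=lambda t: len(t.foci))
        disp = focus_displacement(track, movie.times)
        assert disp == pytest.approx(0.45, abs=0.1)  # within one pixel
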