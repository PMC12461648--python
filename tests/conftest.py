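import math

import numpy as np
import pytest

from frapsr.phantom import (
    BleachEvent,
    FocusSpec,
    ImagingSpec,
    SceneSpec,
    SubcompartmentSpec,
    imaging_preset,
    preset_bleach,
    preset_scene,
    simulate_frap_movie,
)


def disk_polygon(center, radius, n=24):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def compact_scene(k=0.0693147, mobile_fraction=1.0, nucleoplasm_k=0.3, radius=500.0):
    """Small single-focus scene for fast unit tests."""
    center = (2600.0, 2100.0)
    sc = SubcompartmentSpec(
        region=disk_polygon(center, radius * 1.5),
        k_exchange=k,
        mobile_fraction=mobile_fraction,
        brightness=5.0,
    )
    focus = FocusSpec(
        centroid=center, contour_class="compact", subcompartments=(sc,), radius=radius
    )
    return SceneSpec(
        nucleus_center=center,
        nucleus_semi_axes=(2200.0, 1700.0),
        foci=(focus,),
        nucleoplasm_k=nucleoplasm_k,
    )


def two_half_scene(k_fast=0.1386, k_slow=0.0231, jitter=0.0):
    """Amorphous two-lobe focus whose halves recover at different rates."""
    center = (2600.0, 2100.0)
    cx, cy = center
    big = 2000.0
    left = np.array([[cx - big, cy - big], [cx, cy - big], [cx, cy + big], [cx - big, cy + big]])
    right = np.array([[cx, cy - big], [cx + big, cy - big], [cx + big, cy + big], [cx, cy + big]])
    scs = (
        SubcompartmentSpec(left, k_fast, 1.0, 5.0),
        SubcompartmentSpec(right, k_slow, 1.0, 5.0),
    )
    focus = FocusSpec(
        centroid=center,
        contour_class="amorphous",
        subcompartments=scs,
        lobes=((-350.0, 0.0, 400.0), (350.0, 0.0, 400.0)),
        shape_jitter_amplitude=jitter,
    )
    return SceneSpec(
        nucleus_center=center, nucleus_semi_axes=(2200.0, 1700.0), foci=(focus,)
    )


def noiseless_imaging(**overrides):
    kw = dict(
        pixel_size=100.0,
        psf_fwhm=250.0,
        shot_noise=False,
        read_noise_sd=0.0,
        camera_offset=100.0,
        seed=0,
        n_z=1,
    )
    kw.update(overrides)
    return ImagingSpec(**kw)


def bleach_for(scene, depth=1.0, radius=900.0):
    return BleachEvent(center=scene.foci[0].centroid, radius=radius, depth=depth)


@pytest.fixture(scope="session")
def compact_noiseless():
    """Noiseless compact-focus movie with matched nucleoplasm kinetics
    (every bleached voxel shares one rate, so fits are exact)."""
    k = 0.0693147
    scene = compact_scene(k=k, nucleoplasm_k=k)
    movie, truth = simulate_frap_movie(scene, noiseless_imaging(), bleach_for(scene))
    return movie, truth, k


@pytest.fixture(scope="session")
def two_half_noiseless():
    scene = two_half_scene()
    movie, truth = simulate_frap_movie(
        scene, noiseless_imaging(pixel_size=50.0, psf_fwhm=120.0), bleach_for(scene, radius=1100.0)
    )
    return movie, truth


@pytest.fixture(scope="session")
def preset_compact_movie():
    scene = preset_scene("untreated_compact")
    imaging = imaging_preset("disim", seed=0, n_z=1)
    return simulate_frap_movie(scene, imaging, preset_bleach(scene))
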