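import numpy as np
import pytest

from vamorph.morpho import measure_record, skeleton_centerline
from vamorph.phantom import PhantomSpec, RadiusProfile, build_radius_profile, rasterize_phantom
from vamorph.segment import CutPlane, SegmentationParams, isolate_va


def noise_free_spec(profile, **kwargs) -> PhantomSpec:
    defaults = dict(
        length_mm=10.0,
        bend_radius_mm=20.0,
        tilt_deg=15.0,
        blur_sigma_mm=0.0,
        noise_sd_hu=0.0,
        spacing=(0.2, 0.2, 0.2),
    )
    defaults.update(kwargs)
    return PhantomSpec(profile, **defaults)


def segment_phantom(image, ground_truth, params=None):
    lm = ground_truth.landmarks
    return isolate_va(
        image,
        params or SegmentationParams(),
        lm.seed_point,
        CutPlane(tuple(lm.vestibule_exit), tuple(lm.exit_normal)),
        CutPlane(tuple(lm.operculum), tuple(lm.operculum_normal)),
    )


def measure_phantom(spec):
    """Full measurement chain on one phantom; returns (gt, record, centerline, mask)."""
    image, _truth_lumen, gt = rasterize_phantom(spec)
    va = segment_phantom(image, gt)
    lm = gt.landmarks
    cl = skeleton_centerline(va, lm.vestibule_exit, lm.operculum)
    rec = measure_record(image, va, cl, ear_id="test", rater_id="r1")
    return gt, rec, cl, va


@pytest.fixture(scope="session")
def cylinder():
    """Noise-free straight axial cylinder, r = 1.5 mm, L = 10 mm, 0.2 mm iso."""
    spec = noise_free_spec(
        RadiusProfile(1.5, 1.5, 1.5), bend_radius_mm=None, tilt_deg=0.0
    )
    image, truth_lumen, gt = rasterize_phantom(spec)
    return spec, image, truth_lumen, gt


@pytest.fixture(scope="session")
def central_dilatation():
    """Curved, tilted duct dilated at mid-course (r = 0.4 / 1.6 / 0.5 mm)."""
    spec = noise_free_spec(build_radius_profile("central_dilatation", 0.4, 1.6, 0.5))
    gt, rec, cl, va = measure_phantom(spec)
    return spec, gt, rec, cl, va


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
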