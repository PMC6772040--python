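"""Shared fixtures: small grids, seeded fields and phantom cohorts.

Everything is generated programmatically at test time; heavyweight objects
are session-scoped so the suite stays fast.
"""

import numpy as np
import pytest

import volref as vr

ANISO = (2.07, 2.07, 8.0)


@pytest.fixture(scope="session")
def small_grid():
    return vr.GridInfo((16, 16, 16), ANISO)


@pytest.fixture(scope="session")
def smooth_field():
    """Seeded smooth diffeomorphic field on a 16^3 grid."""
    return vr.make_diffeomorphism(
        (16, 16, 16), ANISO, smoothness_mm=15.0, magnitude_mm=4.0,
        min_jacobian=0.5, seed=11,
    )


@pytest.fixture(scope="session")
def phantom48():
    spec = vr.PhantomSpec(shape=(48, 48, 48), seed=0)
    image, labels = vr.make_phantom(spec)
    return image, labels


@pytest.fixture(scope="session")
def body48(phantom48):
    image, _ = phantom48
    return vr.MaskVolume(image.channel("mask") > 0.5, image.grid)


@pytest.fixture(scope="session")
def cohort_fields48():
    """Five seeded diffeomorphisms on the 48^3 grid (min J >= 0.2)."""
    return [
        vr.make_diffeomorphism(
            (48, 48, 48), ANISO, smoothness_mm=20.0, magnitude_mm=6.0,
            min_jacobian=0.2, seed=s,
        )
        for s in range(5)
    ]


@pytest.fixture(scope="session")
def reference_result48(phantom48, body48, cohort_fields48):
    """Fitted average-volume reference on the 48^3 phantom cohort."""
    image, _ = phantom48
    cfg = vr.SynthesisConfig(mask=body48)
    return vr.build_reference(image, cohort_fields48, cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """32^3 phantom cohort of 3 with images, labels and ground-truth fields."""
    spec = vr.PhantomSpec(shape=(32, 32, 32), seed=2)
    template, tlabels, subjects = vr.make_cohort(
        spec, n_subjects=3, deform_params={"magnitude_mm": 4.0}, seed=5
    )
    return template, tlabels, subjects
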