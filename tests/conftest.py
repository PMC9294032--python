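"""Shared fixtures: phantom study setups and independent projection oracles.

Session-scoped fixtures carry the full-scale study configuration (default
phantom, default C-arm, the 51x51 coarse DRR database) so the expensive
renders happen once per test session.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import spinereg as sr
from spinereg.drr import build_drr_database, hu_to_mu
from spinereg.geometry import CArmIntrinsics, CArmPose, rotation_matrix


# --------------------------------------------------------------------------
# independent pinhole oracle (brute-force ray/detector-plane intersection)
# --------------------------------------------------------------------------

def pinhole_oracle(intrinsics: CArmIntrinsics, pose: CArmPose,
                   points: np.ndarray) -> np.ndarray:
    """Project world points by explicit ray-plane intersection.

    Moves the rig rigidly (rotate about the isocenter, then translate),
    builds the detector plane from its world-frame basis vectors, and
    intersects each source-to-point ray with it.  Shares no code with the
    projection-matrix path.
    """
    ic = intrinsics.isocenter
    t = np.asarray(pose.translation, float)
    R = rotation_matrix(pose.rotation)

    def rig(p_cam):
        return R @ (np.asarray(p_cam, float) - ic) + ic + t

    source = rig([0.0, 0.0, 0.0])
    cop_w = rig([intrinsics.sdd, 0.0, 0.0])
    e_u, e_v, normal = R @ [0, 1, 0], R @ [0, 0, 1], R @ [1, 0, 0]
    u0, v0 = intrinsics.cop
    px, py = intrinsics.pixel_size
    out = []
    for p in np.atleast_2d(points):
        d = p - source
        tau = normal @ (cop_w - source) / (normal @ d)
        hit = source + tau * d
        out.append([u0 + (hit - cop_w) @ e_u / px, v0 + (hit - cop_w) @ e_v / py])
    return np.asarray(out)


@pytest.fixture
def oracle():
    return pinhole_oracle


# --------------------------------------------------------------------------
# small, fast setup for unit tests
# --------------------------------------------------------------------------

@pytest.fixture
def small_intrinsics() -> CArmIntrinsics:
    return CArmIntrinsics(sdd=800.0, pixel_size=(2.0, 2.0), detector_size=(96, 96))


@pytest.fixture
def small_phantom():
    vol, lms = sr.generate_spine_phantom(
        n_vertebrae=4, spacing_mm=26.0, body_radius_mm=10.0,
        volume_shape=(36, 36, 60), voxel_mm=2.5, seed=11)
    return vol, lms


# --------------------------------------------------------------------------
# full-scale study setup (session scope)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def study():
    """Default phantom + default C-arm geometry, world-frame landmarks."""
    volume, lms = sr.generate_spine_phantom(seed=1)
    intr = sr.default_intrinsics()
    lms_world = lms.translated(intr.isocenter - volume.center)
    return {"volume": volume, "landmarks": lms, "landmarks_world": lms_world,
            "intrinsics": intr, "mu": hu_to_mu(volume)}


@pytest.fixture(scope="session")
def full_db(study):
    """The 51x51 (+/-50 mm, 2 mm) coarse database; build time recorded."""
    t0 = time.perf_counter()
    db = build_drr_database(study["mu"], study["intrinsics"],
                            range_mm=50.0, step_mm=2.0, coarse_pixel_mm=4.0)
    elapsed = time.perf_counter() - t0
    return db, elapsed


@pytest.fixture(scope="session")
def hidden_capture_case(study):
    """Noiseless radiograph at a hidden in-grid in-plane pose."""
    rng = np.random.default_rng(2024)
    ty, tz = rng.choice(np.arange(-30, 31, 2), size=2)
    pose = CArmPose(translation=(0.0, float(ty), float(tz)))
    xray, lms2d, truth = sr.simulate_intraoperative_xray(
        study["volume"], study["intrinsics"], pose, study["landmarks"])
    return {"xray": xray, "landmarks2d": lms2d, "truth": truth, "pose": pose}
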