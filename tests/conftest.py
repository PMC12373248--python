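"""Shared fixtures and geometry helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from chinpoint import LandmarkSet, Point3, SubjectRecord

#: a plausible midline profile in sagittal (anterior, superior) mm coordinates
BASE_PROFILE: dict[str, tuple[float, float]] = {
    "G'": (0.0, 80.0),
    "Sn'": (0.0, 0.0),
    "Pn'": (20.0, 10.0),
    "Col": (8.0, 2.0),
    "UL": (11.0, -12.0),
    "LL": (9.5, -24.0),
    "ACP": (5.0, -55.0),
}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240517)


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation matrix + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(0.0, 40.0, size=3)
    return R, t


def landmarks_from_profile(
    profile: dict[str, tuple[float, float]] | None = None,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    lateral: dict[str, float] | None = None,
) -> LandmarkSet:
    """Embed a 2D profile as a 3D landmark set, optionally posed rigidly."""
    profile = dict(BASE_PROFILE if profile is None else profile)
    lateral = lateral or {}
    pts = {}
    for name, (a, s) in profile.items():
        p = np.array([a, s, lateral.get(name, 0.0)])
        if rotation is not None:
            p = rotation @ p
        if translation is not None:
            p = p + translation
        pts[name] = Point3(*p)
    return LandmarkSet(pts)


def record_from_profile(
    subject_id: str = "S001",
    sex: str = "female",
    timepoint: str = "T0",
    **kwargs,
) -> SubjectRecord:
    return SubjectRecord(
        subject_id=subject_id,
        sex=sex,
        timepoint=timepoint,
        landmark_set=landmarks_from_profile(**kwargs),
    )


def profile_with_chin_on_ray(
    rng: np.random.Generator, target_angle: float = 170.0
) -> dict[str, tuple[float, float]]:
    """Random profile whose ACP sits exactly on the target-convexity ray.

    The chin is placed on the posterior-rotation branch, so the
    construction's fixed point applies: MCP must coincide with ACP.
    """
    face_height = rng.uniform(60.0, 95.0)
    eps = math.radians(180.0 - target_angle)
    depth = rng.uniform(40.0, 70.0)  # vertical drop to the chin
    t = depth / math.cos(eps)
    acp = (-t * math.sin(eps), -depth)
    profile = dict(BASE_PROFILE)
    profile["G'"] = (0.0, face_height)
    profile["ACP"] = acp
    profile["Pn'"] = (rng.uniform(16.0, 24.0), rng.uniform(6.0, 12.0))
    profile["Col"] = (rng.uniform(6.0, 10.0), rng.uniform(1.0, 4.0))
    profile["UL"] = (rng.uniform(8.0, 14.0), rng.uniform(-16.0, -8.0))
    profile["LL"] = (rng.uniform(6.0, 12.0), rng.uniform(-30.0, -18.0))
    return profile
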