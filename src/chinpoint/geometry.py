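"""Midsagittal measurement frame and 2D profile-geometry primitives.

All downstream measurements happen in a 2D sagittal coordinate system
(*a* = millimetres along the anterior axis, positive toward the front of
the face; *s* = millimetres along the superior axis, positive toward the
top of the head).  The frame is fitted to each subject's midline
landmarks as a stand-in for natural head position: a total-least-squares
plane through the seven midline points, with the in-plane superior axis
aligned to the subnasale->glabella direction and the origin at subnasale.

Sign convention: a point lying on the *anterior* side of a reference
line has a positive signed distance.  This makes protrusive lips
positive and retrusive lips negative, the usual cephalometric reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = [
    "ProfilePoint",
    "SagittalLine",
    "SagittalFrame",
    "fit_midsagittal_frame",
    "project",
    "lateral_coordinate",
    "facial_convexity_angle",
    "signed_distance_to_line",
    "horizontal_offset_to_line",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class ProfilePoint:
    """A 2D point in the sagittal plane (anterior, superior), in mm."""

    a: float
    s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.s)):
            raise GeometryError(f"non-finite profile point ({self.a}, {self.s})")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.s], dtype=float)


@dataclass(frozen=True)
class SagittalLine:
    """An infinite line in the sagittal plane: anchor point + unit direction."""

    p0: ProfilePoint
    direction: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (2,):
            raise GeometryError("line direction must be a 2-vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise GeometryError("line direction must be unit length")
        # renormalize to the internal tolerance
        object.__setattr__(self, "direction", d / np.linalg.norm(d))

    @classmethod
    def through_points(cls, p: ProfilePoint, q: ProfilePoint) -> "SagittalLine":
        """Line anchored at ``p`` pointing toward ``q``."""
        d = q.as_array() - p.as_array()
        n = np.linalg.norm(d)
        if n <= 1e-6:
            raise GeometryError(
                f"cannot build a line through coincident points ({p.a}, {p.s})"
            )
        return cls(p0=p, direction=d / n)

    def anterior_normal(self) -> np.ndarray:
        """Unit normal pointing toward the anterior (+a) side of the line.

        For a (nearly) horizontal line anteriority is undefined; the
        superior-pointing normal is returned as a deterministic tie-break.
        """
        da, ds = self.direction
        n = np.array([ds, -da])
        if n[0] < -1e-12 or (abs(n[0]) <= 1e-12 and n[1] < 0.0):
            n = -n
        return n

    def point_at(self, t: float) -> ProfilePoint:
        p = self.p0.as_array() + t * self.direction
        return ProfilePoint(float(p[0]), float(p[1]))


@dataclass(frozen=True)
class SagittalFrame:
    """Orthonormal right-handed measurement frame in 3D scan coordinates.

    ``lateral_axis == anterior_axis x superior_axis``; positive lateral is
    toward the subject's left.
    """

    origin: np.ndarray
    anterior_axis: np.ndarray
    superior_axis: np.ndarray
    lateral_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "anterior_axis", "superior_axis", "lateral_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise GeometryError(f"frame {name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        a, s, l = self.anterior_axis, self.superior_axis, self.lateral_axis
        gram_err = max(
            abs(a @ a - 1.0), abs(s @ s - 1.0), abs(l @ l - 1.0),
            abs(a @ s), abs(a @ l), abs(s @ l),
        )
        if gram_err > 1e-6:
            raise GeometryError("frame axes are not orthonormal")
        if np.linalg.norm(np.cross(a, s) - l) > 1e-6:
            raise GeometryError("frame axes are not right-handed")


def fit_midsagittal_frame(landmarks) -> SagittalFrame:
    """Fit the measurement frame to a :class:`~chinpoint.landmarks.LandmarkSet`.

    The sagittal plane is the total-least-squares plane through the seven
    midline landmarks (minimizing summed squared lateral distances).  The
    superior axis is the in-plane unit vector best aligned with
    subnasale -> glabella; the anterior axis is the in-plane orthogonal
    direction, signed so pronasale has a positive anterior coordinate;
    the origin is subnasale.
    """
    pts = landmarks.as_matrix()
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # plane normal = direction of least variance
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    if sing[1] <= 1e-9 * max(sing[0], 1.0):
        raise GeometryError("landmarks are (near-)collinear; sagittal plane undefined")
    normal = vt[2]

    sn = landmarks["Sn'"].as_array()
    g = landmarks["G'"].as_array()
    pn = landmarks["Pn'"].as_array()

    v = g - sn
    v_in = v - (v @ normal) * normal
    nv = np.linalg.norm(v_in)
    if nv <= 1e-9:
        raise GeometryError("G' and Sn' coincide in the sagittal plane")
    superior = v_in / nv

    anterior = np.cross(superior, normal)
    anterior /= np.linalg.norm(anterior)
    if (pn - sn) @ anterior < 0.0:
        anterior = -anterior
    lateral = np.cross(anterior, superior)
    return SagittalFrame(
        origin=sn, anterior_axis=anterior, superior_axis=superior, lateral_axis=lateral
    )


def project(landmarks, frame: SagittalFrame) -> dict[str, ProfilePoint]:
    """Express every landmark as an (a, s) profile point; lateral is dropped."""
    out: dict[str, ProfilePoint] = {}
    for name, p in landmarks.items():
        rel = p.as_array() - frame.origin
        out[name] = ProfilePoint(
            float(rel @ frame.anterior_axis), float(rel @ frame.superior_axis)
        )
    return out


def lateral_coordinate(point, frame: SagittalFrame) -> float:
    """Signed lateral (out-of-plane) coordinate of a 3D landmark, in mm."""
    return float((point.as_array() - frame.origin) @ frame.lateral_axis)


def facial_convexity_angle(
    g: ProfilePoint, sn: ProfilePoint, pog: ProfilePoint
) -> float:
    """Interior angle at subnasale between the rays sn->g and sn->pog, degrees.

    180 deg is a perfectly straight profile; smaller values mean the chin
    sits off the glabella-subnasale line.  The value lies in (0, 180].
    """
    u = g.as_array() - sn.as_array()
    w = pog.as_array() - sn.as_array()
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu <= 1e-9 or nw <= 1e-9:
        raise GeometryError("zero-length ray in convexity angle")
    c = np.clip((u @ w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def signed_distance_to_line(p: ProfilePoint, line: SagittalLine) -> float:
    """Perpendicular distance of ``p`` from the infinite line, in mm.

    Positive when ``p`` lies on the anterior side of the line.
    """
    n = line.anterior_normal()
    return float(n @ (p.as_array() - line.p0.as_array()))


def horizontal_offset_to_line(p: ProfilePoint, line: SagittalLine) -> float:
    """Purely anteroposterior offset of ``p`` from the line at p's height.

    Alternative distance convention for sensitivity analyses: the signed
    difference between p.a and the line's anterior coordinate at s = p.s.
    Requires a non-horizontal line.
    """
    da, ds = line.direction
    if abs(ds) <= 1e-9:
        raise GeometryError("horizontal offset undefined for a horizontal line")
    t = (p.s - line.p0.s) / ds
    a_line = line.p0.a + t * da
    return float(p.a - a_line)
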