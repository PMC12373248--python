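"""Modified chin point (MCP) construction.

The construction standardizes the chin position at a fixed angle of
facial convexity (default 170 deg, the value found to be stable in
aesthetically balanced profiles):

1. *Line A* runs through glabella (G') and subnasale (Sn').
2. *Line M* starts at Sn' and makes the target convexity angle with the
   ray Sn'->G', rotated to the posterior side of line A and pointing
   inferiorly.
3. The actual chin point (ACP, the soft-tissue pogonion) is translated
   horizontally (constant superior coordinate) onto line M; the landing
   point is the MCP.
4. ``x`` is the signed horizontal ACP->MCP offset (anterior-positive);
   its magnitude is the ACP-to-MCP distance reported clinically.

A chin that already realizes the target convexity on the posterior
branch lies on line M, so MCP == ACP and x == 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .geometry import ProfilePoint, SagittalLine, facial_convexity_angle

__all__ = [
    "ChinConstruction",
    "construct_line_A",
    "construct_line_M",
    "compute_mcp",
    "construct_chin",
    "acp_mcp_distance",
]

#: line M closer than this (deg) to horizontal is refused as ill-conditioned
_MIN_ANGLE_FROM_HORIZONTAL = 1.0


@dataclass(frozen=True)
class ChinConstruction:
    """Full record of one chin-point construction for a subject/timepoint."""

    line_A: SagittalLine
    line_M: SagittalLine
    acp: ProfilePoint
    mcp: ProfilePoint
    x: float  # signed horizontal ACP->MCP offset, mm, anterior-positive
    target_angle: float  # deg


def construct_line_A(g: ProfilePoint, sn: ProfilePoint) -> SagittalLine:
    """Line through glabella and subnasale, directed from G' toward Sn'."""
    return SagittalLine.through_points(g, sn)


def construct_line_M(
    line_A: SagittalLine, sn: ProfilePoint, target_angle: float = 170.0
) -> SagittalLine:
    """Ray from subnasale making ``target_angle`` with the ray Sn'->G'.

    Of the two rays realizing the angle, the one on the posterior
    (negative-anterior) side of line A is taken; because the angle
    exceeds 90 deg the ray always points inferiorly.  Returned as an
    infinite line anchored at Sn'.
    """
    if not (90.0 < target_angle <= 180.0):
        raise ParameterError(
            f"target convexity angle must be in (90, 180], got {target_angle}"
        )
    if target_angle - 90.0 < _MIN_ANGLE_FROM_HORIZONTAL:
        raise ParameterError(
            f"target angle {target_angle} deg leaves line M within "
            f"{_MIN_ANGLE_FROM_HORIZONTAL} deg of horizontal; the horizontal "
            "projection of the chin point is ill-conditioned"
        )
    off = sn.as_array() - line_A.p0.as_array()
    d = line_A.direction
    perp = off - (off @ d) * d
    if np.linalg.norm(perp) > 1e-6:
        raise GeometryError("subnasale does not lie on line A")

    u = -d  # Sn' -> G' (line A is directed G' -> Sn')
    theta = np.radians(target_angle)
    ct, st = np.cos(theta), np.sin(theta)
    cand = [
        np.array([ct * u[0] - st * u[1], st * u[0] + ct * u[1]]),
        np.array([ct * u[0] + st * u[1], -st * u[0] + ct * u[1]]),
    ]
    n_a = line_A.anterior_normal()
    # posterior side of line A; at 180 deg both candidates coincide
    direction = min(cand, key=lambda c: float(c @ n_a))
    return SagittalLine(p0=sn, direction=direction)


def compute_mcp(
    acp: ProfilePoint,
    line_M: SagittalLine,
    *,
    line_A: SagittalLine,
    target_angle: float,
) -> ChinConstruction:
    """Horizontally translate the ACP onto line M and record the offset x."""
    da, ds = line_M.direction
    if abs(ds) <= np.sin(np.radians(_MIN_ANGLE_FROM_HORIZONTAL)):
        angle_from_horizontal = float(np.degrees(np.arcsin(abs(ds))))
        raise GeometryError(
            "line M is within "
            f"{angle_from_horizontal:.3f} deg of horizontal; the horizontal "
            "intersection with the chin level is ill-conditioned"
        )
    t = (acp.s - line_M.p0.s) / ds
    mcp = ProfilePoint(float(line_M.p0.a + t * da), acp.s)
    x = mcp.a - acp.a
    return ChinConstruction(
        line_A=line_A,
        line_M=line_M,
        acp=acp,
        mcp=mcp,
        x=float(x),
        target_angle=float(target_angle),
    )


def construct_chin(
    g: ProfilePoint,
    sn: ProfilePoint,
    acp: ProfilePoint,
    target_angle: float = 170.0,
) -> ChinConstruction:
    """Run the full construction from the three defining landmarks."""
    line_a = construct_line_A(g, sn)
    line_m = construct_line_M(line_a, sn, target_angle)
    return compute_mcp(acp, line_m, line_A=line_a, target_angle=target_angle)


def acp_mcp_distance(construction: ChinConstruction) -> float:
    """Unsigned ACP-to-MCP horizontal distance |x|, mm."""
    return abs(construction.x)


def convexity_of_construction(construction: ChinConstruction, g: ProfilePoint) -> float:
    """Convexity angle realized by the MCP (equals the target by design)."""
    return facial_convexity_angle(g, construction.line_M.p0, construction.mcp)
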