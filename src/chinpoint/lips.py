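"""Lip position metrics against the Steiner S and Ricketts E lines.

The S line joins the columella point to the soft-tissue pogonion; the E
line joins the pronasale (nose tip) to the pogonion.  Both are built
twice per subject/timepoint — once anchored at the actual chin point
(ACP) and once at the modified chin point (MCP) — and the signed
distances of the upper and lower lip to each line are recorded
(anterior-positive, mm).

Distances are perpendicular point-to-line distances in the sagittal
plane by default; a purely anteroposterior ("horizontal") offset mode is
available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chin import ChinConstruction
from .errors import ParameterError
from .geometry import (
    ProfilePoint,
    SagittalLine,
    horizontal_offset_to_line,
    signed_distance_to_line,
)

__all__ = [
    "LipMeasurements",
    "build_s_line",
    "build_e_line",
    "measure_subject",
    "aesthetic_flag",
    "LIP_VARIABLES",
]

LIP_VARIABLES: tuple[str, ...] = ("ul_s", "ul_e", "ll_s", "ll_e")


@dataclass(frozen=True)
class LipMeasurements:
    """Signed lip-to-line distances (mm) for one pogonion source."""

    pogonion_source: str  # "ACP" | "MCP"
    ul_s: float
    ul_e: float
    ll_s: float
    ll_e: float

    def as_dict(self) -> dict[str, float]:
        return {v: getattr(self, v) for v in LIP_VARIABLES}


def build_s_line(col: ProfilePoint, pog: ProfilePoint) -> SagittalLine:
    """Steiner S line: columella point -> pogonion (ACP or MCP)."""
    return SagittalLine.through_points(col, pog)


def build_e_line(pn: ProfilePoint, pog: ProfilePoint) -> SagittalLine:
    """Ricketts E line: pronasale -> pogonion (ACP or MCP)."""
    return SagittalLine.through_points(pn, pog)


def _distance(p: ProfilePoint, line: SagittalLine, mode: str) -> float:
    if mode == "perpendicular":
        return signed_distance_to_line(p, line)
    if mode == "horizontal":
        return horizontal_offset_to_line(p, line)
    raise ParameterError(f"unknown distance mode {mode!r}")


def measure_subject(
    profile: Mapping[str, ProfilePoint],
    construction: ChinConstruction,
    mode: str = "perpendicular",
) -> tuple[LipMeasurements, LipMeasurements]:
    """Measure the four lip distances under the ACP- and MCP-based lines.

    ``profile`` must contain the projected ``Col``, ``Pn'``, ``UL`` and
    ``LL`` points.  The S and E lines share their nose anchors across the
    two pogonion sources; only the chin anchor switches.
    """
    col, pn = profile["Col"], profile["Pn'"]
    ul, ll = profile["UL"], profile["LL"]
    out = []
    for source, pog in (("ACP", construction.acp), ("MCP", construction.mcp)):
        s_line = build_s_line(col, pog)
        e_line = build_e_line(pn, pog)
        out.append(
            LipMeasurements(
                pogonion_source=source,
                ul_s=_distance(ul, s_line, mode),
                ul_e=_distance(ul, e_line, mode),
                ll_s=_distance(ll, s_line, mode),
                ll_e=_distance(ll, e_line, mode),
            )
        )
    return out[0], out[1]


def aesthetic_flag(m: LipMeasurements, window: float = 2.0) -> dict[str, str]:
    """Flag each distance as within/outside the aesthetic window.

    Lip positions within about +/-2 mm of the S and E lines are rated
    most aesthetic; the window is a closed interval (|d| <= window).
    """
    if not window > 0:
        raise ParameterError(f"aesthetic window must be positive, got {window}")
    return {
        v: ("within" if abs(d) <= window else "outside")
        for v, d in m.as_dict().items()
    }
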