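"""Per-tooth movement measures in the anatomical reference frame.

After the T1 scan has been registered onto the T2 implants, every tooth
landmark of both timepoints lives in one common frame.  This module
expresses them in the anatomical coordinate system built on the T2 scan
(x superior, y anterior, z transverse, origin at PNS'), measures each
tooth's sagittal long-axis inclination, and forms the T1 - T2 change
variables:

* ``dx`` — vertical change per landmark; negative values indicate
  intrusion, positive extrusion.
* ``dy`` — sagittal change per landmark; positive values indicate distal
  movement (retraction), negative mesial movement.
* ``m``  — 3D displacement magnitude per landmark.
* ``dL`` — crown-to-apex length change; positive values indicate root
  shortening (resorption).
* ``dtheta`` — sagittal inclination change; positive values indicate
  crown-posterior / root-anterior tipping (distal crown tipping for the
  posterior teeth, lingual "torque" change for the incisors).

Table-style variable names follow the conventional shorthand: ``U6C_X``
and ``U6C_Y`` for the molar-cusp linear changes, ``M6C``/``M6R`` for
displacements, ``L6`` for root-length change, and ``Tip6``, ``Tip3``,
``Tor2``, ``Tor1`` for the angle changes of molar, canine, lateral and
central incisor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import Plane, ReferenceFrame, build_reference_frame, sagittal_axis_angle
from .landmarks import TEETH, LandmarkSet

#: angle-change variable name per tooth (Tip = tipping, Tor = torque)
ANGLE_NAMES = {"U6": "Tip6", "U3": "Tip3", "U2": "Tor2", "U1": "Tor1"}


def build_frame(t2: LandmarkSet) -> tuple[ReferenceFrame, Plane, Plane]:
    """Anatomical frame of a T2 scan.

    The occlusal plane (plane 1) is fitted to the four crown points
    U6C and U1C of both sides; ANS and PNS orient the axes.
    """
    occlusal = np.stack(
        [
            t2.get("U6C", "L"),
            t2.get("U6C", "R"),
            t2.get("U1C", "L"),
            t2.get("U1C", "R"),
        ]
    )
    return build_reference_frame(occlusal, t2.get("ANS"), t2.get("PNS"))


@dataclass(frozen=True)
class ToothMeasures:
    """One tooth's landmarks and axis inclination at one timepoint."""

    tooth: str
    side: str
    timepoint: str
    crown_xyz: np.ndarray  # frame coordinates, mm
    root_xyz: np.ndarray
    theta_unsigned: float  # degrees
    theta_signed: float
    root_length: float  # mm, 3D crown-apex distance


def measure_tooth(
    lms_in_t2_frame: LandmarkSet,
    frame: ReferenceFrame,
    plane1: Plane,
    tooth: str,
    side: str,
) -> ToothMeasures:
    """Frame coordinates, sagittal angle and root length of one tooth.

    ``lms_in_t2_frame`` must already live in the T2 scan frame: T2 sets
    natively, T1 sets after implant registration.
    """
    if tooth not in TEETH:
        raise ValueError(f"tooth must be one of {TEETH}, got {tooth!r}")
    crown = lms_in_t2_frame.get(f"{tooth}C", side)
    root = lms_in_t2_frame.get(f"{tooth}R", side)
    theta_u, theta_s = sagittal_axis_angle(crown, root, frame, plane1)
    return ToothMeasures(
        tooth=tooth,
        side=side,
        timepoint=lms_in_t2_frame.timepoint,
        crown_xyz=frame.coords(crown),
        root_xyz=frame.coords(root),
        theta_unsigned=theta_u,
        theta_signed=theta_s,
        root_length=float(np.linalg.norm(crown - root)),
    )


@dataclass(frozen=True)
class MovementRecord:
    """T1 - T2 change variables of one tooth (one side or side-integrated)."""

    tooth: str
    side: str  # "L", "R" or "integrated"
    dx_crown: float
    dx_root: float
    dy_crown: float
    dy_root: float
    m_crown: float
    m_root: float
    dL: float
    dtheta: float  # from unsigned angles (default reporting)
    dtheta_signed: float


def movement(m_t1: ToothMeasures, m_t2: ToothMeasures) -> MovementRecord:
    """Subtract T2 measures from T1 measures for one tooth.

    Both inputs must describe the same tooth and side and be expressed in
    the common T2 frame.
    """
    if (m_t1.tooth, m_t1.side) != (m_t2.tooth, m_t2.side):
        raise ValueError(
            f"tooth/side mismatch: {(m_t1.tooth, m_t1.side)} vs {(m_t2.tooth, m_t2.side)}"
        )
    d_crown = m_t1.crown_xyz - m_t2.crown_xyz
    d_root = m_t1.root_xyz - m_t2.root_xyz
    return MovementRecord(
        tooth=m_t1.tooth,
        side=m_t1.side,
        dx_crown=float(d_crown[0]),
        dx_root=float(d_root[0]),
        dy_crown=float(d_crown[1]),
        dy_root=float(d_root[1]),
        m_crown=float(np.linalg.norm(d_crown)),
        m_root=float(np.linalg.norm(d_root)),
        dL=float(m_t1.root_length - m_t2.root_length),
        dtheta=float(m_t1.theta_unsigned - m_t2.theta_unsigned),
        dtheta_signed=float(m_t1.theta_signed - m_t2.theta_signed),
    )


_NUMERIC_FIELDS = (
    "dx_crown",
    "dx_root",
    "dy_crown",
    "dy_root",
    "m_crown",
    "m_root",
    "dL",
    "dtheta",
    "dtheta_signed",
)


def integrate_sides(
    left: MovementRecord, right: MovementRecord, policy: str = "average"
) -> list[MovementRecord]:
    """Combine the two sides of one tooth into reported records.

    ``"average"`` returns a single record with component-wise means
    (patient as the unit of analysis); ``"per_side"`` passes both records
    through, tagged by side.
    """
    if left.tooth != right.tooth:
        raise ValueError(f"tooth mismatch: {left.tooth} vs {right.tooth}")
    if policy == "per_side":
        return [left, right]
    if policy == "average":
        averaged = {
            f: 0.5 * (getattr(left, f) + getattr(right, f)) for f in _NUMERIC_FIELDS
        }
        return [replace(left, side="integrated", **averaged)]
    raise ValueError(f"unknown integration policy {policy!r}")


def movement_variables(record: MovementRecord) -> dict[str, float]:
    """Flatten a record into table-style named variables.

    E.g. for the canine: ``U3C_X``, ``U3C_Y``, ``U3R_X``, ``U3R_Y``
    (linear changes), ``M3C``, ``M3R`` (displacements), ``L3``
    (root-length change) and ``Tip3`` (angle change).
    """
    t = record.tooth
    digit = t[1:]
    return {
        f"{t}C_X": record.dx_crown,
        f"{t}C_Y": record.dy_crown,
        f"{t}R_X": record.dx_root,
        f"{t}R_Y": record.dy_root,
        f"M{digit}C": record.m_crown,
        f"M{digit}R": record.m_root,
        f"L{digit}": record.dL,
        ANGLE_NAMES[t]: record.dtheta,
    }
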