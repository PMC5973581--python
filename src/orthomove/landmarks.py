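"""Landmark vocabulary and the per-scan landmark container.

One :class:`LandmarkSet` bundles every named 3D point digitised on a
single CBCT scan (one patient at one timepoint), in that scan's native
coordinate frame.  Landmarks are either *sided* (left/right tooth points
and implant endpoints) or *midline* skeletal points (ANS, PNS).

Tooth landmark names follow the usual cephalometric shorthand: ``U6C`` is
the mesiobuccal crown cusp of the maxillary first molar, ``U6R`` its
mesiobuccal root tip; ``U3C``/``U3R`` crown cusp and root tip of the
canine; ``U2C``/``U2R`` and ``U1C``/``U1R`` incisal-edge midpoint and
root tip of the lateral and central incisor.  Implant fiducials are the
head (mucosal end) and tail (bone-deep end) of the posterior and anterior
mini-screw on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import MissingLandmarkError, SchemaError
from .geometry import RigidTransform, as_point

TEETH = ("U6", "U3", "U2", "U1")
TOOTH_LANDMARKS = tuple(f"{t}{part}" for t in TEETH for part in ("C", "R"))
MIDLINE_LANDMARKS = ("ANS", "PNS")
IMPLANT_LANDMARKS = ("IMP_P_HEAD", "IMP_P_TAIL", "IMP_A_HEAD", "IMP_A_TAIL")
SIDED_LANDMARKS = TOOTH_LANDMARKS + IMPLANT_LANDMARKS
SIDES = ("L", "R")
TIMEPOINTS = ("T1", "T2")

#: canonical key for every valid (name, side) combination
VALID_KEYS = frozenset(
    [f"{name}_{side}" for name in SIDED_LANDMARKS for side in SIDES]
    + list(MIDLINE_LANDMARKS)
)


def canonical_key(name: str, side: str | None = None) -> str:
    """Canonical dictionary key for a landmark, validating the vocabulary.

    Midline landmarks take ``side`` in {None, "", "M"}; sided landmarks
    require "L" or "R".
    """
    name = name.strip()
    side = (side or "").strip()
    if name in MIDLINE_LANDMARKS:
        if side not in ("", "M"):
            raise SchemaError(f"midline landmark {name!r} cannot have side {side!r}")
        return name
    if name in SIDED_LANDMARKS:
        if side not in SIDES:
            raise SchemaError(f"landmark {name!r} requires side 'L' or 'R', got {side!r}")
        return f"{name}_{side}"
    raise SchemaError(f"unknown landmark name {name!r}")


def split_key(key: str) -> tuple[str, str]:
    """Inverse of :func:`canonical_key`: returns ``(name, side)``; side "M" for midline."""
    if key in MIDLINE_LANDMARKS:
        return key, "M"
    name, _, side = key.rpartition("_")
    return name, side


@dataclass
class LandmarkSet:
    """All landmarks of one patient at one timepoint, in the scan frame.

    ``points`` maps canonical keys (e.g. ``"U3R_L"``, ``"ANS"``) to
    ``(3,)`` coordinate arrays in millimetres.
    """

    patient_id: str
    timepoint: str
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise SchemaError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        validated = {}
        for key, p in self.points.items():
            if key not in VALID_KEYS:
                raise SchemaError(f"unknown landmark key {key!r}")
            validated[key] = as_point(p)
        self.points = validated

    def __contains__(self, key: str) -> bool:
        return key in self.points

    def __iter__(self) -> Iterator[str]:
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def get(self, name: str, side: str | None = None) -> np.ndarray:
        key = canonical_key(name, side)
        try:
            return self.points[key]
        except KeyError:
            raise MissingLandmarkError(
                f"patient {self.patient_id!r} {self.timepoint}: landmark {key!r} missing"
            ) from None

    def has(self, name: str, side: str | None = None) -> bool:
        try:
            return canonical_key(name, side) in self.points
        except SchemaError:
            return False

    def implant_points(self, side: str) -> np.ndarray:
        """The four same-side implant endpoints as a ``(4, 3)`` array.

        Order is fixed: posterior head, posterior tail, anterior head,
        anterior tail — so corresponding rows of two scans correspond.
        """
        return np.stack([self.get(name, side) for name in IMPLANT_LANDMARKS])

    def transformed(self, transform: RigidTransform, keys=None) -> "LandmarkSet":
        """A copy with ``transform`` applied to ``keys`` (default: all)."""
        keys = set(self.points if keys is None else keys)
        pts = {
            k: (transform.apply(p) if k in keys else p.copy())
            for k, p in self.points.items()
        }
        return LandmarkSet(self.patient_id, self.timepoint, pts)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            self.patient_id, self.timepoint, {k: p.copy() for k, p in self.points.items()}
        )

    def side_keys(self, side: str) -> list[str]:
        """Keys of all sided landmarks on ``side`` that are present."""
        return [k for k in self.points if k.endswith(f"_{side}")]
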