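"""Implant-based superimposition and implant-stability audit.

The T1 scan is registered into the T2 scan frame by a rigid fit of the
four same-side mini-screw implant endpoints (head and tail of the
posterior and anterior implant).  Tooth landmarks never influence the
transform.  Before trusting the implants as fiducials, their mutual
distances within each scan are compared between timepoints: stable
implants keep the same head-to-head and tail-to-tail separation, so the
paired T1-T2 differences should be indistinguishable from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateTestError
from .geometry import RigidTransform, fit_rigid_transform
from .landmarks import SIDES, LandmarkSet
from .stats import paired_t

#: default FRE threshold above which a registration is flagged (mm);
#: roughly twice a typical CBCT voxel size
DEFAULT_FRE_THRESHOLD = 0.5

STABILITY_MEASURES = ("ImplantH", "ImplantT")


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one same-side implant registration."""

    side: str
    transform: RigidTransform
    fre: float
    flagged: bool


def register_side(
    t1: LandmarkSet,
    t2: LandmarkSet,
    side: str,
    fre_threshold: float = DEFAULT_FRE_THRESHOLD,
) -> RegistrationResult:
    """Rigid registration of T1 into the T2 frame on one side's implants.

    Fits the least-squares proper rigid transform mapping the four T1
    implant endpoints onto the corresponding T2 endpoints and reports the
    fiducial registration error.  The result is flagged when the FRE
    exceeds ``fre_threshold``.
    """
    if side not in SIDES:
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    transform, fre = fit_rigid_transform(
        t1.implant_points(side), t2.implant_points(side)
    )
    return RegistrationResult(side, transform, fre, fre > fre_threshold)


def inter_implant_distances(lms: LandmarkSet, side: str) -> tuple[float, float]:
    """Head-to-head and tail-to-tail distances of the two same-side implants.

    Computed in the scan's native frame, hence invariant to scanner pose.
    """
    h = np.linalg.norm(lms.get("IMP_P_HEAD", side) - lms.get("IMP_A_HEAD", side))
    t = np.linalg.norm(lms.get("IMP_P_TAIL", side) - lms.get("IMP_A_TAIL", side))
    return float(h), float(t)


@dataclass(frozen=True)
class StabilityRecord:
    """Inter-implant distances of one patient-side at both timepoints."""

    patient_id: str
    side: str
    implant_h_t1: float
    implant_h_t2: float
    implant_t_t1: float
    implant_t_t2: float
    diff_h: float = field(init=False)
    diff_t: float = field(init=False)

    def __post_init__(self):
        for v in (self.implant_h_t1, self.implant_h_t2, self.implant_t_t1, self.implant_t_t2):
            if not v > 0:
                raise ValueError("inter-implant distances must be positive")
        object.__setattr__(self, "diff_h", self.implant_h_t1 - self.implant_h_t2)
        object.__setattr__(self, "diff_t", self.implant_t_t1 - self.implant_t_t2)


def stability_record(t1: LandmarkSet, t2: LandmarkSet, side: str) -> StabilityRecord:
    h1, d1 = inter_implant_distances(t1, side)
    h2, d2 = inter_implant_distances(t2, side)
    return StabilityRecord(t1.patient_id, side, h1, h2, d1, d2)


def stability_table(records: list[StabilityRecord]) -> pd.DataFrame:
    """Summary of implant stability across a cohort.

    One row per measure (head distance, tail distance) with mean/SD at
    T1, at T2 and of the paired T1-T2 difference, plus the paired t-test
    of the difference against zero.

    Raises
    ------
    DegenerateTestError
        If the paired differences have zero variance (the test is
        undefined).
    """
    if len(records) < 2:
        raise ValueError("stability summary needs at least 2 records")
    cols = {
        "ImplantH": (
            np.array([r.implant_h_t1 for r in records]),
            np.array([r.implant_h_t2 for r in records]),
        ),
        "ImplantT": (
            np.array([r.implant_t_t1 for r in records]),
            np.array([r.implant_t_t2 for r in records]),
        ),
    }
    rows = []
    for measure, (v1, v2) in cols.items():
        diff = v1 - v2
        if diff.std(ddof=1) <= 0:
            raise DegenerateTestError(f"{measure}: zero variance of paired differences")
        res = paired_t(diff)
        rows.append(
            {
                "measure": measure,
                "t1_mean": v1.mean(),
                "t1_sd": v1.std(ddof=1),
                "t2_mean": v2.mean(),
                "t2_sd": v2.std(ddof=1),
                "diff_mean": diff.mean(),
                "diff_sd": diff.std(ddof=1),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "n": len(diff),
                "significant_0.05": res.p < 0.05,
            }
        )
    return pd.DataFrame(rows).set_index("measure")


def stability_changes_from_means(means: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Mean paired change (T1 - T2) per measure from per-timepoint means.

    ``means`` maps a measure name to its ``(T1 mean, T2 mean)``; because
    the paired mean difference equals the difference of the means, this
    reproduces a published change column from the published timepoint
    columns.
    """
    return {name: m1 - m2 for name, (m1, m2) in means.items()}
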