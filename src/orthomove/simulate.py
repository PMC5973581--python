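"""Synthetic two-timepoint landmark cohorts with known ground truth.

A template maxillary arch (bilaterally mirror-symmetric landmark
coordinates in an anatomical frame: x superior, y anterior, z toward the
patient's left, occlusal crown points at x = 0) is deformed by known
per-tooth rigid movements, optionally shortened at the root apex
(resorption), re-expressed in an arbitrary "scanner pose" for the T1
scan, and corrupted with isotropic Gaussian digitisation noise.  Because
every generative parameter is recorded, registration, frame
construction, measurement and statistics can all be validated by
parameter recovery without any real scan data.

Kinematics of one tooth movement, applied to the T1 (template) position
to produce T2:

1. rotate crown and root by the tipping angle phi about the transverse
   (z) axis through a configurable centre (default: the midpoint of the
   crown-root axis); positive phi tips the crown posteriorly,
2. translate by the given vector (anatomical components; the transverse
   component is mirrored on the right side so bilateral movements stay
   mirror-symmetric),
3. move the root apex by the resorption amount toward the crown along
   the post-movement axis.

Implants, ANS and PNS never move: they are the stable structures.  With
zero noise the full pipeline recovers every movement parameter exactly;
the paired T1 - T2 sign convention makes retraction positive in dy,
intrusion negative in dx, resorption positive in dL and crown-posterior
tipping positive in dtheta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .geometry import RigidTransform
from .landmarks import SIDES, TEETH, LandmarkSet, canonical_key
from .metrics import MovementRecord

#: default digitisation noise, mm (approximately one CBCT voxel /
#: landmark-replacement repeatability)
DEFAULT_SIGMA = 0.25


@dataclass(frozen=True)
class Template:
    """Noise-free bilateral landmark coordinates of the synthetic arch."""

    points: dict[str, np.ndarray]

    def landmark_set(self, patient_id: str, timepoint: str) -> LandmarkSet:
        return LandmarkSet(
            patient_id, timepoint, {k: p.copy() for k, p in self.points.items()}
        )

    def get(self, name: str, side: str | None = None) -> np.ndarray:
        return self.points[canonical_key(name, side)]

    def validate(self, mirror_tol: float = 1e-6) -> None:
        """Check mirror symmetry and anatomically plausible root lengths."""
        mirror = np.array([1.0, 1.0, -1.0])
        for key, p in self.points.items():
            if key.endswith("_L"):
                q = self.points[key[:-2] + "_R"]
                if np.max(np.abs(p * mirror - q)) > mirror_tol:
                    raise ConfigError(f"template not mirror-symmetric at {key}")
        for tooth in TEETH:
            for side in SIDES:
                length = np.linalg.norm(
                    self.get(f"{tooth}C", side) - self.get(f"{tooth}R", side)
                )
                if not 8.0 < length < 30.0:
                    raise ConfigError(
                        f"template {tooth} root length {length:.1f} mm implausible"
                    )


def default_template() -> Template:
    """The template arch shipped with the package (editable CSV)."""
    with resources.files("orthomove.data").joinpath("template_landmarks.csv").open() as fh:
        df = pd.read_csv(fh)
    points = {
        canonical_key(row.landmark, None if row.side == "M" else row.side): np.array(
            [row.x, row.y, row.z], dtype=float
        )
        for row in df.itertuples()
    }
    template = Template(points)
    template.validate()
    return template


@dataclass(frozen=True)
class MovementParams:
    """True rigid movement of one tooth between T1 and T2.

    ``translation`` is the applied displacement in anatomical components
    (superior, anterior, transverse-left), mm.  ``tipping_deg`` rotates
    about the transverse axis through ``center`` ("mid_axis", "crown",
    "root", or an explicit point); positive tips the crown posteriorly.
    ``resorption_mm`` shortens the root apex toward the crown.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tipping_deg: float = 0.0
    resorption_mm: float = 0.0
    center: str = "mid_axis"

    def __post_init__(self):
        if self.resorption_mm < 0:
            raise ConfigError("resorption must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "translation": list(map(float, self.translation)),
            "tipping_deg": float(self.tipping_deg),
            "resorption_mm": float(self.resorption_mm),
            "center": self.center if isinstance(self.center, str) else list(self.center),
        }


@dataclass(frozen=True)
class SimulationTruth:
    """Everything the generator applied for one synthetic patient."""

    patient_id: str
    movements: dict[tuple[str, str], MovementParams]  # (tooth, side) -> params
    pose: RigidTransform
    sigma: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "movements": {
                f"{tooth}_{side}": mp.to_dict()
                for (tooth, side), mp in self.movements.items()
            },
            "pose": {
                "rotation": self.pose.rotation.tolist(),
                "translation": self.pose.translation.tolist(),
            },
            "sigma": float(self.sigma),
            "seed": int(self.seed),
        }


def bilateral(movements_by_tooth: dict[str, MovementParams]) -> dict:
    """Expand per-tooth parameters to mirror-symmetric both-side parameters."""
    return {
        (tooth, side): mp
        for tooth, mp in movements_by_tooth.items()
        for side in SIDES
    }


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _resolve_center(mp: MovementParams, crown: np.ndarray, root: np.ndarray) -> np.ndarray:
    if isinstance(mp.center, str):
        if mp.center == "mid_axis":
            return 0.5 * (crown + root)
        if mp.center == "crown":
            return crown
        if mp.center == "root":
            return root
        raise ConfigError(f"unknown rotation center {mp.center!r}")
    return np.asarray(mp.center, dtype=float)


def _moved_tooth(
    template: Template, tooth: str, side: str, mp: MovementParams
) -> tuple[np.ndarray, np.ndarray]:
    """T2 crown and root positions of one tooth, in anatomical coordinates."""
    crown = template.get(f"{tooth}C", side)
    root = template.get(f"{tooth}R", side)
    center = _resolve_center(mp, crown, root)
    rot = _rot_z(mp.tipping_deg)
    translation = np.asarray(mp.translation, dtype=float).copy()
    if side == "R":
        translation[2] = -translation[2]
    crown2 = center + rot @ (crown - center) + translation
    root2 = center + rot @ (root - center) + translation
    length = np.linalg.norm(crown2 - root2)
    if mp.resorption_mm >= length:
        raise ConfigError(
            f"resorption {mp.resorption_mm} mm exceeds {tooth} root length {length:.1f} mm"
        )
    root2 = root2 + mp.resorption_mm * (crown2 - root2) / length
    return crown2, root2


def make_patient(
    template: Template,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
) -> tuple[LandmarkSet, LandmarkSet]:
    """Generate the (T1, T2) landmark sets of one synthetic patient.

    T2 stays in the template's anatomical frame; the complete T1 set is
    mapped by the inverse scanner pose into a distinct native frame (so
    ``truth.pose`` is the transform registration should recover).  Noise
    is added last, independently to every landmark of both scans,
    mimicking two separate digitisation sessions.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    t1 = template.landmark_set(truth.patient_id, "T1")
    t2 = template.landmark_set(truth.patient_id, "T2")
    for (tooth, side), mp in truth.movements.items():
        crown2, root2 = _moved_tooth(template, tooth, side, mp)
        t2.points[canonical_key(f"{tooth}C", side)] = crown2
        t2.points[canonical_key(f"{tooth}R", side)] = root2
    t1 = t1.transformed(truth.pose.inverse())
    if truth.sigma > 0:
        for ls in (t1, t2):
            for key in ls.points:
                ls.points[key] = ls.points[key] + rng.normal(0.0, truth.sigma, 3)
    return t1, t2


def expected_movement(
    template: Template, truth: SimulationTruth, tooth: str, side: str
) -> MovementRecord:
    """Closed-form noise-free movement record implied by the truth.

    Computed directly in the template's anatomical frame, with no
    registration or plane fitting.  It matches the pipeline output
    exactly (sigma = 0) whenever the applied movements leave the
    measurement frame unchanged — i.e. the occlusal crown points U6C/U1C
    either do not move or move within the occlusal plane.  Movements that
    tilt the fitted occlusal plane make the pipeline's frame differ from
    the template frame, and this oracle becomes approximate.
    """
    crown1 = template.get(f"{tooth}C", side)
    root1 = template.get(f"{tooth}R", side)
    mp = truth.movements.get((tooth, side), MovementParams())
    crown2, root2 = _moved_tooth(template, tooth, side, mp)

    def theta_signed(crown: np.ndarray, root: np.ndarray) -> float:
        d = crown - root  # sagittal components: (x superior, y anterior)
        return float(np.degrees(np.arctan2(d[1], -d[0])))

    th1, th2 = theta_signed(crown1, root1), theta_signed(crown2, root2)
    d_crown = crown1 - crown2
    d_root = root1 - root2
    return MovementRecord(
        tooth=tooth,
        side=side,
        dx_crown=float(d_crown[0]),
        dx_root=float(d_root[0]),
        dy_crown=float(d_crown[1]),
        dy_root=float(d_root[1]),
        m_crown=float(np.linalg.norm(d_crown)),
        m_root=float(np.linalg.norm(d_root)),
        dL=float(
            np.linalg.norm(crown1 - root1) - np.linalg.norm(crown2 - root2)
        ),
        dtheta=abs(th1) - abs(th2),
        dtheta_signed=th1 - th2,
    )


def random_pose(rng: np.random.Generator, max_translation: float = 30.0) -> RigidTransform:
    """Uniformly random rotation with a uniform box translation (mm)."""
    rot = Rotation.random(rng=rng).as_matrix()
    return RigidTransform(rot, rng.uniform(-max_translation, max_translation, 3))


Normal = tuple[float, float]  # (mean, sd)


@dataclass(frozen=True)
class ToothTruthDistribution:
    """Per-patient sampling distributions of one tooth's true movement.

    ``retraction`` is posterior translation (mm; enters dy positively),
    ``intrusion`` superior translation (mm; enters dx negatively),
    ``tipping`` crown-posterior rotation (degrees) and ``resorption``
    apex shortening (mm, truncated at zero).
    """

    retraction: Normal = (0.0, 0.0)
    intrusion: Normal = (0.0, 0.0)
    tipping: Normal = (0.0, 0.0)
    resorption: Normal = (0.0, 0.0)
    #: rotation centre for the tipping component.  "root" makes the four
    #: distributions orthogonal (translation moves the apex, tipping only
    #: the crown), so apex-row and angle-row parameters can be recovered
    #: independently; "mid_axis" couples them as a mid-root rotation would.
    center: str = "root"


@dataclass(frozen=True)
class CohortConfig:
    """Generative description of one synthetic study group."""

    label: str
    n_patients: int
    tooth_truths: dict[str, ToothTruthDistribution] = field(default_factory=dict)
    sigma: float = DEFAULT_SIGMA
    seed: int = 0
    randomize_pose: bool = True

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigError("cohort needs at least 2 patients")
        if self.sigma < 0:
            raise ConfigError("noise sigma must be nonnegative")
        for tooth in self.tooth_truths:
            if tooth not in TEETH:
                raise ConfigError(f"unknown tooth {tooth!r} in cohort config")
            for dist in (
                self.tooth_truths[tooth].retraction,
                self.tooth_truths[tooth].intrusion,
                self.tooth_truths[tooth].tipping,
                self.tooth_truths[tooth].resorption,
            ):
                if dist[1] < 0:
                    raise ConfigError("distribution sd must be nonnegative")


@dataclass(frozen=True)
class CohortResult:
    config: CohortConfig
    truths: list[SimulationTruth]
    patients: list[tuple[LandmarkSet, LandmarkSet]]

    def manifest(self) -> dict:
        return {
            "label": self.config.label,
            "n_patients": self.config.n_patients,
            "sigma": self.config.sigma,
            "seed": self.config.seed,
            "patients": [t.to_dict() for t in self.truths],
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def _draw(rng: np.random.Generator, dist: Normal) -> float:
    mean, sd = dist
    return float(mean if sd == 0 else rng.normal(mean, sd))


def simulate_cohort(template: Template, config: CohortConfig) -> CohortResult:
    """Draw a cohort of synthetic patients from a cohort configuration.

    Per-patient substreams are derived from the cohort seed by counter,
    so runs are reproducible and patients mutually independent.  A drawn
    movement is applied bilaterally (both sides share one truth), which
    matches side-integrated analysis.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_patients)
    truths: list[SimulationTruth] = []
    patients: list[tuple[LandmarkSet, LandmarkSet]] = []
    for i, patient_seed in enumerate(seeds):
        patient_seed = int(patient_seed) % 2**31
        rng = np.random.default_rng(patient_seed)
        by_tooth = {}
        for tooth, dist in config.tooth_truths.items():
            by_tooth[tooth] = MovementParams(
                translation=(_draw(rng, dist.intrusion), -_draw(rng, dist.retraction), 0.0),
                tipping_deg=_draw(rng, dist.tipping),
                resorption_mm=max(0.0, _draw(rng, dist.resorption)),
                center=dist.center,
            )
        pose = random_pose(rng) if config.randomize_pose else RigidTransform.identity()
        truth = SimulationTruth(
            patient_id=f"{config.label}-{i + 1:03d}",
            movements=bilateral(by_tooth),
            pose=pose,
            sigma=config.sigma,
            seed=patient_seed,
        )
        truths.append(truth)
        patients.append(make_patient(template, truth, rng))
    return CohortResult(config, truths, patients)


#: per-group movement-parameter distributions used as study-condition
#: presets: root-apex linear changes, angle changes and root-length
#: changes of a first-premolar-extraction en-masse-retraction cohort
#: (G1 adolescents, G2 adults)
GROUP_PRESETS: dict[str, dict[str, ToothTruthDistribution]] = {
    "G1": {
        "U6": ToothTruthDistribution(
            retraction=(-0.33, 1.62), intrusion=(-0.06, 1.14),
            tipping=(-1.82, 6.76), resorption=(0.71, 1.11),
        ),
        "U3": ToothTruthDistribution(
            retraction=(4.34, 1.54), intrusion=(-0.35, 1.62),
            tipping=(-0.33, 4.99), resorption=(0.64, 1.70),
        ),
        "U2": ToothTruthDistribution(
            retraction=(0.31, 1.81), intrusion=(0.13, 1.96),
            tipping=(8.25, 10.15), resorption=(0.96, 1.41),
        ),
        "U1": ToothTruthDistribution(
            retraction=(0.77, 1.59), intrusion=(0.64, 1.76),
            tipping=(9.82, 8.97), resorption=(0.38, 1.19),
        ),
    },
    "G2": {
        "U6": ToothTruthDistribution(
            retraction=(-0.37, 1.39), intrusion=(1.02, 3.08),
            tipping=(4.44, 3.77), resorption=(0.42, 0.69),
        ),
        "U3": ToothTruthDistribution(
            retraction=(1.62, 1.26), intrusion=(0.04, 0.99),
            tipping=(8.00, 5.57), resorption=(1.03, 1.03),
        ),
        "U2": ToothTruthDistribution(
            retraction=(0.99, 1.22), intrusion=(0.17, 1.15),
            tipping=(11.91, 7.01), resorption=(1.04, 1.33),
        ),
        "U1": ToothTruthDistribution(
            retraction=(1.08, 1.20), intrusion=(-0.11, 0.87),
            tipping=(11.47, 6.70), resorption=(1.08, 0.86),
        ),
    },
}

#: default group sizes of the emulated two-group study design
GROUP_SIZES = {"G1": 15, "G2": 19}


def canine_retraction_cohort(
    mean: float = 4.34,
    sd: float = 1.54,
    n: int = 15,
    sigma: float = 0.1,
    seed: int = 0,
    label: str = "G1",
) -> CohortConfig:
    """Cohort in which only the canines move, by pure sagittal translation.

    The per-patient true distal (posterior) displacement of the canine —
    crown and root apex alike — is drawn from N(mean, sd^2).  Because the
    frame-defining landmarks stay put, the pipeline's recovered
    ``dy_root`` estimates the drawn truth directly; defaults reproduce
    the adolescent-group canine root-apex displacement distribution.
    """
    return CohortConfig(
        label=label,
        n_patients=n,
        tooth_truths={"U3": ToothTruthDistribution(retraction=(mean, sd))},
        sigma=sigma,
        seed=seed,
    )


def stable_cohort_config(
    n: int = 15, sigma: float = DEFAULT_SIGMA, seed: int = 0, label: str = "stable"
) -> CohortConfig:
    """Cohort with no tooth movement at all (noise and pose only)."""
    return CohortConfig(label=label, n_patients=n, sigma=sigma, seed=seed)


def group_preset_cohort(
    group: str, sigma: float = DEFAULT_SIGMA, seed: int = 0, n: int | None = None
) -> CohortConfig:
    """Full study-condition cohort for group ``"G1"`` or ``"G2"``."""
    if group not in GROUP_PRESETS:
        raise ConfigError(f"unknown group {group!r}; expected G1 or G2")
    return CohortConfig(
        label=group,
        n_patients=GROUP_SIZES[group] if n is None else n,
        tooth_truths=GROUP_PRESETS[group],
        sigma=sigma,
        seed=seed,
    )
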