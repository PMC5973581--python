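"""End-to-end analysis: registration, frame, measures, tables.

``analyze_patient`` runs the full single-patient workflow:

1. build the anatomical reference frame on the T2 scan,
2. per side, register T1 onto the T2 implants and map the T1 tooth
   landmarks into the T2 frame,
3. measure every tooth at both timepoints and form T1 - T2 movement
   records,
4. integrate the two sides (average by default),
5. audit implant stability from intra-scan inter-implant distances.

``run_pipeline`` wraps this for landmark files on disk and writes the
result tables, echoing its configuration and seed into a run log so
every output row is traceable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import DegenerateTestError, OrthomoveError
from .geometry import Plane, ReferenceFrame
from .landmarks import SIDES, TEETH, LandmarkSet
from .metrics import (
    MovementRecord,
    ToothMeasures,
    build_frame,
    integrate_sides,
    measure_tooth,
    movement,
    movement_variables,
)
from .stats import build_comparison_tables
from .superimpose import (
    DEFAULT_FRE_THRESHOLD,
    RegistrationResult,
    StabilityRecord,
    register_side,
    stability_record,
    stability_table,
)

logger = logging.getLogger("orthomove")


@dataclass
class PatientResult:
    patient_id: str
    frame: ReferenceFrame
    plane1: Plane
    registrations: dict[str, RegistrationResult]
    measures: dict[tuple[str, str, str], ToothMeasures]  # (tooth, side, timepoint)
    records: list[MovementRecord]
    stability: list[StabilityRecord]

    def variables(self) -> dict[str, float]:
        """Flat per-patient variable map (averaged over records per variable)."""
        out: dict[str, list[float]] = {}
        for rec in self.records:
            for name, value in movement_variables(rec).items():
                out.setdefault(name, []).append(value)
        return {name: sum(v) / len(v) for name, v in out.items()}


def analyze_patient(
    t1: LandmarkSet,
    t2: LandmarkSet,
    policy: str = "average",
    fre_threshold: float = DEFAULT_FRE_THRESHOLD,
    teeth=TEETH,
) -> PatientResult:
    """Run the full measurement workflow for one patient."""
    frame, plane1, _ = build_frame(t2)
    registrations: dict[str, RegistrationResult] = {}
    measures: dict[tuple[str, str, str], ToothMeasures] = {}
    records: list[MovementRecord] = []
    per_side: dict[str, dict[str, MovementRecord]] = {s: {} for s in SIDES}
    for side in SIDES:
        reg = register_side(t1, t2, side, fre_threshold)
        registrations[side] = reg
        t1_in_t2 = t1.transformed(reg.transform)
        for tooth in teeth:
            m1 = measure_tooth(t1_in_t2, frame, plane1, tooth, side)
            m2 = measure_tooth(t2, frame, plane1, tooth, side)
            measures[(tooth, side, "T1")] = m1
            measures[(tooth, side, "T2")] = m2
            per_side[side][tooth] = movement(m1, m2)
    for tooth in teeth:
        records.extend(
            integrate_sides(per_side["L"][tooth], per_side["R"][tooth], policy)
        )
    stability = [stability_record(t1, t2, side) for side in SIDES]
    return PatientResult(
        patient_id=t1.patient_id,
        frame=frame,
        plane1=plane1,
        registrations=registrations,
        measures=measures,
        records=records,
        stability=stability,
    )


def analyze_cohort(
    pairs: list[tuple[LandmarkSet, LandmarkSet]],
    policy: str = "average",
    fre_threshold: float = DEFAULT_FRE_THRESHOLD,
) -> list[PatientResult]:
    results = []
    for t1, t2 in pairs:
        try:
            results.append(analyze_patient(t1, t2, policy, fre_threshold))
        except OrthomoveError as exc:
            logger.warning("patient %s skipped: %s", t1.patient_id, exc)
    return results


def cohort_variables(results: list[PatientResult]) -> pd.DataFrame:
    """Per-patient movement-variable table (rows: patients, columns: variables)."""
    rows = {r.patient_id: r.variables() for r in results}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def registration_table(results: list[PatientResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for side, reg in r.registrations.items():
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "side": side,
                    "fre_mm": reg.fre,
                    "flagged": reg.flagged,
                    "rotation_deg": reg.transform.rotation_angle_deg(),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    input_g1: str | None = None
    input_g2: str | None = None
    output_dir: str = "orthomove_out"
    policy: str = "average"
    t_test_method: str = "pooled"
    alphas: tuple[float, float] = (0.05, 0.01)
    fre_threshold: float = DEFAULT_FRE_THRESHOLD
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for a in self.alphas:
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {k: payload.pop(k) for k in list(payload) if k in cls.__dataclass_fields__}
        if "alphas" in known:
            known["alphas"] = tuple(known["alphas"])
        return cls(**known, extra=payload)

    def echo(self) -> dict:
        return {
            "version": __version__,
            "input_g1": self.input_g1,
            "input_g2": self.input_g2,
            "output_dir": self.output_dir,
            "policy": self.policy,
            "t_test_method": self.t_test_method,
            "alphas": list(self.alphas),
            "fre_threshold": self.fre_threshold,
            "seed": self.seed,
        }


def _load_pairs(path) -> list[tuple[LandmarkSet, LandmarkSet]]:
    from .io import pair_timepoints, read_landmarks

    pairs = []
    for pid, scans in pair_timepoints(read_landmarks(path)).items():
        if "T1" not in scans or "T2" not in scans:
            logger.warning("patient %s skipped: missing timepoint", pid)
            continue
        pairs.append((scans["T1"], scans["T2"]))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """File-level pipeline entry point; returns the in-memory results bundle.

    Writes per-group variable tables, registration and stability tables,
    the between/within comparison tables when two groups are given, a
    JSON echo of the configuration, and a run log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("orthomove %s starting; config=%s", __version__, config.echo())
        bundle: dict = {"config": config}
        groups = {}
        for label, path in (("G1", config.input_g1), ("G2", config.input_g2)):
            if path is None:
                continue
            pairs = _load_pairs(path)
            if not pairs:
                raise OrthomoveError(f"no complete patients in {path}")
            results = analyze_cohort(pairs, config.policy, config.fre_threshold)
            variables = cohort_variables(results)
            variables.to_csv(out / f"variables_{label}.csv")
            registration_table(results).to_csv(out / f"registration_{label}.csv", index=False)
            try:
                stab = stability_table([s for r in results for s in r.stability])
                stab.to_csv(out / f"stability_{label}.csv")
            except (DegenerateTestError, ValueError) as exc:
                logger.warning("group %s: stability summary unavailable (%s)", label, exc)
                stab = None
            groups[label] = {
                "results": results,
                "variables": variables,
                "stability": stab,
            }
            logger.info("group %s: %d patients analysed", label, len(results))
        bundle["groups"] = groups
        if len(groups) == 2:
            tables = build_comparison_tables(
                groups["G1"]["variables"],
                groups["G2"]["variables"],
                method=config.t_test_method,
                alphas=config.alphas,
            )
            tables["between"].to_csv(out / "between_groups.csv")
            for label, table in tables["within"].items():
                table.to_csv(out / f"within_{label}.csv")
            bundle["tables"] = tables
        with open(out / "config_echo.json", "w") as fh:
            json.dump(config.echo(), fh, indent=1)
        logger.info("done")
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
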