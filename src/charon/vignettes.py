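"""Canonical per-entity vignettes and seeded cohort simulation.

Each of the 17 covered entities has a *prototype*: a complete tri-state
feature assignment (no unknowns), an onset-age range, and laboratory
sampling rules anchored to the decision constants of the knowledge base
(the AFP cut-offs at 15 and 65 ug/L, the juvenile/adult onset boundary
at 20 years).  The midpoint instantiation of every prototype classifies
to its own entity as strict top-1; this is asserted by the test suite.

The simulator perturbs prototype instantiations with symmetric
present/absent flip noise and missingness, logging every perturbation,
to measure how gracefully the engine degrades under imperfect or
incomplete radiological reads.  Labs and onset receive missingness but
no flips (a sign flip on a concentration has no defined magnitude).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .findings import (
    CoQ10Status,
    FindingsError,
    PatientFindings,
    TriState,
    TRISTATE_FIELDS,
    VitaminEStatus,
    findings_to_dict,
    parse_findings,
)

__all__ = [
    "VignettePrototype",
    "PROTOTYPES",
    "ENTITY_CODES",
    "canonical_vignette",
    "FIGURE_CASES",
    "figure_case",
    "figure_case_text",
    "NoiseModel",
    "Perturbation",
    "CohortRecord",
    "generate_cohort",
    "cohort_to_dataframe",
    "write_cohort_csv",
    "write_cohort_jsonl",
    "load_cohort_jsonl",
]

# anchored to the knowledge-base decision constants
_AFP_LOW = 15.0
_AFP_HIGH = 65.0
_AFP_NORMAL_RANGE = (1.0, 9.0)


@dataclass(frozen=True)
class VignettePrototype:
    """Canonical feature assignment for one entity."""

    entity: str
    tristate: dict[str, TriState]  # complete over TRISTATE_FIELDS
    onset_range: tuple[float, float]
    afp_range: tuple[float, float] = _AFP_NORMAL_RANGE
    vitamin_e: VitaminEStatus = VitaminEStatus.NORMAL
    coq10: CoQ10Status = CoQ10Status.NORMAL
    citations: tuple[str, ...] = ()

    def instantiate(self, onset: float, afp: float,
                    patient_id: str = "") -> PatientFindings:
        return PatientFindings(
            patient_id=patient_id or self.entity,
            onset_age_years=float(onset),
            lab_afp_ug_per_L=float(afp),
            lab_vitamin_e=self.vitamin_e,
            lab_coq10=self.coq10,
            **self.tristate,
        )

    def midpoint(self, patient_id: str = "") -> PatientFindings:
        """Deterministic instantiation at the midpoint of every range."""
        return self.instantiate(
            onset=sum(self.onset_range) / 2.0,
            afp=sum(self.afp_range) / 2.0,
            patient_id=patient_id,
        )


_GLOBAL_ATROPHY = {
    "mri_vermis_superior_atrophy": TriState.PRESENT,
    "mri_vermis_inferior_atrophy": TriState.PRESENT,
    "mri_hemispheric_atrophy": TriState.PRESENT,
}


def _proto(entity: str, onset_range: tuple[float, float],
           present: Sequence[str] = (), *,
           afp_range: tuple[float, float] = _AFP_NORMAL_RANGE,
           vitamin_e: VitaminEStatus = VitaminEStatus.NORMAL,
           coq10: CoQ10Status = CoQ10Status.NORMAL,
           citations: Sequence[str] = ()) -> VignettePrototype:
    tristate = {name: TriState.ABSENT for name in TRISTATE_FIELDS}
    for name in present:
        tristate[name] = TriState.PRESENT
    return VignettePrototype(
        entity=entity, tristate=tristate, onset_range=onset_range,
        afp_range=afp_range, vitamin_e=vitamin_e, coq10=coq10,
        citations=tuple(citations))


PROTOTYPES: dict[str, VignettePrototype] = {p.entity: p for p in (
    _proto("CTX", (20, 50),
           [*_GLOBAL_ATROPHY, "mri_dn_t2_hyperintensity",
            "mri_swi_low_signal_around_dn"],
           citations=("dentate T2 hyperintensity with SWI low-signal rim",)),
    _proto("AOA1", (2, 10),
           [*_GLOBAL_ATROPHY, "mri_dn_t2_hyperintensity",
            "clin_oculomotor_deficits", "clin_peripheral_neuropathy"],
           afp_range=(2, 14),
           citations=("juvenile onset, AFP below the 15 ug/L cut-off",)),
    _proto("AOA2", (10, 19),
           [*_GLOBAL_ATROPHY, "mri_dn_t2_hyperintensity",
            "clin_oculomotor_deficits", "clin_peripheral_neuropathy"],
           afp_range=(20, 60),
           citations=("juvenile onset, AFP between the two cut-offs",)),
    _proto("SPG7", (30, 60),
           [*_GLOBAL_ATROPHY, "mri_dn_t2_hyperintensity",
            "clin_spastic_paraplegia", "clin_optic_atrophy"],
           citations=("adult onset, dentate hyperintensity, spasticity",)),
    _proto("SCAR10", (25, 55),
           [*_GLOBAL_ATROPHY, "mri_dn_t2_hyperintensity",
            "clin_fasciculations"],
           coq10=CoQ10Status.LOW,
           citations=("adult onset, dentate hyperintensity, low CoQ10",)),
    _proto("SCA1", (30, 50),
           [*_GLOBAL_ATROPHY, "mri_hcb_sign", "mri_pons_atrophy",
            "mri_medulla_atrophy", "clin_pyramidal_signs"],
           citations=("Hot Cross Bun with ponto-medullary atrophy, "
                      "pyramidal signs",)),
    _proto("SCA2", (30, 50),
           [*_GLOBAL_ATROPHY, "mri_hcb_sign", "mri_pons_atrophy",
            "mri_medulla_atrophy", "clin_oculomotor_deficits"],
           citations=("Hot Cross Bun with ponto-medullary atrophy, "
                      "oculomotor deficits",)),
    _proto("SCA3", (30, 50),
           [*_GLOBAL_ATROPHY, "mri_hcb_sign", "mri_pons_atrophy",
            "mri_medulla_atrophy", "clin_ankle_reflex_alteration"],
           citations=("Hot Cross Bun with ponto-medullary atrophy, "
                      "ankle-reflex alteration",)),
    _proto("SCA6", (45, 65),
           [*_GLOBAL_ATROPHY, "clin_downbeat_nystagmus"],
           citations=("pure cerebellar atrophy, adult onset, "
                      "downbeat nystagmus",)),
    _proto("SCA7", (20, 45),
           [*_GLOBAL_ATROPHY, "mri_hcb_sign", "mri_pons_atrophy"],
           citations=("Hot Cross Bun with selective pontine atrophy",)),
    _proto("SCA8", (30, 55),
           [*_GLOBAL_ATROPHY, "mri_hcb_sign"],
           citations=("Hot Cross Bun without brainstem involvement",)),
    _proto("SCA17", (25, 55),
           [*_GLOBAL_ATROPHY, "clin_cognitive_psychiatric"],
           citations=("pure cerebellar atrophy, cognitive/psychiatric "
                      "symptoms",)),
    _proto("ARSACS", (2, 20),
           ["mri_vermis_superior_atrophy", "mri_pontine_thickening",
            "mri_lateral_pons_lesions", "mri_parietal_atrophy",
            "clin_peripheral_neuropathy", "clin_spastic_paraplegia"],
           citations=("selective superior vermian atrophy, pontine "
                      "thickening, lateral pontine changes",)),
    _proto("FXTAS", (60, 80),
           [*_GLOBAL_ATROPHY, "mri_mcp_wm_lesions",
            "mri_splenium_wm_lesions"],
           citations=("middle-cerebellar-peduncle and splenium "
                      "white-matter lesions",)),
    _proto("FRDA", (8, 18),
           ["mri_medulla_atrophy", "mri_cervical_cord_atrophy",
            "clin_diabetes_mellitus", "clin_skeletal_abnormalities",
            "clin_ankle_reflex_alteration"],
           citations=("preserved cerebellar volume with mild medulla and "
                      "cervical cord atrophy",)),
    _proto("AT", (2, 10),
           [*_GLOBAL_ATROPHY, "mri_swi_deep_wm_changes",
            "clin_immunodeficiency", "clin_oculomotor_deficits"],
           afp_range=(70, 260),
           citations=("juvenile pure cerebellar atrophy, SWI deep "
                      "white-matter changes, AFP above 65 ug/L",)),
    _proto("AVED", (5, 20),
           ["clin_peripheral_neuropathy"],
           vitamin_e=VitaminEStatus.REDUCED,
           citations=("preserved cerebellar volume with reduced "
                      "vitamin E",)),
)}

ENTITY_CODES: tuple[str, ...] = tuple(sorted(PROTOTYPES))


def canonical_vignette(entity: str) -> PatientFindings:
    """Deterministic, fully-specified findings for one entity
    (midpoint onset and labs)."""
    try:
        proto = PROTOTYPES[entity]
    except KeyError:
        raise KeyError(f"unknown entity code {entity!r}; expected one of "
                       f"{', '.join(ENTITY_CODES)}") from None
    return proto.midpoint()


# ---------------------------------------------------------------------------
# figure cases (partial records: only caption-asserted findings set)
# ---------------------------------------------------------------------------

FIGURE_CASES: tuple[str, ...] = (
    "fig2_sca6", "fig3_arsacs", "fig4_spg7", "fig5_sca2")


def figure_case_text(name: str) -> str:
    if name not in FIGURE_CASES:
        raise KeyError(f"unknown figure case {name!r}; expected one of "
                       f"{', '.join(FIGURE_CASES)}")
    return (resources.files("charon") / "data" / "cases"
            / f"{name}.yaml").read_text()


def figure_case(name: str) -> PatientFindings:
    import yaml
    return parse_findings(yaml.safe_load(figure_case_text(name)))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Perturbation model for simulated radiological reads.

    flip_rate
        Probability that a tri-state finding is flipped present<->absent.
    missing_rate
        Probability that a tri-state finding is masked to unknown
        (applied after flips).
    lab_missing_rate
        Probability that a numeric/categorical scalar (onset age, AFP,
        vitamin E, CoQ10) is masked.
    """

    flip_rate: float = 0.0
    missing_rate: float = 0.0
    lab_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flip_rate", "missing_rate", "lab_missing_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass(frozen=True)
class Perturbation:
    field: str
    kind: str  # "flip" | "mask"
    before: str
    after: str


_SCALAR_FIELDS = ("onset_age_years", "lab_afp_ug_per_L",
                  "lab_vitamin_e", "lab_coq10")
_SCALAR_MASKED = {"onset_age_years": None, "lab_afp_ug_per_L": None,
                  "lab_vitamin_e": VitaminEStatus.UNKNOWN,
                  "lab_coq10": CoQ10Status.UNKNOWN}


def _token(value: Any) -> str:
    if value is None:
        return "unknown"
    if hasattr(value, "value"):
        return value.value
    return str(value)


@dataclass(frozen=True)
class CohortRecord:
    """One simulated referral with its ground truth and perturbation log."""

    findings: PatientFindings
    true_entity: str
    perturbations: tuple[Perturbation, ...]
    clean: PatientFindings


def generate_cohort(n_per_entity: int, noise: NoiseModel | None = None,
                    entities: Iterable[str] | None = None
                    ) -> list[CohortRecord]:
    """Simulate ``n_per_entity`` noisy referrals per entity.

    Reproducible: identical seed and parameters give identical cohorts.
    """
    if n_per_entity < 1:
        raise ValueError("n_per_entity must be >= 1")
    noise = noise or NoiseModel()
    codes = ENTITY_CODES if entities is None else tuple(entities)
    if not codes:
        raise ValueError("entity subset must be non-empty")
    unknown = sorted(set(codes) - set(PROTOTYPES))
    if unknown:
        raise KeyError(f"unknown entity code(s): {', '.join(unknown)}")

    rng = np.random.default_rng(noise.seed)
    records: list[CohortRecord] = []
    for code in codes:
        proto = PROTOTYPES[code]
        for i in range(n_per_entity):
            onset = rng.uniform(*proto.onset_range)
            afp = rng.uniform(*proto.afp_range)
            clean = proto.instantiate(onset=onset, afp=afp,
                                      patient_id=f"{code}-{i:03d}")
            perturbed: dict[str, Any] = {}
            log: list[Perturbation] = []
            for name in TRISTATE_FIELDS:
                value = proto.tristate[name]
                if noise.flip_rate and rng.random() < noise.flip_rate:
                    flipped = (TriState.ABSENT
                               if value is TriState.PRESENT
                               else TriState.PRESENT)
                    log.append(Perturbation(name, "flip",
                                            value.value, flipped.value))
                    value = flipped
                if noise.missing_rate and rng.random() < noise.missing_rate:
                    if value is not TriState.UNKNOWN:
                        log.append(Perturbation(name, "mask",
                                                value.value, "unknown"))
                    value = TriState.UNKNOWN
                if value is not proto.tristate[name]:
                    perturbed[name] = value
            for name in _SCALAR_FIELDS:
                if noise.lab_missing_rate \
                        and rng.random() < noise.lab_missing_rate:
                    before = getattr(clean, name)
                    log.append(Perturbation(name, "mask",
                                            _token(before), "unknown"))
                    perturbed[name] = _SCALAR_MASKED[name]
            findings = replace(clean, **perturbed) if perturbed else clean
            records.append(CohortRecord(
                findings=findings, true_entity=code,
                perturbations=tuple(log), clean=clean))
    return records


def cohort_to_dataframe(records: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = findings_to_dict(rec.findings)
        row["true_entity"] = rec.true_entity
        row["n_perturbations"] = len(rec.perturbations)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: Sequence[CohortRecord],
                     path: str | Path | TextIO) -> None:
    frame = cohort_to_dataframe(records)
    # serialize unknown numerics as empty cells in the batch format
    frame = frame.replace({"unknown": ""})
    frame.to_csv(path, index=False)


def write_cohort_jsonl(records: Sequence[CohortRecord],
                       path: str | Path | TextIO) -> None:
    """JSON-lines variant carrying the full perturbation log."""
    lines = []
    for rec in records:
        lines.append(json.dumps({
            "findings": findings_to_dict(rec.findings),
            "true_entity": rec.true_entity,
            "perturbations": [
                {"field": p.field, "kind": p.kind,
                 "before": p.before, "after": p.after}
                for p in rec.perturbations
            ],
            "clean": findings_to_dict(rec.clean),
        }))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)  # type: ignore[union-attr]
    else:
        Path(path).write_text(text)


def load_cohort_jsonl(source: str | Path | TextIO
                      ) -> tuple[list[CohortRecord], list[tuple[int, str]]]:
    """Read a simulated cohort; returns (records, per-line errors)."""
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text()
    records: list[CohortRecord] = []
    errors: list[tuple[int, str]] = []
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        try:
            doc = json.loads(line)
            findings = parse_findings(doc["findings"])
            clean = parse_findings(doc.get("clean", doc["findings"]))
            records.append(CohortRecord(
                findings=findings,
                true_entity=str(doc["true_entity"]),
                perturbations=tuple(
                    Perturbation(p["field"], p["kind"],
                                 p["before"], p["after"])
                    for p in doc.get("perturbations", ())),
                clean=clean,
            ))
        except (KeyError, ValueError, FindingsError) as exc:
            errors.append((i, str(exc)))
    return records, errors
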