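"""Structured findings vocabulary for hereditary-ataxia phenotyping.

The rule engine never sees images: its only input is a
:class:`PatientFindings` record of radiologist-asserted MRI features,
basic demographics and laboratory values.  Every imaging or clinical
feature is *tri-state* -- asserted present, asserted absent, or not
assessed (unknown) -- because real referrals are incomplete and the
engine must distinguish "looked and absent" from "never looked".

The vocabulary is closed: unknown keys are rejected at parse time so a
record can never silently carry information the engine ignores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dataclass_fields
from enum import Enum
from itertools import product
from pathlib import Path
from typing import Any, Iterable, Mapping, TextIO

import pandas as pd
import yaml

__all__ = [
    "TriState",
    "VitaminEStatus",
    "CoQ10Status",
    "AtrophyPattern",
    "AtrophyPatternWarning",
    "FindingsError",
    "FindingsSchemaError",
    "FindingsValueError",
    "FieldSpec",
    "FIELD_SPECS",
    "TRISTATE_FIELDS",
    "NUMERIC_FIELDS",
    "CATEGORY_FIELDS",
    "ATROPHY_COMPONENT_FIELDS",
    "PatientFindings",
    "parse_findings",
    "findings_to_dict",
    "classify_atrophy_pattern",
    "possible_atrophy_patterns",
    "load_findings",
    "dump_findings",
    "read_findings_csv",
    "write_findings_csv",
    "field_schema",
]


class TriState(str, Enum):
    """Presence state of a single imaging or clinical finding."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class VitaminEStatus(str, Enum):
    REDUCED = "reduced"
    NORMAL = "normal"
    UNKNOWN = "unknown"


class CoQ10Status(str, Enum):
    LOW = "low"
    NORMAL = "normal"
    UNKNOWN = "unknown"


class AtrophyPattern(str, Enum):
    """Top-level cerebellar atrophy classification.

    GLOBAL
        Hemispheric atrophy together with at least one vermian component
        ("pure" cerebellar atrophy).
    SELECTIVE_VERMIAN
        A vermian component atrophic with hemispheres explicitly spared.
    NONE
        All three cerebellar components explicitly spared.
    INDETERMINATE
        The available assertions cannot resolve one of the above, either
        because a component is unknown or because the combination
        (e.g. isolated hemispheric atrophy) has no assigned branch.
    """

    GLOBAL = "global"
    SELECTIVE_VERMIAN = "selective_vermian"
    NONE = "none"
    INDETERMINATE = "indeterminate"


class AtrophyPatternWarning(UserWarning):
    """Raised when a fully-asserted record has no assignable pattern."""


class FindingsError(ValueError):
    """Base class for findings validation problems."""


class FindingsSchemaError(FindingsError):
    """A record used field names outside the closed vocabulary."""


class FindingsValueError(FindingsError):
    """A known field carried a malformed value."""

    def __init__(self, field_name: str, value: Any, reason: str):
        self.field_name = field_name
        self.value = value
        super().__init__(f"{field_name}: {reason} (got {value!r})")


@dataclass(frozen=True)
class FieldSpec:
    """Machine-readable description of one findings field."""

    name: str
    kind: str  # "tristate" | "number" | "category" | "id"
    description: str
    unit: str | None = None
    states: tuple[str, ...] = ()


def _tri(name: str, description: str) -> FieldSpec:
    return FieldSpec(name, "tristate", description,
                     states=tuple(s.value for s in TriState))


_SPEC_LIST: tuple[FieldSpec, ...] = (
    FieldSpec("patient_id", "id", "Opaque patient identifier."),
    FieldSpec("onset_age_years", "number",
              "Age at symptom onset.", unit="years"),
    # -- cerebellar atrophy components -------------------------------------
    _tri("mri_vermis_superior_atrophy", "Atrophy of the superior vermis."),
    _tri("mri_vermis_inferior_atrophy", "Atrophy of the inferior vermis."),
    _tri("mri_hemispheric_atrophy", "Atrophy of the cerebellar hemispheres."),
    # -- other infratentorial / supratentorial morphology ------------------
    _tri("mri_pons_atrophy", "Atrophy of the pons."),
    _tri("mri_medulla_atrophy", "Atrophy of the medulla oblongata."),
    _tri("mri_pontine_thickening", "Thickened appearance of the pons."),
    _tri("mri_cervical_cord_atrophy", "Atrophy of the cervical spinal cord."),
    _tri("mri_parietal_atrophy", "Atrophy of the parietal lobes."),
    # -- T2-weighted signal changes ----------------------------------------
    _tri("mri_dn_t2_hyperintensity",
         "Bilateral T2 hyperintensity of the dentate nuclei."),
    _tri("mri_hcb_sign",
         "Hot Cross Bun sign: cruciform T2 hyperintensity of transverse "
         "pontine fibers and median raphe."),
    _tri("mri_mcp_wm_lesions",
         "T2 white-matter lesions of the middle cerebellar peduncles."),
    _tri("mri_splenium_wm_lesions",
         "T2 white-matter lesions of the splenium of the corpus callosum."),
    _tri("mri_lateral_pons_lesions",
         "T2 signal changes of the lateral portion of the pons."),
    # -- susceptibility-weighted imaging -----------------------------------
    _tri("mri_swi_low_signal_around_dn",
         "SWI low-signal rim surrounding the dentate nuclei."),
    _tri("mri_swi_deep_wm_changes",
         "SWI signal changes in the deep white matter."),
    # -- laboratory ---------------------------------------------------------
    FieldSpec("lab_afp_ug_per_L", "number",
              "Serum alpha-fetoprotein concentration.", unit="ug/L"),
    FieldSpec("lab_vitamin_e", "category", "Serum vitamin E status.",
              states=tuple(s.value for s in VitaminEStatus)),
    FieldSpec("lab_coq10", "category", "Coenzyme Q10 status.",
              states=tuple(s.value for s in CoQ10Status)),
    # -- clinical signs ------------------------------------------------------
    _tri("clin_spastic_paraplegia", "Spastic paraplegia."),
    _tri("clin_downbeat_nystagmus", "Downbeat nystagmus."),
    _tri("clin_cognitive_psychiatric", "Cognitive or psychiatric symptoms."),
    _tri("clin_fasciculations", "Fasciculations."),
    _tri("clin_peripheral_neuropathy", "Peripheral neuropathy."),
    _tri("clin_optic_atrophy", "Optic atrophy."),
    _tri("clin_diabetes_mellitus", "Diabetes mellitus."),
    _tri("clin_skeletal_abnormalities",
         "Skeletal abnormalities (e.g. scoliosis, pes cavus)."),
    _tri("clin_immunodeficiency", "Immunodeficiency."),
    _tri("clin_ankle_reflex_alteration", "Alteration of ankle reflexes."),
    _tri("clin_pyramidal_signs", "Pyramidal signs."),
    _tri("clin_oculomotor_deficits", "Oculomotor deficits."),
)

FIELD_SPECS: dict[str, FieldSpec] = {s.name: s for s in _SPEC_LIST}
TRISTATE_FIELDS: tuple[str, ...] = tuple(
    s.name for s in _SPEC_LIST if s.kind == "tristate")
NUMERIC_FIELDS: tuple[str, ...] = tuple(
    s.name for s in _SPEC_LIST if s.kind == "number")
CATEGORY_FIELDS: tuple[str, ...] = tuple(
    s.name for s in _SPEC_LIST if s.kind == "category")
ATROPHY_COMPONENT_FIELDS: tuple[str, ...] = (
    "mri_vermis_superior_atrophy",
    "mri_vermis_inferior_atrophy",
    "mri_hemispheric_atrophy",
)

_CATEGORY_ENUMS = {"lab_vitamin_e": VitaminEStatus, "lab_coq10": CoQ10Status}


@dataclass(frozen=True)
class PatientFindings:
    """One patient's validated findings record.

    ``defaulted_fields`` is a provenance note: the fields that were not
    supplied by the referrer and therefore defaulted to unknown.  It is
    excluded from equality so that two records carrying the same
    assertions compare equal regardless of how they were entered.
    """

    patient_id: str = ""
    onset_age_years: float | None = None

    mri_vermis_superior_atrophy: TriState = TriState.UNKNOWN
    mri_vermis_inferior_atrophy: TriState = TriState.UNKNOWN
    mri_hemispheric_atrophy: TriState = TriState.UNKNOWN
    mri_pons_atrophy: TriState = TriState.UNKNOWN
    mri_medulla_atrophy: TriState = TriState.UNKNOWN
    mri_pontine_thickening: TriState = TriState.UNKNOWN
    mri_cervical_cord_atrophy: TriState = TriState.UNKNOWN
    mri_parietal_atrophy: TriState = TriState.UNKNOWN
    mri_dn_t2_hyperintensity: TriState = TriState.UNKNOWN
    mri_hcb_sign: TriState = TriState.UNKNOWN
    mri_mcp_wm_lesions: TriState = TriState.UNKNOWN
    mri_splenium_wm_lesions: TriState = TriState.UNKNOWN
    mri_lateral_pons_lesions: TriState = TriState.UNKNOWN
    mri_swi_low_signal_around_dn: TriState = TriState.UNKNOWN
    mri_swi_deep_wm_changes: TriState = TriState.UNKNOWN

    lab_afp_ug_per_L: float | None = None
    lab_vitamin_e: VitaminEStatus = VitaminEStatus.UNKNOWN
    lab_coq10: CoQ10Status = CoQ10Status.UNKNOWN

    clin_spastic_paraplegia: TriState = TriState.UNKNOWN
    clin_downbeat_nystagmus: TriState = TriState.UNKNOWN
    clin_cognitive_psychiatric: TriState = TriState.UNKNOWN
    clin_fasciculations: TriState = TriState.UNKNOWN
    clin_peripheral_neuropathy: TriState = TriState.UNKNOWN
    clin_optic_atrophy: TriState = TriState.UNKNOWN
    clin_diabetes_mellitus: TriState = TriState.UNKNOWN
    clin_skeletal_abnormalities: TriState = TriState.UNKNOWN
    clin_immunodeficiency: TriState = TriState.UNKNOWN
    clin_ankle_reflex_alteration: TriState = TriState.UNKNOWN
    clin_pyramidal_signs: TriState = TriState.UNKNOWN
    clin_oculomotor_deficits: TriState = TriState.UNKNOWN

    defaulted_fields: tuple[str, ...] = field(
        default=(), compare=False, repr=False)


# sanity: the dataclass and the field registry must agree
_DC_NAMES = {f.name for f in dataclass_fields(PatientFindings)} - {
    "defaulted_fields"}
assert _DC_NAMES == set(FIELD_SPECS), "field registry out of sync"


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {None, "", "unknown", "na", "nan", "none", "?"}


def _coerce_tristate(name: str, value: Any) -> TriState:
    if isinstance(value, TriState):
        return value
    if isinstance(value, bool):
        return TriState.PRESENT if value else TriState.ABSENT
    if isinstance(value, str):
        token = value.strip().lower()
        if token in _MISSING_TOKENS:
            return TriState.UNKNOWN
        try:
            return TriState(token)
        except ValueError:
            pass
    elif value is None:
        return TriState.UNKNOWN
    raise FindingsValueError(
        name, value, "expected one of present/absent/unknown")


def _coerce_category(name: str, value: Any) -> Enum:
    enum = _CATEGORY_ENUMS[name]
    if isinstance(value, enum):
        return value
    if isinstance(value, str):
        token = value.strip().lower()
        if token in _MISSING_TOKENS:
            return enum("unknown")
        try:
            return enum(token)
        except ValueError:
            pass
    elif value is None:
        return enum("unknown")
    allowed = "/".join(s.value for s in enum)
    raise FindingsValueError(name, value, f"expected one of {allowed}")


def _coerce_number(name: str, value: Any) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        token = value.strip().lower()
        if token in _MISSING_TOKENS:
            return None
        try:
            value = float(token)
        except ValueError:
            raise FindingsValueError(name, value, "expected a number") from None
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise FindingsValueError(name, value, "expected a number")
    value = float(value)
    if not math.isfinite(value):
        raise FindingsValueError(name, value, "must be finite")
    if value < 0:
        raise FindingsValueError(name, value, "must be non-negative")
    return value


def parse_findings(record: Mapping[str, Any]) -> PatientFindings:
    """Validate a key-value mapping into a :class:`PatientFindings`.

    Unknown keys are rejected; absent keys default to unknown and are
    recorded in the ``defaulted_fields`` provenance note.
    """
    if not isinstance(record, Mapping):
        raise FindingsSchemaError(
            f"findings record must be a mapping, got {type(record).__name__}")
    extra = sorted(set(record) - set(FIELD_SPECS))
    if extra:
        raise FindingsSchemaError(
            f"unknown findings field(s): {', '.join(extra)}")
    kwargs: dict[str, Any] = {}
    defaulted: list[str] = []
    for spec in _SPEC_LIST:
        if spec.name == "patient_id":
            raw = record.get("patient_id", "")
            kwargs["patient_id"] = "" if raw is None else str(raw)
            continue
        if spec.name not in record:
            defaulted.append(spec.name)
            continue
        value = record[spec.name]
        if spec.kind == "tristate":
            kwargs[spec.name] = _coerce_tristate(spec.name, value)
        elif spec.kind == "number":
            kwargs[spec.name] = _coerce_number(spec.name, value)
        else:
            kwargs[spec.name] = _coerce_category(spec.name, value)
    kwargs["defaulted_fields"] = tuple(defaulted)
    return PatientFindings(**kwargs)


def findings_to_dict(f: PatientFindings) -> dict[str, Any]:
    """Serialize to plain types; states lowercase, unknown numerics "unknown"."""
    out: dict[str, Any] = {}
    for spec in _SPEC_LIST:
        value = getattr(f, spec.name)
        if spec.kind == "id":
            out[spec.name] = value
        elif spec.kind == "number":
            out[spec.name] = "unknown" if value is None else float(value)
        else:
            out[spec.name] = value.value
    return out


def load_findings(source: str | Path | TextIO) -> PatientFindings:
    """Read a single-patient findings record from a JSON or YAML document."""
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text()
    data = yaml.safe_load(text)
    if data is None:
        raise FindingsSchemaError("empty findings document")
    return parse_findings(data)


def dump_findings(f: PatientFindings, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(findings_to_dict(f), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass(frozen=True)
class ParsedRow:
    """One row of a batch table: either a record or a validation error."""

    row: int
    findings: PatientFindings | None = None
    error: str | None = None


def read_findings_csv(source: str | Path | TextIO) -> list[ParsedRow]:
    """Parse a batch CSV (one column per field; empty cell = unknown)."""
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    extra = sorted(set(frame.columns) - set(FIELD_SPECS))
    if extra:
        raise FindingsSchemaError(
            f"unknown findings column(s): {', '.join(extra)}")
    rows: list[ParsedRow] = []
    for i, raw in enumerate(frame.to_dict(orient="records")):
        record = {k: v for k, v in raw.items() if v.strip() != ""}
        try:
            rows.append(ParsedRow(row=i, findings=parse_findings(record)))
        except FindingsError as exc:
            rows.append(ParsedRow(row=i, error=str(exc)))
    return rows


def write_findings_csv(records: Iterable[PatientFindings],
                       path: str | Path | TextIO) -> None:
    frame = pd.DataFrame([findings_to_dict(f) for f in records],
                         columns=[s.name for s in _SPEC_LIST])
    frame.to_csv(path, index=False)


def field_schema() -> dict[str, Any]:
    """Machine-readable schema of every field, its states and units."""
    return {
        spec.name: {
            "kind": spec.kind,
            "description": spec.description,
            **({"unit": spec.unit} if spec.unit else {}),
            **({"states": list(spec.states)} if spec.states else {}),
        }
        for spec in _SPEC_LIST
    }


# ---------------------------------------------------------------------------
# atrophy-pattern classification
# ---------------------------------------------------------------------------

def classify_atrophy_pattern(f: PatientFindings, *,
                             _warn: bool = True) -> AtrophyPattern:
    """Derive the top-level cerebellar atrophy pattern.

    Total over all 3^3 tri-state combinations of the three components;
    unresolvable combinations map to INDETERMINATE.  Isolated
    hemispheric atrophy has no assigned branch and also maps to
    INDETERMINATE, with a warning when fully asserted.
    """
    sup = f.mri_vermis_superior_atrophy
    inf = f.mri_vermis_inferior_atrophy
    hemi = f.mri_hemispheric_atrophy
    vermian_present = TriState.PRESENT in (sup, inf)
    if hemi is TriState.PRESENT and vermian_present:
        return AtrophyPattern.GLOBAL
    if hemi is TriState.ABSENT and vermian_present:
        return AtrophyPattern.SELECTIVE_VERMIAN
    if sup is TriState.ABSENT and inf is TriState.ABSENT:
        if hemi is TriState.ABSENT:
            return AtrophyPattern.NONE
        if hemi is TriState.PRESENT:
            if _warn:
                warnings.warn(
                    "isolated hemispheric atrophy has no assigned branch; "
                    "pattern is indeterminate and both groups are explored",
                    AtrophyPatternWarning, stacklevel=2)
            return AtrophyPattern.INDETERMINATE
    return AtrophyPattern.INDETERMINATE


def possible_atrophy_patterns(f: PatientFindings) -> frozenset[AtrophyPattern]:
    """Patterns compatible with the record over all resolutions of unknowns.

    Each unknown atrophy component is resolved both ways; the returned
    set is the image of :func:`classify_atrophy_pattern` over those
    resolutions.  Used by the engine to keep branch decisions consistent
    with at least one concrete resolution of the record.
    """
    unknowns = [name for name in ATROPHY_COMPONENT_FIELDS
                if getattr(f, name) is TriState.UNKNOWN]
    if not unknowns:
        return frozenset({classify_atrophy_pattern(f, _warn=False)})
    patterns = set()
    from dataclasses import replace
    for combo in product((TriState.PRESENT, TriState.ABSENT),
                         repeat=len(unknowns)):
        resolved = replace(f, **dict(zip(unknowns, combo)))
        patterns.add(classify_atrophy_pattern(resolved, _warn=False))
    return frozenset(patterns)
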