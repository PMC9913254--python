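"""Data model and table I/O for multi-lesion radiomic cohorts.

A cohort is described by two CSV tables:

* a *lesion table* with one row per lesion (patient id, lesion id, anatomical
  site, 37 radiomic texture features in six semantic groups, plus the
  conventional SUV-derived quantities SUV_max, TLA and GLCM entropy), as
  exported by LIFEx-style radiomics software;
* a *clinical table* with one row per patient (Gleason score, PSA, therapy
  fields, response, follow-up time and event flag).

The grouping of radiomic features into the six semantic views (HISTOGRAM,
SHAPE, GLCM, GLRLM, NGLDM, GLZLM) is configuration-driven: the default map
follows the LIFEx naming convention but can be replaced by a YAML/JSON file,
since feature naming varies across software versions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lesionforest")

#: Anatomical sites admitted for a lesion.
SITES = ("regional_lymph_node", "distant_lymph_node", "bone")

#: Canonical order of the six semantic radiomic views.
DEFAULT_VIEWS = ("HISTOGRAM", "SHAPE", "GLCM", "GLRLM", "NGLDM", "GLZLM")

# Best-effort LIFEx-era feature list (37 features over six views). The exact
# export list varies between software versions, hence the map is overridable.
_DEFAULT_ASSIGNMENT: dict[str, str] = {
    # HISTOGRAM (4)
    "HISTO_Skewness": "HISTOGRAM",
    "HISTO_Kurtosis": "HISTOGRAM",
    "HISTO_Entropy_log10": "HISTOGRAM",
    "HISTO_Energy": "HISTOGRAM",
    # SHAPE (3)
    "SHAPE_Sphericity": "SHAPE",
    "SHAPE_Compacity": "SHAPE",
    "SHAPE_Volume_mL": "SHAPE",
    # GLCM (5)
    "GLCM_Homogeneity": "GLCM",
    "GLCM_Energy": "GLCM",
    "GLCM_Contrast": "GLCM",
    "GLCM_Correlation": "GLCM",
    "GLCM_Entropy_log10": "GLCM",
    # GLRLM (11)
    "GLRLM_SRE": "GLRLM",
    "GLRLM_LRE": "GLRLM",
    "GLRLM_LGRE": "GLRLM",
    "GLRLM_HGRE": "GLRLM",
    "GLRLM_SRLGE": "GLRLM",
    "GLRLM_SRHGE": "GLRLM",
    "GLRLM_LRLGE": "GLRLM",
    "GLRLM_LRHGE": "GLRLM",
    "GLRLM_GLNU": "GLRLM",
    "GLRLM_RLNU": "GLRLM",
    "GLRLM_RP": "GLRLM",
    # NGLDM (3)
    "NGLDM_Coarseness": "NGLDM",
    "NGLDM_Contrast": "NGLDM",
    "NGLDM_Busyness": "NGLDM",
    # GLZLM (11)
    "GLZLM_SZE": "GLZLM",
    "GLZLM_LZE": "GLZLM",
    "GLZLM_LGZE": "GLZLM",
    "GLZLM_HGZE": "GLZLM",
    "GLZLM_SZLGE": "GLZLM",
    "GLZLM_SZHGE": "GLZLM",
    "GLZLM_LZLGE": "GLZLM",
    "GLZLM_LZHGE": "GLZLM",
    "GLZLM_GLNU": "GLZLM",
    "GLZLM_ZLNU": "GLZLM",
    "GLZLM_ZP": "GLZLM",
}

#: Conventional SUV-derived quantities, excluded from the depth computation
#: and kept aside for interpretation of the fitted phenotypes.
DEFAULT_CONVENTIONAL = ("SUV_max", "SUV_mean", "SUV_peak", "TLA", "GLCM_Entropy")


@dataclass(frozen=True)
class FeatureGroupMap:
    """Assignment of radiomic feature names to semantic views.

    Parameters
    ----------
    view_names
        Ordered view labels; the order fixes the order of depth profiles.
    assignment
        Mapping feature name -> view label. Every feature belongs to exactly
        one view and every view must be non-empty.
    conventional_names
        Feature names excluded from depth computation (SUV-related).
    """

    view_names: tuple[str, ...] = DEFAULT_VIEWS
    assignment: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_ASSIGNMENT)
    )
    conventional_names: tuple[str, ...] = DEFAULT_CONVENTIONAL

    def __post_init__(self) -> None:
        views = set(self.view_names)
        if len(views) != len(self.view_names):
            raise ValueError("duplicate view names")
        for feat, view in self.assignment.items():
            if view not in views:
                raise ValueError(f"feature {feat!r} assigned to unknown view {view!r}")
        for view in self.view_names:
            if not any(v == view for v in self.assignment.values()):
                raise ValueError(f"view {view!r} has no features")
        overlap = set(self.assignment) & set(self.conventional_names)
        if overlap:
            raise ValueError(
                f"conventional features cannot also map to a view: {sorted(overlap)}"
            )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def features_in_view(self, view: str) -> tuple[str, ...]:
        if view not in self.view_names:
            raise KeyError(view)
        return tuple(f for f, v in self.assignment.items() if v == view)

    @property
    def n_features(self) -> int:
        return len(self.assignment)

    @classmethod
    def default(cls) -> "FeatureGroupMap":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureGroupMap":
        """Load a group map from YAML or JSON.

        Expected keys: ``views`` (ordered list), ``assignment``
        (feature -> view), optional ``conventional`` (list).
        """
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(
            view_names=tuple(data["views"]),
            assignment=dict(data["assignment"]),
            conventional_names=tuple(data.get("conventional", DEFAULT_CONVENTIONAL)),
        )

    def to_file(self, path: str | Path) -> None:
        data = {
            "views": list(self.view_names),
            "assignment": dict(self.assignment),
            "conventional": list(self.conventional_names),
        }
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


@dataclass
class LesionRecord:
    """One lesion: identifiers, site, radiomic features and SUV quantities."""

    patient_id: str
    lesion_id: str
    site: str
    features: dict[str, float]
    suv_max: float
    tla: float
    glcm_entropy: float

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(
                f"unknown site {self.site!r} for lesion "
                f"{self.patient_id}/{self.lesion_id}; expected one of {SITES}"
            )
        for name, value in self.features.items():
            if not math.isfinite(value):
                raise ValueError(
                    f"non-finite value for feature {name!r} in lesion "
                    f"{self.patient_id}/{self.lesion_id}"
                )
        if self.tla < 0:
            raise ValueError(f"negative TLA in lesion {self.patient_id}/{self.lesion_id}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.lesion_id)


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and time-to-event outcome.

    ``gleason_score``, ``psa``, ``response`` and ``initial_therapy`` admit
    missing values (None / NaN); everything else is required.
    """

    patient_id: str
    age: float
    followup_time: float
    event: bool
    gleason_score: float | None = None
    psa: float | None = None
    initial_therapy: str | None = None
    ongoing_adt: bool = False
    combined_therapy: bool = False
    radiotherapy: bool = False
    hormonotherapy: bool = False
    response: bool | None = None

    def __post_init__(self) -> None:
        if self.followup_time < 0:
            raise ValueError(
                f"negative follow-up time for patient {self.patient_id}"
            )

    @property
    def gleason_category(self) -> str | None:
        """Dichotomised Gleason score: '<=7' vs '>7' (None when missing)."""
        if self.gleason_score is None or (
            isinstance(self.gleason_score, float) and math.isnan(self.gleason_score)
        ):
            return None
        return ">7" if self.gleason_score > 7 else "<=7"


@dataclass
class CohortDataset:
    """A validated cohort: lesions, clinical rows and the feature group map."""

    lesions: list[LesionRecord]
    clinical: list[ClinicalRecord]
    group_map: FeatureGroupMap

    @property
    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.clinical]

    def lesions_of(self, patient_id: str) -> list[LesionRecord]:
        return [l for l in self.lesions if l.patient_id == patient_id]

    def lesion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lesion in self.lesions:
            counts[lesion.patient_id] = counts.get(lesion.patient_id, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ID_COLUMNS = ("patient_id", "lesion_id", "site")


def _resolve_columns(columns: Iterable[str], wanted: Iterable[str]) -> dict[str, str]:
    """Case-insensitive resolution of wanted column names against a header."""
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for name in wanted:
        actual = lower.get(name.lower())
        if actual is None:
            raise ValueError(f"missing required column {name!r}")
        resolved[name] = actual
    return resolved


def read_lesion_table(
    path: str | Path, group_map: FeatureGroupMap | None = None
) -> list[LesionRecord]:
    """Read a lesion-level radiomic CSV into :class:`LesionRecord` objects.

    Feature columns are matched case-insensitively against the group map; a
    missing mapped column, a non-numeric feature cell or an unknown site label
    is a hard error. Row order is preserved.
    """
    group_map = group_map or FeatureGroupMap.default()
    df = pd.read_csv(path, dtype={"patient_id": str, "lesion_id": str})
    wanted = list(_ID_COLUMNS) + list(group_map.feature_names) + [
        "SUV_max",
        "TLA",
        "GLCM_Entropy",
    ]
    cols = _resolve_columns(df.columns, wanted)

    records: list[LesionRecord] = []
    for idx, row in df.iterrows():
        features = {}
        for name in group_map.feature_names:
            raw = row[cols[name]]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {raw!r} for feature {name!r} in row {idx}"
                ) from None
            if not math.isfinite(value):
                raise ValueError(f"missing/non-finite feature {name!r} in row {idx}")
            features[name] = value
        records.append(
            LesionRecord(
                patient_id=str(row[cols["patient_id"]]),
                lesion_id=str(row[cols["lesion_id"]]),
                site=str(row[cols["site"]]),
                features=features,
                suv_max=float(row[cols["SUV_max"]]),
                tla=float(row[cols["TLA"]]),
                glcm_entropy=float(row[cols["GLCM_Entropy"]]),
            )
        )
    return records


def write_lesion_table(
    lesions: Sequence[LesionRecord],
    path: str | Path,
    group_map: FeatureGroupMap | None = None,
) -> None:
    group_map = group_map or FeatureGroupMap.default()
    rows = []
    for lesion in lesions:
        row: dict[str, object] = {
            "patient_id": lesion.patient_id,
            "lesion_id": lesion.lesion_id,
            "site": lesion.site,
        }
        row.update({name: lesion.features[name] for name in group_map.feature_names})
        row["SUV_max"] = lesion.suv_max
        row["TLA"] = lesion.tla
        row["GLCM_Entropy"] = lesion.glcm_entropy
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_CLINICAL_REQUIRED = ("patient_id", "age", "followup_time", "event")
_CLINICAL_BOOL = (
    "ongoing_adt",
    "combined_therapy",
    "radiotherapy",
    "hormonotherapy",
)


def _as_optional_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)  # type: ignore[arg-type]


def _as_bool(value: object) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def _as_optional_bool(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return _as_bool(value)


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the patient-level clinical CSV.

    Missing values are admitted (and preserved as ``None``) for
    ``gleason_score``, ``psa``, ``response`` and ``initial_therapy``.
    Duplicate patient ids and negative follow-up times are hard errors.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    cols = _resolve_columns(df.columns, _CLINICAL_REQUIRED)
    dupes = df[cols["patient_id"]][df[cols["patient_id"]].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate patient_id values: {sorted(set(dupes))}")

    lower = {c.lower(): c for c in df.columns}
    records = []
    for _, row in df.iterrows():
        therapy = row.get(lower.get("initial_therapy", ""), None)
        if isinstance(therapy, float) and math.isnan(therapy):
            therapy = None
        if isinstance(therapy, str) and not therapy.strip():
            therapy = None
        records.append(
            ClinicalRecord(
                patient_id=str(row[cols["patient_id"]]),
                age=float(row[cols["age"]]),
                followup_time=float(row[cols["followup_time"]]),
                event=_as_bool(row[cols["event"]]),
                gleason_score=_as_optional_float(row.get(lower.get("gleason_score", ""))),
                psa=_as_optional_float(row.get(lower.get("psa", ""))),
                initial_therapy=therapy,
                ongoing_adt=_as_bool(row.get(lower.get("ongoing_adt", ""), False)),
                combined_therapy=_as_bool(
                    row.get(lower.get("combined_therapy", ""), False)
                ),
                radiotherapy=_as_bool(row.get(lower.get("radiotherapy", ""), False)),
                hormonotherapy=_as_bool(
                    row.get(lower.get("hormonotherapy", ""), False)
                ),
                response=_as_optional_bool(row.get(lower.get("response", ""))),
            )
        )
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age,
                "gleason_score": rec.gleason_score,
                "psa": rec.psa,
                "initial_therapy": rec.initial_therapy,
                "ongoing_adt": rec.ongoing_adt,
                "combined_therapy": rec.combined_therapy,
                "radiotherapy": rec.radiotherapy,
                "hormonotherapy": rec.hormonotherapy,
                "response": rec.response,
                "followup_time": rec.followup_time,
                "event": rec.event,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_cohort(
    lesions: Sequence[LesionRecord],
    clinical: Sequence[ClinicalRecord],
    group_map: FeatureGroupMap | None = None,
    permissive: bool = False,
) -> CohortDataset:
    """Cross-validate lesion and clinical tables into a :class:`CohortDataset`.

    The study inclusion criterion requires at least two lesions per patient:
    in strict mode (default) a patient with fewer lesions raises an error
    naming the patient; with ``permissive=True`` such patients are excluded
    and a warning is logged. A lesion referencing an unknown patient is always
    a hard error, as are duplicate lesion ids within a patient.
    """
    group_map = group_map or FeatureGroupMap.default()
    known = {c.patient_id for c in clinical}
    for lesion in lesions:
        if lesion.patient_id not in known:
            raise ValueError(
                f"lesion {lesion.lesion_id!r} references unknown patient "
                f"{lesion.patient_id!r}"
            )
    seen: set[tuple[str, str]] = set()
    for lesion in lesions:
        if lesion.key in seen:
            raise ValueError(
                f"duplicate lesion id {lesion.lesion_id!r} for patient "
                f"{lesion.patient_id!r}"
            )
        seen.add(lesion.key)

    counts: dict[str, int] = {c.patient_id: 0 for c in clinical}
    for lesion in lesions:
        counts[lesion.patient_id] += 1
    too_few = sorted(pid for pid, n in counts.items() if n < 2)
    if too_few:
        if not permissive:
            raise ValueError(
                "patients with fewer than two lesions (inclusion criterion "
                f"requires >= 2): {too_few}"
            )
        logger.warning(
            "excluding %d patient(s) with fewer than two lesions: %s",
            len(too_few),
            too_few,
        )
        excluded = set(too_few)
        lesions = [l for l in lesions if l.patient_id not in excluded]
        clinical = [c for c in clinical if c.patient_id not in excluded]
    return CohortDataset(list(lesions), list(clinical), group_map)


def cohort_summary(dataset: CohortDataset) -> dict:
    """JSON-serialisable cohort summary: sizes and per-patient lesion counts."""
    counts = dataset.lesion_counts()
    return {
        "n_patients": len(dataset.clinical),
        "n_lesions": len(dataset.lesions),
        "median_lesions_per_patient": float(np.median(list(counts.values()))),
        "lesions_per_patient": counts,
        "views": list(dataset.group_map.view_names),
        "n_features": dataset.group_map.n_features,
    }
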