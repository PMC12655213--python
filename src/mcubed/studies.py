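"""Study descriptors: the machine-readable form of a published popPK analysis.

A published population-pharmacokinetic study is reduced to a
:class:`StudyDescriptor`: covariate summary statistics (the numbers a paper
prints in its demographics table), the structural PK model with its
clearance–creatinine-clearance relationship, the variance components, and
the dosing/sampling design.  Descriptors are stored as YAML (JSON is read
interchangeably) under a small versioned schema, validated on load, and
screened for biological plausibility of the clearance model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

SCHEMA_VERSION = 1

COVARIATE_NAMES = {"AGE", "BW", "CLCR", "SEX"}
REPORTING_FORMS = {"mean_sd", "median_range", "median_iqr", "mean_sd_range"}
DISTRIBUTION_HINTS = {"normal", "lognormal", "uniform"}
CL_FORMULA_KINDS = {"linear", "power"}
RESIDUAL_KINDS = {"proportional", "additive", "combined"}
WINDOW_TAGS = {"peak", "random", "trough"}

#: reference creatinine clearance (mL/min) for the plausibility screen
CLCR_REFERENCE = 50.0
#: plausibility bounds on typical CL at the reference CLcr (L/h); a renally
#: cleared drug with CLcr = 50 mL/min should clear roughly 3 L/h, and models
#: more than twofold off in either direction are rejected
CL_PLAUSIBLE_LOW = 1.5
CL_PLAUSIBLE_HIGH = 6.0


class StudyValidationError(ValueError):
    """Raised when a descriptor violates the schema; names study and field."""

    def __init__(self, study_id: str, fieldname: str, message: str):
        self.study_id = study_id
        self.fieldname = fieldname
        super().__init__(f"study {study_id!r}, field {fieldname!r}: {message}")


class ImplausibleModelError(ValueError):
    pass


@dataclass
class CovariateSummary:
    """Summary statistics for one covariate as printed in a source paper."""

    name: str
    reporting_form: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    range_is_iqr: bool = False
    units_normalized_to_bsa: bool = False
    distribution_hint: Optional[str] = None

    def validate(self, study_id: str = "?") -> None:
        if self.name not in COVARIATE_NAMES:
            raise StudyValidationError(study_id, "name",
                                       f"unknown covariate {self.name!r}")
        if self.reporting_form not in REPORTING_FORMS:
            raise StudyValidationError(study_id, "reporting_form",
                                       f"unknown form {self.reporting_form!r}")
        if self.distribution_hint is not None and \
                self.distribution_hint not in DISTRIBUTION_HINTS:
            raise StudyValidationError(study_id, "distribution_hint",
                                       f"unknown hint {self.distribution_hint!r}")
        form = self.reporting_form
        if form in ("mean_sd", "mean_sd_range"):
            if self.mean is None or self.sd is None:
                raise StudyValidationError(study_id, self.name,
                                           f"form {form} requires mean and sd")
            if self.sd < 0:
                raise StudyValidationError(study_id, self.name, "sd < 0")
        if form in ("median_range", "median_iqr"):
            if self.median is None or self.lo is None or self.hi is None:
                raise StudyValidationError(
                    study_id, self.name, f"form {form} requires median, lo, hi")
        center = self.median if self.median is not None else self.mean
        if center is not None:
            if self.lo is not None and self.lo > center + 1e-12:
                raise StudyValidationError(study_id, self.name,
                                           f"lo {self.lo} > center {center}")
            if self.hi is not None and self.hi < center - 1e-12:
                raise StudyValidationError(study_id, self.name,
                                           f"hi {self.hi} < center {center}")


@dataclass
class ResidualSpec:
    kind: str = "proportional"
    sigma2: float = 0.0          # proportional variance (unitless)
    sigma2_add: float = 0.0      # additive variance (mg/L)^2, combined only

    def validate(self, study_id: str = "?") -> None:
        if self.kind not in RESIDUAL_KINDS:
            raise StudyValidationError(study_id, "residual.kind",
                                       f"unknown kind {self.kind!r}")
        if self.sigma2 < 0 or self.sigma2_add < 0:
            raise StudyValidationError(study_id, "residual", "variance < 0")


@dataclass
class SourceModel:
    """Structural popPK model of a source study (CLcr the sole CL covariate)."""

    n_compartments: int
    cl_formula_kind: str            # 'linear': CL = a + b*CLcr ; 'power': a*CLcr**b
    cl_coefficients: tuple
    volume_params: dict             # V1 and, per compartment count, Q2/V2, Q3/V3 (L, L/h)
    bsv: dict = field(default_factory=dict)      # parameter -> omega^2 (exp scale)
    residual: ResidualSpec = field(default_factory=ResidualSpec)
    unverified: bool = False        # transcription placeholder flag

    REQUIRED_VOLUMES = {1: ("V1",), 2: ("V1", "Q2", "V2"),
                        3: ("V1", "Q2", "V2", "Q3", "V3")}

    def validate(self, study_id: str = "?") -> None:
        if self.n_compartments not in (1, 2, 3):
            raise StudyValidationError(study_id, "n_compartments",
                                       f"must be 1-3, got {self.n_compartments}")
        if self.cl_formula_kind not in CL_FORMULA_KINDS:
            raise StudyValidationError(study_id, "cl_formula_kind",
                                       f"unknown kind {self.cl_formula_kind!r}")
        if len(self.cl_coefficients) != 2:
            raise StudyValidationError(study_id, "cl_coefficients",
                                       "expect exactly two coefficients")
        for key in self.REQUIRED_VOLUMES[self.n_compartments]:
            val = self.volume_params.get(key)
            if val is None or val <= 0:
                raise StudyValidationError(study_id, f"volume_params.{key}",
                                           f"must be > 0, got {val}")
        for p, w2 in self.bsv.items():
            if w2 < 0:
                raise StudyValidationError(study_id, f"bsv.{p}", "omega^2 < 0")
        self.residual.validate(study_id)
        # any positive CLcr must yield positive CL
        if self.cl_formula_kind == "power":
            if self.cl_coefficients[0] <= 0:
                raise StudyValidationError(study_id, "cl_coefficients",
                                           "power coefficient must be > 0")
        else:
            a, b = self.cl_coefficients
            if a < 0 or (a == 0 and b <= 0):
                raise StudyValidationError(
                    study_id, "cl_coefficients",
                    "linear CL must be positive for CLcr > 0")

    def typical_cl(self, clcr: float) -> float:
        """Typical clearance (L/h) at creatinine clearance ``clcr`` (mL/min)."""
        a, b = self.cl_coefficients
        if self.cl_formula_kind == "power":
            return a * clcr ** b
        return a + b * clcr


@dataclass
class SamplingWindow:
    tag: str
    start: Optional[float] = None   # h after the dose event start
    end: Optional[float] = None

    def validate(self, study_id: str = "?") -> None:
        if self.tag not in WINDOW_TAGS:
            raise StudyValidationError(study_id, "sampling.tag",
                                       f"unknown tag {self.tag!r}")
        if self.start is not None and self.end is not None \
                and not self.start < self.end:
            raise StudyValidationError(study_id, "sampling",
                                       f"window start {self.start} >= end {self.end}")


@dataclass
class RenalBand:
    clcr_lo: float
    clcr_hi: float
    dose_mg: float
    interval_h: float


@dataclass
class DesignSpec:
    """Dosing regimen and blood-sampling design of a source study."""

    dose_mg: float
    interval_h: float
    infusion_h: float
    loading_dose_mg: Optional[float] = None
    loading_dose_mg_per_kg: Optional[float] = None
    renal_table: list = field(default_factory=list)       # list[RenalBand]
    sampling_windows: list = field(default_factory=list)  # list[SamplingWindow]
    samples_per_patient: float = 1.0
    steady_state_only: bool = True
    n_intervals: Optional[int] = None   # override automatic steady-state length

    def validate(self, study_id: str = "?") -> None:
        if self.interval_h <= 0:
            raise StudyValidationError(study_id, "interval_h",
                                       f"must be > 0, got {self.interval_h}")
        if not 0 < self.infusion_h <= self.interval_h:
            raise StudyValidationError(
                study_id, "infusion_h",
                f"must lie in (0, interval], got {self.infusion_h}")
        if self.dose_mg <= 0:
            raise StudyValidationError(study_id, "dose_mg", "must be > 0")
        if self.samples_per_patient < 1:
            raise StudyValidationError(study_id, "samples_per_patient",
                                       "must be >= 1")
        for w in self.sampling_windows:
            w.validate(study_id)
            if w.start is not None and (w.start < 0 or w.end > self.interval_h):
                raise StudyValidationError(
                    study_id, "sampling",
                    "window must lie within one dosing interval")
        for band in self.renal_table:
            if band.interval_h <= 0 or band.dose_mg <= 0:
                raise StudyValidationError(study_id, "renal_table",
                                           "band dose/interval must be > 0")


@dataclass
class StudyDescriptor:
    """One published popPK study in machine-readable form."""

    study_id: str
    n_patients: int
    covariates: dict                  # name -> CovariateSummary
    source_model: SourceModel
    design: DesignSpec
    disease_labels: set = field(default_factory=set)
    bmi_min: Optional[float] = None   # e.g. extreme-obesity inclusion criterion

    def __post_init__(self):
        self.disease_labels = {str(s).lower() for s in self.disease_labels}

    def validate(self) -> None:
        sid = self.study_id
        if self.n_patients < 1:
            raise StudyValidationError(sid, "n_patients", "must be >= 1")
        for required in ("CLCR", "BW"):
            if required not in self.covariates:
                raise StudyValidationError(sid, "covariates",
                                           f"{required} summary is required")
        for name, cov in self.covariates.items():
            if name != cov.name:
                raise StudyValidationError(sid, "covariates",
                                           f"key {name!r} != summary name {cov.name!r}")
            cov.validate(sid)
        self.source_model.validate(sid)
        self.design.validate(sid)


# ---------------------------------------------------------------------------
# operations

def typical_cl_at_reference(model: SourceModel,
                            clcr_ref: float = CLCR_REFERENCE) -> float:
    """Evaluate a study's CL formula at a reference CLcr, random effects zero."""
    if clcr_ref <= 0:
        raise ValueError(f"clcr_ref must be > 0, got {clcr_ref}")
    cl = model.typical_cl(clcr_ref)
    if not cl > 0:
        raise ImplausibleModelError(
            f"typical CL at CLcr={clcr_ref} is {cl} L/h (must be > 0)")
    return cl


def plausibility_screen(model: SourceModel) -> str:
    """Classify a source model by its typical CL at CLcr = 50 mL/min.

    Returns ``'plausible'``, ``'implausible_high'`` (CL > 6 L/h) or
    ``'implausible_low'`` (CL < 1.5 L/h); the boundaries count as plausible.
    """
    cl = typical_cl_at_reference(model, CLCR_REFERENCE)
    if cl > CL_PLAUSIBLE_HIGH:
        return "implausible_high"
    if cl < CL_PLAUSIBLE_LOW:
        return "implausible_low"
    return "plausible"


# ---------------------------------------------------------------------------
# serialization

def _summary_from_dict(name: str, d: dict) -> CovariateSummary:
    return CovariateSummary(name=name, **d)


def _model_from_dict(d: dict) -> SourceModel:
    d = dict(d)
    resid = d.pop("residual", {})
    d["residual"] = ResidualSpec(**resid)
    d["cl_coefficients"] = tuple(d["cl_coefficients"])
    return SourceModel(**d)


def _design_from_dict(d: dict) -> DesignSpec:
    d = dict(d)
    d["sampling_windows"] = [SamplingWindow(**w)
                             for w in d.get("sampling_windows", [])]
    d["renal_table"] = [RenalBand(**b) for b in d.get("renal_table", [])]
    return DesignSpec(**d)


def descriptor_from_dict(d: dict) -> StudyDescriptor:
    try:
        study = StudyDescriptor(
            study_id=str(d["study_id"]),
            n_patients=int(d["n_patients"]),
            covariates={name: _summary_from_dict(name, s)
                        for name, s in d.get("covariates", {}).items()},
            source_model=_model_from_dict(d["source_model"]),
            design=_design_from_dict(d["design"]),
            disease_labels=set(d.get("disease_labels", [])),
            bmi_min=d.get("bmi_min"),
        )
    except (KeyError, TypeError) as exc:
        raise StudyValidationError(str(d.get("study_id", "?")), "schema",
                                   str(exc)) from exc
    study.validate()
    return study


def descriptor_to_dict(study: StudyDescriptor) -> dict:
    d = asdict(study)
    d["disease_labels"] = sorted(study.disease_labels)
    for name, cov in d["covariates"].items():
        cov.pop("name")
        # drop unpopulated fields for readable round-trips
        d["covariates"][name] = {k: v for k, v in cov.items()
                                 if v is not None and v is not False}
    d["source_model"]["cl_coefficients"] = list(
        study.source_model.cl_coefficients)
    return d


def load_studies(path) -> list:
    """Load and validate a list of study descriptors from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if doc is None:
        return []
    if isinstance(doc, dict):
        version = doc.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise StudyValidationError("?", "schema_version",
                                       f"unsupported version {version}")
        entries = doc.get("studies", [])
    else:
        entries = doc
    return [descriptor_from_dict(e) for e in entries]


def dump_studies(studies, path) -> None:
    """Write descriptors to YAML (or JSON when the suffix says so)."""
    doc = {"schema_version": SCHEMA_VERSION,
           "studies": [descriptor_to_dict(s) for s in studies]}
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def vancomycin_fixture_path() -> Path:
    """Path of the packaged 19-study vancomycin descriptor file."""
    return Path(__file__).parent / "data" / "vancomycin_studies.yaml"


def load_vancomycin_studies() -> list:
    return load_studies(vancomycin_fixture_path())
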