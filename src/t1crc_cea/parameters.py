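"""Model input registry: parameters, biomarker classes, and treatment strategies.

Every quantity the model consumes — transition probabilities, costs (2019 USD),
health-state utilities, and analysis settings — lives in a :class:`ParameterSet`
loaded from a YAML config. The packaged default (``data/basecase.yaml``) carries
the published base-case estimates with their sensitivity ranges and sampling
distribution families, so deterministic and probabilistic sensitivity analyses
can rewrite any entry without touching code.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import yaml

__all__ = [
    "Strategy",
    "ClassId",
    "BiomarkerClass",
    "Parameter",
    "ParameterSet",
    "ParameterValidationError",
    "load_parameter_set",
    "default_parameter_set",
    "parameter_at",
]

FAMILIES = ("beta", "gamma", "uniform", "fixed")
ROLES = ("probability", "cost", "utility", "rate", "setting")


class ParameterValidationError(ValueError):
    """A config entry is missing, unparseable, or violates an invariant."""


class Strategy(enum.Enum):
    """Elective treatment strategy for the index T1 lesion.

    ET and LC carry an intra-procedural conversion pathway to emergency open
    colectomy; OC has no emergency pathway.
    """

    ET = "ET"
    LC = "LC"
    OC = "OC"

    @property
    def has_emergency_pathway(self) -> bool:
        return self is not Strategy.OC


class ClassId(enum.Enum):
    """Biomarker prognostic class (APC/KRAS/TP53 genotype, or BRAFV600E MSI-H)."""

    class0 = "class0"
    class1 = "class1"
    class2 = "class2"
    class3 = "class3"
    class4 = "class4"
    msi_h = "msi_h"


@dataclass(frozen=True)
class BiomarkerClass:
    id: ClassId
    label: str
    monthly_crc_mortality: float
    class_hazard_ratio: float | None  # None for MSI-H (outside the HR ladder)
    mortality_param: str = ""

    def __post_init__(self):
        if not 0.0 <= self.monthly_crc_mortality <= 1.0:
            raise ParameterValidationError(
                f"{self.id.value}: monthly CRC mortality {self.monthly_crc_mortality} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class Parameter:
    """One model input with its base-case value, sensitivity range, and PSA family."""

    name: str
    base: float
    low: float
    high: float
    family: str = "fixed"
    units: str = ""
    role: str = "probability"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterValidationError(
                f"{self.name}: unknown distribution family {self.family!r}"
            )
        if self.role not in ROLES:
            raise ParameterValidationError(f"{self.name}: unknown role {self.role!r}")
        if not (self.low <= self.base <= self.high):
            raise ParameterValidationError(
                f"{self.name}: range violation, need low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.role == "probability" and not (
            0.0 <= self.low and self.high <= 1.0
        ):
            raise ParameterValidationError(
                f"{self.name}: probability range ({self.low}, {self.high}) outside [0, 1]"
            )
        if self.role == "utility" and not (0.0 <= self.low and self.high <= 1.0):
            raise ParameterValidationError(
                f"{self.name}: utility range ({self.low}, {self.high}) outside [0, 1]"
            )
        if self.role == "cost" and self.low < 0:
            raise ParameterValidationError(f"{self.name}: negative cost {self.low}")


# Names the engine resolves; validation rejects a config missing any of them.
REQUIRED_PARAMETERS = (
    "p_mort30_ET", "p_mort30_OC", "p_mort30_LC",
    "p_compl_ET", "p_compl_OC", "p_compl_LC",
    "p_convert_ET", "p_convert_LC",
    "p_recur_ET", "p_recur_OC", "p_recur_LC",
    "p_crcdeath_class0", "p_crcdeath_class1", "p_crcdeath_class2",
    "p_crcdeath_class3", "p_crcdeath_class4", "p_crcdeath_msi_h",
    "cost_ET", "cost_OC", "cost_LC",
    "cost_emergency_after_ET", "cost_emergency_after_LC",
    "cost_surveillance_monthly",
    "cost_recur_treatment_ET", "cost_recur_treatment_OC", "cost_recur_treatment_LC",
    "cost_compl_bleeding", "cost_compl_obstruction",
    "u_pre",
    "u_ET_m1", "u_ET_post", "u_OC_m1", "u_OC_post", "u_LC_m1", "u_LC_post",
    "u_emergency_m1", "u_emergency_post",
    "u_recur_ET", "u_recur_OC", "u_recur_LC",
    "discount_rate_annual", "start_age_years", "max_age_years",
    "cycle_length_months", "wtp_per_qaly",
)


@dataclass(frozen=True)
class ParameterSet:
    """Validated registry of all model inputs plus the six biomarker classes."""

    parameters: Mapping[str, Parameter]
    classes: Mapping[ClassId, BiomarkerClass]
    currency: str = "2019 USD"

    def __post_init__(self):
        missing = [n for n in REQUIRED_PARAMETERS if n not in self.parameters]
        if missing:
            raise ParameterValidationError(f"missing parameters: {', '.join(missing)}")
        missing_cls = [c for c in ClassId if c not in self.classes]
        if missing_cls:
            raise ParameterValidationError(
                f"missing biomarker classes: {', '.join(c.value for c in missing_cls)}"
            )

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self.parameters[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def value(self, name: str) -> float:
        return self[name].base

    def values(self) -> dict[str, float]:
        """Base-case value of every parameter (one flat dict for the engine)."""
        return {n: p.base for n, p in self.parameters.items()}

    def biomarker_class(self, cls: Union[ClassId, str]) -> BiomarkerClass:
        cls = ClassId(cls) if not isinstance(cls, ClassId) else cls
        return self.classes[cls]

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """A copy with one parameter's base value replaced (range widened to fit).

        This is the hook sensitivity analyses use to move a single input; the
        replacement value may lie anywhere, so the stored range is stretched to
        keep the low <= base <= high invariant rather than rejecting the probe.
        """
        p = self[name]
        new = replace(p, base=value, low=min(p.low, value), high=max(p.high, value))
        params = dict(self.parameters)
        params[name] = new
        return ParameterSet(params, self.classes, self.currency)

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        ps = self
        for name, value in overrides.items():
            ps = ps.with_value(name, value)
        return ps

    def to_yaml(self) -> str:
        doc = {
            "currency": self.currency,
            "classes": {
                c.id.value: {
                    "label": c.label,
                    "hazard_ratio": c.class_hazard_ratio,
                    "mortality_param": c.mortality_param,
                }
                for c in self.classes.values()
            },
            "parameters": {
                p.name: {
                    "base": p.base, "low": p.low, "high": p.high,
                    "family": p.family, "units": p.units, "role": p.role,
                }
                for p in self.parameters.values()
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)


def _coerce_number(name: str, key: str, raw) -> float:
    if raw is None or isinstance(raw, bool) or not isinstance(raw, (int, float)):
        raise ParameterValidationError(f"{name}: field {key!r} is not a number ({raw!r})")
    return float(raw)


def load_parameter_set(source: Union[str, Path, io.TextIOBase]) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML path, YAML text, or stream.

    Raises :class:`ParameterValidationError` naming the offending entry on any
    missing key, unparseable value, or range violation.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = str(source)

    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParameterValidationError(f"config does not parse as YAML: {exc}") from exc
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ParameterValidationError("config must be a mapping with a 'parameters' block")

    params: dict[str, Parameter] = {}
    for name, entry in doc["parameters"].items():
        if not isinstance(entry, dict):
            raise ParameterValidationError(f"{name}: entry must be a mapping")
        for key in ("base", "low", "high"):
            if key not in entry:
                raise ParameterValidationError(f"{name}: missing field {key!r}")
        params[name] = Parameter(
            name=name,
            base=_coerce_number(name, "base", entry["base"]),
            low=_coerce_number(name, "low", entry["low"]),
            high=_coerce_number(name, "high", entry["high"]),
            family=entry.get("family", "fixed"),
            units=entry.get("units", ""),
            role=entry.get("role", "probability"),
        )

    classes: dict[ClassId, BiomarkerClass] = {}
    for key, entry in (doc.get("classes") or {}).items():
        try:
            cid = ClassId(key)
        except ValueError:
            raise ParameterValidationError(f"unknown biomarker class {key!r}") from None
        mortality_param = entry.get("mortality_param", f"p_crcdeath_{cid.value}")
        if mortality_param not in params:
            raise ParameterValidationError(
                f"{key}: mortality_param {mortality_param!r} not in parameters"
            )
        hr = entry.get("hazard_ratio")
        classes[cid] = BiomarkerClass(
            id=cid,
            label=entry.get("label", cid.value),
            monthly_crc_mortality=params[mortality_param].base,
            class_hazard_ratio=None if hr is None else float(hr),
            mortality_param=mortality_param,
        )

    return ParameterSet(params, classes, currency=doc.get("currency", "2019 USD"))


def default_parameter_set() -> ParameterSet:
    """The packaged base case (published Table of inputs, 2019 USD)."""
    text = resources.files("t1crc_cea").joinpath("data/basecase.yaml").read_text()
    return load_parameter_set(text)


def parameter_at(params: ParameterSet, name: str, level: str) -> float:
    """Return a parameter's value at one of the sensitivity levels low|base|high."""
    p = params[name]
    if level not in ("low", "base", "high"):
        raise ValueError(f"level must be low|base|high, got {level!r}")
    return getattr(p, level)
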