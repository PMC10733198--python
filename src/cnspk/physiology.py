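"""CNS physiology registry: literature values, aggregation, derivations.

Every physiological parameter carries its literature values, the rule that
produced its final value (``mean``, ``median``, ``single``, ``printed`` or
``derived``), and an optional derivation formula. Registries are stored as
YAML; the packaged ``mouse_default`` registry is loaded with
:func:`mouse_registry`. Values are converted to canonical units
(ml, ml/min, cm^2, cm) on access via :meth:`PhysiologyRegistry.canonical`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from statistics import mean as _mean, median as _median

import yaml

__all__ = [
    "PhysiologyParameter",
    "PhysiologyRegistry",
    "ValidationReport",
    "aggregate_parameter",
    "derive_dependent_parameters",
    "validate_physiology",
    "mouse_registry",
    "csf_flow_from_turnover",
    "cell_membrane_surface",
]

AGGREGATIONS = ("mean", "median", "single", "printed", "derived")

#: declared unit -> (canonical unit, multiplicative factor)
_UNIT_TO_CANONICAL = {
    "ul": ("ml", 1e-3),
    "ml": ("ml", 1.0),
    "ml/min": ("ml/min", 1.0),
    "cm^2": ("cm^2", 1.0),
    "um": ("cm", 1e-4),
    "cm": ("cm", 1.0),
    "unitless": ("unitless", 1.0),
    "pH": ("pH", 1.0),
    "count": ("count", 1.0),
}


def aggregate_parameter(values, method):
    """Aggregate literature values into a single final value.

    Parameters
    ----------
    values : sequence of float
        Positive literature values.
    method : {"mean", "median"}
        Arithmetic statistic to apply.
    """
    values = list(values)
    if not values:
        raise ValueError("cannot aggregate an empty list of values")
    if any(v <= 0 for v in values):
        raise ValueError(f"all literature values must be positive, got {values}")
    if method == "mean":
        return float(_mean(values))
    if method == "median":
        return float(_median(values))
    raise ValueError(f"unknown aggregation method {method!r}")


# ---------------------------------------------------------------------------
# Derivation formulas (footnote-style dependencies between parameters)
# ---------------------------------------------------------------------------

def csf_flow_from_turnover(csf_volume_ml=0.040, turnovers_per_day=13.0):
    """CSF flow (ml/min) from total CSF volume and daily turnover count."""
    return csf_volume_ml * turnovers_per_day / (24.0 * 60.0)


def cell_membrane_surface(n_cells, v_icf_ul):
    """Total brain-cell membrane surface (cm^2), monodisperse-sphere model.

    Each of ``n_cells`` cells is a sphere of volume ``V_ICF / n_cells``;
    the sphere surface is (36*pi)^(1/3) * v^(2/3).
    """
    if n_cells <= 0 or v_icf_ul <= 0:
        raise ValueError("n_cells and V_ICF must be positive")
    v_cm3 = v_icf_ul * 1e-3  # 1 ul = 1e-3 cm^3
    per_cell = v_cm3 / n_cells
    return n_cells * (36.0 * math.pi) ** (1.0 / 3.0) * per_cell ** (2.0 / 3.0)


def _derive_icf(reg):
    return 0.8 * reg.value("V_brain_total")


def _derive_lysosome(reg):
    return 0.0125 * reg.value("V_ICF")


def _derive_bcsfb(reg):
    return 0.5 * reg.value("SA_BBB")


def _derive_bcm(reg):
    return cell_membrane_surface(reg.value("N_cells"), reg.value("V_ICF"))


#: derivation key -> (dependency names, function of registry)
DERIVATIONS = {
    "icf_from_total_brain": (("V_brain_total",), _derive_icf),
    "lysosome_from_icf": (("V_ICF",), _derive_lysosome),
    "bcsfb_half_bbb": (("SA_BBB",), _derive_bcsfb),
    "cell_membrane_spheres": (("N_cells", "V_ICF"), _derive_bcm),
}


@dataclass
class PhysiologyParameter:
    """One named physiological parameter with provenance."""

    name: str
    unit: str
    aggregation: str
    literature_values: list = field(default_factory=list)
    final_value: float | None = None
    derivation: str | None = None
    source_refs: list = field(default_factory=list)
    note: str | None = None

    def __post_init__(self):
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(
                f"{self.name}: unknown aggregation {self.aggregation!r}"
            )
        if self.unit not in _UNIT_TO_CANONICAL:
            raise ValueError(f"{self.name}: unknown unit {self.unit!r}")

    @property
    def canonical_unit(self):
        return _UNIT_TO_CANONICAL[self.unit][0]

    def canonical_value(self):
        if self.final_value is None:
            raise ValueError(f"parameter {self.name} is unresolved")
        return self.final_value * _UNIT_TO_CANONICAL[self.unit][1]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_physiology`."""

    hard: list = field(default_factory=list)
    soft: list = field(default_factory=list)

    @property
    def ok(self):
        return not self.hard


class PhysiologyRegistry:
    """Named collection of :class:`PhysiologyParameter` objects."""

    def __init__(self, name, parameters, species=None):
        self.name = name
        self.species = species
        self.parameters = dict(parameters)

    # -- access ------------------------------------------------------------

    def __contains__(self, key):
        return key in self.parameters

    def param(self, name):
        try:
            return self.parameters[name]
        except KeyError:
            raise KeyError(f"physiology parameter {name!r} not in registry") from None

    def value(self, name):
        """Final value in the parameter's declared unit."""
        p = self.param(name)
        if p.final_value is None:
            raise ValueError(f"parameter {name!r} is unresolved")
        return p.final_value

    def canonical(self, name):
        """Final value converted to canonical units (ml, ml/min, cm^2, cm)."""
        return self.param(name).canonical_value()

    def __getitem__(self, name):
        return self.canonical(name)

    def with_overrides(self, **overrides):
        """Copy of the registry with final values replaced (declared units)."""
        reg = copy.deepcopy(self)
        for key, val in overrides.items():
            reg.param(key).final_value = float(val)
        return reg

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, payload):
        params = {}
        for name, entry in payload["parameters"].items():
            params[name] = PhysiologyParameter(
                name=name,
                unit=entry["unit"],
                aggregation=entry["aggregation"],
                literature_values=[float(v) for v in entry.get("literature_values", [])],
                final_value=(
                    float(entry["final_value"]) if "final_value" in entry else None
                ),
                derivation=entry.get("derivation"),
                source_refs=list(entry.get("source_refs", [])),
                note=entry.get("note"),
            )
        return cls(payload.get("name", "unnamed"), params, payload.get("species"))

    @classmethod
    def from_yaml(cls, path_or_stream):
        if hasattr(path_or_stream, "read"):
            payload = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    def to_dict(self):
        out = {"name": self.name, "species": self.species, "parameters": {}}
        for name, p in self.parameters.items():
            entry = {"unit": p.unit, "aggregation": p.aggregation}
            if p.literature_values:
                entry["literature_values"] = list(p.literature_values)
            if p.final_value is not None:
                entry["final_value"] = p.final_value
            if p.derivation:
                entry["derivation"] = p.derivation
            if p.source_refs:
                entry["source_refs"] = list(p.source_refs)
            if p.note:
                entry["note"] = p.note
            out["parameters"][name] = entry
        return out

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    # -- resolution --------------------------------------------------------

    def resolve(self):
        """Fill in final values for mean/median/single parameters."""
        for p in self.parameters.values():
            if p.aggregation in ("mean", "median"):
                p.final_value = aggregate_parameter(
                    p.literature_values, p.aggregation
                )
            elif p.aggregation == "single":
                if p.final_value is None:
                    if len(p.literature_values) != 1:
                        raise ValueError(
                            f"{p.name}: aggregation 'single' needs exactly one "
                            f"literature value, got {p.literature_values}"
                        )
                    p.final_value = float(p.literature_values[0])
            elif p.aggregation == "printed":
                if p.final_value is None:
                    raise ValueError(
                        f"{p.name}: aggregation 'printed' requires final_value"
                    )
        return self


def derive_dependent_parameters(registry):
    """Compute every ``derived`` parameter from its derivation formula.

    Returns the same registry with derived final values filled in.
    Raises ``ValueError`` naming the first missing prerequisite.
    """
    for p in registry.parameters.values():
        if p.aggregation != "derived":
            continue
        if p.derivation not in DERIVATIONS:
            raise ValueError(f"{p.name}: unknown derivation {p.derivation!r}")
        deps, fn = DERIVATIONS[p.derivation]
        for dep in deps:
            if dep not in registry or registry.param(dep).final_value is None:
                raise ValueError(
                    f"{p.name}: missing prerequisite parameter {dep!r}"
                )
        p.final_value = float(fn(registry))
    return registry


def _sig4(x):
    if x == 0:
        return 0.0
    return float(f"{x:.4g}")


def validate_physiology(registry):
    """Report hard invariant violations and soft internal inconsistencies.

    Report-only: never raises for a violated invariant.
    """
    report = ValidationReport()
    hard, soft = report.hard, report.soft

    for p in registry.parameters.values():
        if p.final_value is None:
            hard.append(f"{p.name}: unresolved (no final value)")
            continue
        if p.final_value <= 0:
            hard.append(f"{p.name}: final value {p.final_value} is not positive")
        if p.aggregation in ("mean", "median"):
            expected = aggregate_parameter(p.literature_values, p.aggregation)
            if _sig4(expected) != _sig4(p.final_value):
                hard.append(
                    f"{p.name}: final value {p.final_value} != "
                    f"{p.aggregation}({p.literature_values}) = {expected}"
                )
        elif p.aggregation == "printed" and p.literature_values:
            lit_mean = _mean(p.literature_values)
            if abs(p.final_value - lit_mean) > 0.01 * abs(lit_mean):
                soft.append(
                    f"{p.name}: printed final value {p.final_value} differs from "
                    f"the mean of the listed literature values ({lit_mean:.4g})"
                )
        elif p.aggregation == "derived" and p.derivation in DERIVATIONS:
            expected = DERIVATIONS[p.derivation][1](registry)
            if expected > 0 and abs(p.final_value - expected) > 1e-9 * expected:
                hard.append(
                    f"{p.name}: final value {p.final_value} != derivation "
                    f"output {expected}"
                )

    def _have(*names):
        return all(
            n in registry and registry.param(n).final_value is not None
            for n in names
        )

    if _have("V_ICF", "V_ECF", "V_brain_total"):
        if registry.value("V_ICF") + registry.value("V_ECF") >= registry.value(
            "V_brain_total"
        ):
            hard.append("V_ICF + V_ECF >= V_brain_total")

    for name in ("f_trans_BBB", "f_trans_BCSFB", "f_para_BBB", "f_para_BCSFB"):
        if _have(name):
            v = registry.value(name)
            if not (0 < v <= 1):
                hard.append(f"{name}: effective surface fraction {v} not in (0, 1]")

    for name in ("pH_plasma", "pH_ECF", "pH_ICF", "pH_LYS", "pH_CSF"):
        if _have(name):
            v = registry.value(name)
            if not (3.0 <= v <= 9.0):
                hard.append(f"{name}: pH {v} outside [3, 9]")

    if _have("V_ventricles_total", "V_CM", "V_SAS", "V_CSF_total"):
        sub = (
            registry.value("V_ventricles_total")
            + registry.value("V_CM")
            + registry.value("V_SAS")
        )
        total = registry.value("V_CSF_total")
        if abs(sub - total) > 0.05 * total:
            soft.append(
                f"CSF sub-volumes (ventricles + cisterna magna + subarachnoid "
                f"space = {sub:.4g} ul) do not sum to total CSF volume "
                f"({total:.4g} ul)"
            )

    return report


def mouse_registry():
    """Load, resolve and derive the packaged default mouse registry."""
    ref = resources.files("cnspk.data") / "mouse_physiology.yaml"
    with ref.open() as fh:
        reg = PhysiologyRegistry.from_yaml(fh)
    reg.resolve()
    return derive_dependent_parameters(reg)
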