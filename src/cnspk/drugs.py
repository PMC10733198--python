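"""Drug records and pH/lipophilicity-dependent derived quantities."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "DrugRecord",
    "fraction_neutral",
    "unbound_fraction_cells",
    "paracellular_permeability",
    "estimate_p_trans_placeholder",
    "load_drugs",
]

#: pKa sites outside this window are treated as non-ionizable at body pH.
IONIZABLE_PKA_RANGE = (2.0, 12.0)


@dataclass
class DrugRecord:
    """Physicochemical + biological properties of one drug.

    Units: ``mwt`` g/mol, ``psa`` A^2, permeabilities cm/min. ``pka_acid`` /
    ``pka_base`` may list several sites; only those inside
    :data:`IONIZABLE_PKA_RANGE` contribute to ionization.
    """

    name: str
    mwt: float
    logp: float
    pka_acid: list = field(default_factory=list)
    pka_base: list = field(default_factory=list)
    psa: float = 0.0
    hba: int = 0
    hbd: int = 0
    fu_plasma: float = 1.0
    kpuu_bbb: float | None = None
    kpuu_method: str | None = None
    p_trans: float | None = None
    p_para_override: float | None = None

    def __post_init__(self):
        if self.mwt <= 0:
            raise ValueError(f"{self.name}: Mwt must be positive")
        if not (0 < self.fu_plasma <= 1):
            raise ValueError(f"{self.name}: fu_plasma must be in (0, 1]")
        if self.kpuu_bbb is not None and self.kpuu_bbb <= 0:
            raise ValueError(f"{self.name}: Kp,uu,BBB must be positive")
        if self.psa < 0:
            raise ValueError(f"{self.name}: PSA must be non-negative")

    def ionizable_acids(self):
        lo, hi = IONIZABLE_PKA_RANGE
        return [p for p in self.pka_acid if lo <= p <= hi]

    def ionizable_bases(self):
        lo, hi = IONIZABLE_PKA_RANGE
        return [p for p in self.pka_base if lo <= p <= hi]


def fraction_neutral(pH, drug):
    """Fraction of drug in the neutral species at the given pH.

    Henderson-Hasselbalch with an independent-site approximation:
    acids contribute 1/(1+10^(pH-pKa)), bases 1/(1+10^(pKa-pH)), multiprotic
    species multiply site terms. A drug with no ionizable group returns 1.
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH {pH} outside [0, 14]")
    f = 1.0
    for pka in drug.ionizable_acids():
        f *= 1.0 / (1.0 + 10.0 ** (pH - pka))
    for pka in drug.ionizable_bases():
        f *= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return f


def unbound_fraction_cells(drug, f_phospholipid):
    """Unbound fraction in brain cells from nonspecific phospholipid binding.

    fu_cell = 1 / (1 + f_phospholipid * 10^logP).
    """
    if not (0.0 <= f_phospholipid < 1.0):
        raise ValueError("f_phospholipid must be in [0, 1)")
    return 1.0 / (1.0 + f_phospholipid * 10.0 ** drug.logp)


#: aqueous diffusivity D_aq = _DAQ_COEF * Mwt^_DAQ_EXP, cm^2/s
_DAQ_COEF = 9.9e-5
_DAQ_EXP = -0.453


def paracellular_permeability(drug, width_um):
    """Paracellular permeability (cm/min) across a barrier of given width.

    P = D_aq / width with D_aq from a molecular-weight power law; an explicit
    ``p_para_override`` on the record wins.
    """
    if width_um <= 0:
        raise ValueError("width must be positive")
    if drug.p_para_override is not None:
        return drug.p_para_override
    if drug.mwt <= 0:
        raise ValueError("Mwt must be positive")
    d_aq = _DAQ_COEF * drug.mwt ** _DAQ_EXP * 60.0  # cm^2/min
    return d_aq / (width_um * 1e-4)


def estimate_p_trans_placeholder(drug, intercept=-3.5, slope=0.4):
    """PLACEHOLDER passive transcellular permeability (cm/min).

    A deliberately simple logP-linear stand-in, log10(P) = intercept +
    slope*logP, for exploration when no measured permeability is available.
    Not a validated structure-permeability model.
    """
    return 10.0 ** (intercept + slope * drug.logp)


def load_drugs(path=None):
    """Load drug records from YAML; defaults to the packaged fixture."""
    if path is None:
        ref = resources.files("cnspk.data") / "drugs.yaml"
        with ref.open() as fh:
            payload = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            payload = yaml.safe_load(fh)
    drugs = {}
    for name, entry in payload["drugs"].items():
        drugs[name] = DrugRecord(
            name=name,
            mwt=float(entry["mwt"]),
            logp=float(entry["logp"]),
            pka_acid=[float(v) for v in entry.get("pka_acid", [])],
            pka_base=[float(v) for v in entry.get("pka_base", [])],
            psa=float(entry.get("psa", 0.0)),
            hba=int(entry.get("hba", 0)),
            hbd=int(entry.get("hbd", 0)),
            fu_plasma=float(entry.get("fu_plasma", 1.0)),
            kpuu_bbb=(
                float(entry["kpuu_bbb"]) if entry.get("kpuu_bbb") is not None else None
            ),
            kpuu_method=entry.get("kpuu_method"),
            p_trans=(
                float(entry["p_trans_cm_min"])
                if entry.get("p_trans_cm_min") is not None
                else None
            ),
            p_para_override=(
                float(entry["p_para_override_cm_min"])
                if entry.get("p_para_override_cm_min") is not None
                else None
            ),
        )
    return drugs
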