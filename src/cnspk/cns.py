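"""CNS PBPK ODE system: physiology + drug + asymmetry factors + forcing.

Compartments (amounts, ng): brain microvasculature (MV), brain ECF, brain
ICF, lysosomes (LYS), and the CSF cascade lateral ventricles (LV) -> third+
fourth ventricles (TFV) -> cisterna magna (CM) -> subarachnoid space (SAS).
The unbound plasma concentration enters as a forcing function.

Mechanistic conventions (config-overridable where noted):
 - transcellular permeation acts on the neutral species only; paracellular
   permeation acts on total unbound drug and is symmetric;
 - BBB influx clearance is scaled by AF_in and efflux by AF_out;
 - BCSFB flux exchanges MV with LV and TFV in equal halves;
 - ECF bulk flow drains into the cisterna magna; SAS clears to a sink at
   Q_CSF + Q_ECF;
 - intracellular nonspecific binding is an equilibrium unbound fraction
   fu_cell; lysosomes share the same binding.

Because the system is linear, the state equation is dA/dt = M A + b u(t);
steady states are obtained by a direct linear solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .bbb import AsymmetryFactors
from .drugs import fraction_neutral, paracellular_permeability, unbound_fraction_cells

__all__ = [
    "STATE_NAMES",
    "ClearanceTable",
    "CNSModel",
    "CNSSimulationResult",
    "assemble_clearances",
    "build_cns_model",
    "build_ode_system",
    "system_matrices",
    "simulate_cns",
    "steady_state_kpuu",
]

STATE_NAMES = ("MV", "ECF", "ICF", "LYS", "CSF_LV", "CSF_TFV", "CSF_CM", "CSF_SAS")
_I_MV, _I_ECF, _I_ICF, _I_LYS, _I_LV, _I_TFV, _I_CM, _I_SAS = range(8)


@dataclass
class ClearanceTable:
    """Pathway clearances (ml/min) and partition factors for one assembly."""

    cl_bbb_trans: float
    cl_bbb_para: float
    cl_bcsfb_trans: float
    cl_bcsfb_para: float
    cl_bcm: float
    cl_lys: float
    fn_plasma: float
    fn_ecf: float
    fn_icf: float
    fn_lys: float
    fn_csf: float
    fu_cell: float
    # directional totals (asymmetry factors applied)
    bbb_in: float = 0.0
    bbb_out: float = 0.0
    bcsfb_in: float = 0.0
    bcsfb_out: float = 0.0

    def as_dict(self):
        return dict(self.__dict__)


def assemble_clearances(physiology, drug, af, af_bcsfb=None):
    """Precompute all pathway clearances for a drug on a physiology.

    BBB/BCSFB passive clearances combine a transcellular term
    ``P_trans * SA * f_trans`` (neutral species on each face) and a
    paracellular term ``P_para * SA * f_para`` (all unbound species,
    symmetric). Directional totals carry the asymmetry factors. Cell-membrane
    and lysosomal clearances use the same passive transcellular permeability
    over SA_BCM and SA_LYS.
    """
    if drug.p_trans is None:
        raise ValueError(
            f"drug {drug.name!r} has no passive transcellular permeability "
            "(p_trans); supply one in the drug record"
        )
    if af_bcsfb is None:
        af_bcsfb = AsymmetryFactors(1.0, 1.0)

    p_para_bbb = paracellular_permeability(drug, physiology.value("w_BBB"))
    p_para_bcsfb = paracellular_permeability(drug, physiology.value("w_BCSFB"))

    sa_bbb = physiology["SA_BBB"]
    sa_bcsfb = physiology["SA_BCSFB"]

    cl_bbb_trans = drug.p_trans * sa_bbb * physiology["f_trans_BBB"]
    cl_bbb_para = p_para_bbb * sa_bbb * physiology["f_para_BBB"]
    cl_bcsfb_trans = drug.p_trans * sa_bcsfb * physiology["f_trans_BCSFB"]
    cl_bcsfb_para = p_para_bcsfb * sa_bcsfb * physiology["f_para_BCSFB"]
    cl_bcm = drug.p_trans * physiology["SA_BCM"]
    cl_lys = drug.p_trans * physiology["SA_LYS"]

    fn = {
        name: fraction_neutral(physiology.value(f"pH_{tag}"), drug)
        for name, tag in (
            ("plasma", "plasma"),
            ("ecf", "ECF"),
            ("icf", "ICF"),
            ("lys", "LYS"),
            ("csf", "CSF"),
        )
    }
    fu_cell = unbound_fraction_cells(drug, physiology.value("f_phospholipid"))

    table = ClearanceTable(
        cl_bbb_trans=cl_bbb_trans,
        cl_bbb_para=cl_bbb_para,
        cl_bcsfb_trans=cl_bcsfb_trans,
        cl_bcsfb_para=cl_bcsfb_para,
        cl_bcm=cl_bcm,
        cl_lys=cl_lys,
        fn_plasma=fn["plasma"],
        fn_ecf=fn["ecf"],
        fn_icf=fn["icf"],
        fn_lys=fn["lys"],
        fn_csf=fn["csf"],
        fu_cell=fu_cell,
    )
    table.bbb_in = af.af_in * (cl_bbb_trans * fn["plasma"] + cl_bbb_para)
    table.bbb_out = af.af_out * (cl_bbb_trans * fn["ecf"] + cl_bbb_para)
    table.bcsfb_in = af_bcsfb.af_in * (cl_bcsfb_trans * fn["plasma"] + cl_bcsfb_para)
    table.bcsfb_out = af_bcsfb.af_out * (cl_bcsfb_trans * fn["csf"] + cl_bcsfb_para)
    return table


@dataclass
class CNSModel:
    """Assembled CNS PBPK model ready for simulation."""

    physiology: object
    drug: object
    af: AsymmetryFactors
    forcing: object
    af_bcsfb: AsymmetryFactors = field(default_factory=lambda: AsymmetryFactors())
    clearances: ClearanceTable | None = None

    def __post_init__(self):
        if self.clearances is None:
            self.clearances = assemble_clearances(
                self.physiology, self.drug, self.af, self.af_bcsfb
            )

    @property
    def effective_bbb_in(self):
        """CL_in for the ECF closed form: AF_in*(CL_trans*fn_pl + CL_para)."""
        return self.clearances.bbb_in

    @property
    def effective_bbb_out(self):
        return self.clearances.bbb_out


def build_cns_model(physiology, drug, af, forcing, af_bcsfb=None):
    kwargs = {}
    if af_bcsfb is not None:
        kwargs["af_bcsfb"] = af_bcsfb
    return CNSModel(physiology=physiology, drug=drug, af=af, forcing=forcing, **kwargs)


def _unbound_coefficients(model):
    """kappa_i such that unbound concentration in compartment i = kappa_i*A_i."""
    phys, cl = model.physiology, model.clearances
    return np.array(
        [
            1.0 / phys["V_MV"],
            1.0 / phys["V_ECF"],
            cl.fu_cell / phys["V_ICF"],
            cl.fu_cell / phys["V_LYS_total"],
            1.0 / phys["V_LV"],
            1.0 / phys["V_TFV"],
            1.0 / phys["V_CM"],
            1.0 / phys["V_SAS"],
        ]
    )


def system_matrices(model):
    """Linear system dA/dt = M A + b u(t) plus the sink-outflow row.

    Returns ``(M, b, kappa, out_coeffs)`` where ``out_coeffs @ A`` is the
    instantaneous clearance to plasma return + CSF sink (ng/min per unit
    forcing bookkeeping is handled by the caller).
    """
    phys, cl = model.physiology, model.clearances
    kappa = _unbound_coefficients(model)
    q_cbf = phys["Q_CBF"]
    q_ecf = phys["Q_ECF"]
    q_csf = phys["Q_CSF"]

    F = np.zeros((8, 8))  # flux coefficients on unbound concentrations

    # microvasculature <-> plasma
    F[_I_MV, _I_MV] -= q_cbf
    # BBB
    F[_I_MV, _I_MV] -= cl.bbb_in
    F[_I_ECF, _I_MV] += cl.bbb_in
    F[_I_ECF, _I_ECF] -= cl.bbb_out
    F[_I_MV, _I_ECF] += cl.bbb_out
    # BCSFB, split equally between LV and TFV
    for idx in (_I_LV, _I_TFV):
        F[_I_MV, _I_MV] -= 0.5 * cl.bcsfb_in
        F[idx, _I_MV] += 0.5 * cl.bcsfb_in
        F[idx, idx] -= 0.5 * cl.bcsfb_out
        F[_I_MV, idx] += 0.5 * cl.bcsfb_out
    # brain cell membrane: ECF <-> ICF, neutral species
    F[_I_ECF, _I_ECF] -= cl.cl_bcm * cl.fn_ecf
    F[_I_ICF, _I_ECF] += cl.cl_bcm * cl.fn_ecf
    F[_I_ICF, _I_ICF] -= cl.cl_bcm * cl.fn_icf
    F[_I_ECF, _I_ICF] += cl.cl_bcm * cl.fn_icf
    # lysosomes: ICF <-> LYS, neutral species
    F[_I_ICF, _I_ICF] -= cl.cl_lys * cl.fn_icf
    F[_I_LYS, _I_ICF] += cl.cl_lys * cl.fn_icf
    F[_I_LYS, _I_LYS] -= cl.cl_lys * cl.fn_lys
    F[_I_ICF, _I_LYS] += cl.cl_lys * cl.fn_lys
    # bulk flows: ECF -> CM; CSF cascade LV -> TFV -> CM -> SAS -> sink
    F[_I_ECF, _I_ECF] -= q_ecf
    F[_I_CM, _I_ECF] += q_ecf
    F[_I_LV, _I_LV] -= q_csf
    F[_I_TFV, _I_LV] += q_csf
    F[_I_TFV, _I_TFV] -= q_csf
    F[_I_CM, _I_TFV] += q_csf
    F[_I_CM, _I_CM] -= q_csf + q_ecf
    F[_I_SAS, _I_CM] += q_csf + q_ecf
    F[_I_SAS, _I_SAS] -= q_csf + q_ecf

    M = F * kappa[np.newaxis, :]
    b = np.zeros(8)
    b[_I_MV] = q_cbf

    # outflow to plasma return + CSF sink, per amount vector
    out = np.zeros(8)
    out[_I_MV] += q_cbf * kappa[_I_MV]
    out[_I_SAS] += (q_csf + q_ecf) * kappa[_I_SAS]
    return M, b, kappa, out


def build_ode_system(model):
    """Rate function for the 10-state system (8 amounts + cumulative in/out)."""
    M, b, _, out = system_matrices(model)
    forcing = model.forcing

    def rhs(t, y):
        u = forcing(t)
        dy = np.empty(10)
        dy[:8] = M @ y[:8] + b * u
        dy[8] = b[_I_MV] * u  # cumulative input from plasma
        dy[9] = out @ y[:8]  # cumulative return to plasma + CSF sink
        return dy

    jac = np.zeros((10, 10))
    jac[:8, :8] = M
    jac[9, :8] = out
    return rhs, jac


@dataclass
class CNSSimulationResult:
    """Unbound concentration-time profiles plus mass-balance diagnostics."""

    times: np.ndarray
    amounts: pd.DataFrame  # ng per compartment
    unbound: pd.DataFrame  # ng/ml unbound per compartment
    total: pd.DataFrame  # ng/ml total per compartment
    mass_balance_residual: np.ndarray
    diagnostics: dict

    def ecf(self):
        return self.unbound["ECF"].to_numpy()

    def to_tidy(self):
        frames = []
        for comp in STATE_NAMES:
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "compartment": comp,
                        "conc_ng_ml": self.unbound[comp].to_numpy(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_cns(model, t_end, n_points=241, rtol=1e-8, atol=None, t_eval=None):
    """Integrate the CNS system with LSODA over [0, t_end].

    Integration restarts at every forcing breakpoint so that dosing
    discontinuities are handled exactly. Returns unbound concentrations
    (amount/volume for fluid spaces, amount*fu_cell/volume for cells and
    lysosomes) and a relative mass-balance residual series.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    else:
        t_eval = np.asarray(t_eval, float)
    rhs, jac = build_ode_system(model)
    breakpoints = np.asarray(getattr(model.forcing, "breakpoints", [0.0]), float)
    edges = np.unique(
        np.concatenate([[0.0, t_end], breakpoints[(breakpoints > 0) & (breakpoints < t_end)]])
    )
    if atol is None:
        atol = 1e-10

    y = np.zeros(10)
    times_out, states_out = [], []
    nfev = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg_eval = t_eval[(t_eval >= lo) & (t_eval <= hi)]
        seg_eval = np.unique(np.concatenate([[lo], seg_eval, [hi]]))
        sol = solve_ivp(
            rhs,
            (lo, hi),
            y,
            method="LSODA",
            t_eval=seg_eval,
            rtol=rtol,
            atol=atol,
            jac=lambda t, y_: jac,
        )
        if not sol.success:
            raise RuntimeError(f"CNS solver failed on [{lo}, {hi}]: {sol.message}")
        nfev += sol.nfev
        y = sol.y[:, -1].copy()
        for k, t in enumerate(sol.t):
            times_out.append(t)
            states_out.append(sol.y[:, k])

    times_all = np.array(times_out)
    states_all = np.array(states_out)
    # keep only requested output times (first occurrence)
    out_states = np.empty((t_eval.size, 10))
    for i, t in enumerate(t_eval):
        j = int(np.argmin(np.abs(times_all - t)))
        out_states[i] = states_all[j]

    kappa = _unbound_coefficients(model)
    amounts = pd.DataFrame(out_states[:, :8], columns=list(STATE_NAMES))
    unbound = pd.DataFrame(out_states[:, :8] * kappa, columns=list(STATE_NAMES))
    phys = model.physiology
    volumes = np.array(
        [
            phys["V_MV"],
            phys["V_ECF"],
            phys["V_ICF"],
            phys["V_LYS_total"],
            phys["V_LV"],
            phys["V_TFV"],
            phys["V_CM"],
            phys["V_SAS"],
        ]
    )
    total = pd.DataFrame(out_states[:, :8] / volumes, columns=list(STATE_NAMES))

    content = out_states[:, :8].sum(axis=1)
    cum_in, cum_out = out_states[:, 8], out_states[:, 9]
    scale = np.maximum(cum_in, 1e-30)
    residual = (cum_in - cum_out - content) / scale

    cmax = float(unbound.to_numpy().max()) if unbound.size else 0.0
    floor = -1e-9 * max(cmax, 1.0)
    if (unbound.to_numpy() < floor).any():
        raise RuntimeError("negative concentrations beyond numerical floor")

    return CNSSimulationResult(
        times=t_eval,
        amounts=amounts,
        unbound=unbound,
        total=total,
        mass_balance_residual=residual,
        diagnostics={"nfev": int(nfev), "rtol": rtol, "atol": atol},
    )


def steady_state_kpuu(model):
    """Steady-state unbound compartment/plasma ratios under unit forcing.

    Solves M A = -b directly (no time stepping) and returns
    ``{compartment: Cu_compartment / Cu_plasma}``.
    """
    M, b, kappa, _ = system_matrices(model)
    try:
        amounts = np.linalg.solve(M, -b)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular steady-state system: {exc}") from exc
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e14:
        raise RuntimeError(f"steady-state system ill-conditioned (cond={cond:.3g})")
    ratios = amounts * kappa
    return dict(zip(STATE_NAMES, ratios.tolist()))
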