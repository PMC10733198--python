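"""Synthetic microdialysis studies with known ground truth.

Generates plasma observations (destructive or serial sampling) and
interval-averaged brain-ECF microdialysis observations from a generating
plasma model + CNS model, with exponential interindividual variability and
proportional(+additive) residual error. Everything is reproducible from a
seed and emitted in the same CSV schemas the fitting machinery consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .bbb import asymmetry_factors
from .cns import build_cns_model, simulate_cns
from .dataset import NG_PER_MG, StudyDataset
from .plasma import DoseEvent, Forcing, _individual_model, add_residual_error, solve_amounts, IDX_CENTRAL

__all__ = ["StudyDesign", "GroundTruth", "generate_study", "interval_average"]


@dataclass
class StudyDesign:
    """Sampling layout of one synthetic study.

    ``plasma_times`` are the nominal plasma sampling times. With
    ``destructive=True`` each time point is sampled in ``animals_per_time``
    separate animals (one observation per animal); otherwise ``n_animals``
    animals are each sampled at every time. ``microdialysis_windows`` are
    (start, end) collection intervals shared by ``n_microdialysis_animals``
    serial-sampled animals.
    """

    plasma_times: list
    microdialysis_windows: list
    dose_mg_kg: float
    route: str = "IV"
    n_animals: int = 8
    destructive: bool = False
    animals_per_time: int = 3
    n_microdialysis_animals: int = 6
    body_weight_kg: float = 0.025
    recovery_factor: float = 1.0  # microdialysis probe relative recovery
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        windows = sorted(self.microdialysis_windows)
        for (s1, e1), (s2, e2) in zip(windows[:-1], windows[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping microdialysis windows {s1, e1} / {s2, e2}")
        for s, e in windows:
            if e <= s or s < 0:
                raise ValueError(f"invalid microdialysis window ({s}, {e})")


@dataclass
class GroundTruth:
    """Generating model: everything needed to rebuild the data-generating process."""

    plasma_model: object
    drug: object
    physiology: object
    kpuu: float
    ecf_residual: dict = field(default_factory=lambda: {"prop_var": 0.0, "add_var": 0.0})

    def as_dict(self):
        return {
            "kpuu": self.kpuu,
            "p_trans": self.drug.p_trans,
            "plasma_CL": self.plasma_model.CL,
            "plasma_Vc": self.plasma_model.Vc,
            "plasma_iiv": dict(self.plasma_model.iiv),
            "plasma_residual": dict(self.plasma_model.residual),
            "ecf_residual": dict(self.ecf_residual),
        }


def interval_average(curve, window):
    """Time-average of a concentration curve over a collection window.

    ``curve`` is either a callable t -> conc or a ``(times, values)`` pair
    (interpolated monotone-cubically). The average is computed by adaptive
    quadrature.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    if callable(curve):
        fn = curve
        lo, hi = -math.inf, math.inf
    else:
        t, v = curve
        t = np.asarray(t, float)
        v = np.asarray(v, float)
        fn = PchipInterpolator(t, v)
        lo, hi = t[0], t[-1]
    if start < lo or end > hi:
        raise ValueError(f"window ({start}, {end}) outside curve range [{lo}, {hi}]")
    integral, _ = quad(fn, start, end, limit=200)
    return integral / (end - start)


def _plasma_observations(truth, design, rng):
    model = truth.plasma_model
    amount = design.dose_mg_kg * design.body_weight_kg * NG_PER_MG
    doses = [DoseEvent(amount_ng=amount, time_min=0.0, route=design.route)]
    rows = []
    if design.destructive:
        animal = 0
        for t in design.plasma_times:
            for _ in range(design.animals_per_time):
                sub = _individual_model(model, rng)
                amounts = solve_amounts(sub, doses, np.array([t], float))
                pred = amounts[0, IDX_CENTRAL] / sub.Vc
                obs = add_residual_error(np.array([pred]), model.residual, rng=rng)[0]
                rows.append((f"P{animal:03d}", float(t), "plasma", float(obs)))
                animal += 1
    else:
        times = np.asarray(design.plasma_times, float)
        for animal in range(design.n_animals):
            sub = _individual_model(model, rng)
            amounts = solve_amounts(sub, doses, times)
            pred = amounts[:, IDX_CENTRAL] / sub.Vc
            obs = add_residual_error(pred, model.residual, rng=rng)
            rows.extend(
                (f"P{animal:03d}", float(t), "plasma", float(o))
                for t, o in zip(times, obs)
            )
    return rows, doses


def _ecf_observations(truth, design, doses, rng):
    af = asymmetry_factors(truth.kpuu)
    windows = sorted(design.microdialysis_windows)
    t_end = max(e for _, e in windows)
    rows = []
    for animal in range(design.n_microdialysis_animals):
        sub = _individual_model(truth.plasma_model, rng)
        forcing = Forcing(sub, doses, t_end=t_end * 1.0001)
        model = build_cns_model(truth.physiology, truth.drug, af, forcing)
        grid = np.linspace(0.0, t_end, 481)
        grid = np.union1d(grid, np.array([w for pair in windows for w in pair]))
        result = simulate_cns(model, t_end=t_end, t_eval=grid, rtol=1e-8)
        curve = (result.times, result.ecf())
        for start, end in windows:
            pred = interval_average(curve, (start, end)) * design.recovery_factor
            obs = add_residual_error(np.array([pred]), truth.ecf_residual, rng=rng)[0]
            mid = 0.5 * (start + end)
            rows.append((f"M{animal:03d}", float(mid), "brain_ecf", float(obs)))
    return rows


def generate_study(truth, design, lloq_ng_ml=0.0):
    """Generate a complete synthetic study dataset.

    Returns ``(StudyDataset, truth_record_dict)``; fully reproducible from
    ``design.seed``. Observations below ``lloq_ng_ml`` are flagged BQL.
    """
    rng = np.random.default_rng(design.seed)
    plasma_rows, doses = _plasma_observations(truth, design, rng)
    ecf_rows = _ecf_observations(truth, design, doses, rng)

    obs = pd.DataFrame(
        plasma_rows + ecf_rows, columns=["id", "time_min", "matrix", "conc_ng_ml"]
    )
    obs["bql"] = ((obs["conc_ng_ml"] < lloq_ng_ml) | (obs["conc_ng_ml"] <= 0)).astype(int)

    dose_rows = [
        (sid, 0.0, design.dose_mg_kg, design.route) for sid in obs["id"].unique()
    ]
    dose_df = pd.DataFrame(dose_rows, columns=["id", "time_min", "dose_mg_kg", "route"])
    dataset = StudyDataset(observations=obs, doses=dose_df)

    record = truth.as_dict()
    record["seed"] = design.seed
    record["design"] = {
        "plasma_times": list(design.plasma_times),
        "microdialysis_windows": [list(w) for w in design.microdialysis_windows],
        "dose_mg_kg": design.dose_mg_kg,
        "route": design.route,
        "body_weight_kg": design.body_weight_kg,
        "recovery_factor": design.recovery_factor,
    }
    return dataset, record
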