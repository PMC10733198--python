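"""Long-format study datasets: observations + dosing records.

CSV schemas
-----------
observations: ``id, time_min, matrix, conc_ng_ml, bql`` with
``matrix in {plasma, brain_ecf}`` and ``bql in {0, 1}``.
doses: ``id, time_min, dose_mg_kg, route``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["StudyDataset", "MATRICES", "ROUTES", "NG_PER_MG"]

MATRICES = ("plasma", "brain_ecf")
ROUTES = ("IV", "IP", "PO", "SC")
NG_PER_MG = 1e6

OBS_COLUMNS = ["id", "time_min", "matrix", "conc_ng_ml", "bql"]
DOSE_COLUMNS = ["id", "time_min", "dose_mg_kg", "route"]


@dataclass
class StudyDataset:
    """Observations and dosing records for one study."""

    observations: pd.DataFrame
    doses: pd.DataFrame

    def __post_init__(self):
        self.observations = self.observations.reindex(columns=OBS_COLUMNS)
        self.doses = self.doses.reindex(columns=DOSE_COLUMNS)
        self.validate()

    def validate(self):
        obs, doses = self.observations, self.doses
        if obs[["id", "time_min", "matrix"]].isna().any().any():
            raise ValueError("observations contain missing id/time/matrix")
        bad = set(obs["matrix"]) - set(MATRICES)
        if bad:
            raise ValueError(f"unknown matrix values: {sorted(bad)}")
        if not set(obs["bql"].fillna(0).astype(int)) <= {0, 1}:
            raise ValueError("bql must be 0 or 1")
        if (obs["time_min"] < 0).any() or (doses["time_min"] < 0).any():
            raise ValueError("negative times")
        bad = set(doses["route"]) - set(ROUTES)
        if bad:
            raise ValueError(f"unknown routes: {sorted(bad)}")
        if (doses["dose_mg_kg"] <= 0).any():
            raise ValueError("doses must be positive")

    # -- convenience -------------------------------------------------------

    def subset(self, matrix, include_bql=False):
        obs = self.observations
        obs = obs[obs["matrix"] == matrix]
        if not include_bql:
            obs = obs[obs["bql"].fillna(0).astype(int) == 0]
        return obs

    def doses_for(self, subject_id):
        return self.doses[self.doses["id"] == subject_id]

    def dose_amounts_ng(self, subject_id, body_weight_kg):
        """(time_min, amount_ng, route) tuples for one subject."""
        rows = self.doses_for(subject_id)
        return [
            (float(r.time_min), float(r.dose_mg_kg) * body_weight_kg * NG_PER_MG, r.route)
            for r in rows.itertuples()
        ]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, obs_path, dose_path):
        self.observations.to_csv(obs_path, index=False)
        self.doses.to_csv(dose_path, index=False)

    @classmethod
    def from_csv(cls, obs_path, dose_path):
        obs = pd.read_csv(obs_path)
        doses = pd.read_csv(dose_path)
        return cls(observations=obs, doses=doses)
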