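import numpy as np
import pandas as pd
import pytest

from cnspk.bbb import load_kpuu
from cnspk.dataset import StudyDataset
from cnspk.drugs import DrugRecord, load_drugs
from cnspk.physiology import mouse_registry
from cnspk.plasma import DoseEvent, PlasmaPKModel, load_plasma_models


@pytest.fixture(scope="session")
def mouse_reg():
    return mouse_registry()


@pytest.fixture(scope="session")
def drug_records():
    return load_drugs()


@pytest.fixture(scope="session")
def plasma_models():
    return load_plasma_models()


@pytest.fixture(scope="session")
def kpuu_records():
    return load_kpuu()


@pytest.fixture
def neutral_drug():
    """A drug with no ionizable group in the physiological window."""
    return DrugRecord(
        name="neutraline", mwt=300.0, logp=-4.0, fu_plasma=1.0, p_trans=2e-3
    )


@pytest.fixture
def base_drug():
    """Monoprotic base, pKa 9, negligible nonspecific binding."""
    return DrugRecord(
        name="basaline",
        mwt=300.0,
        logp=-4.0,
        pka_base=[9.0],
        fu_plasma=1.0,
        p_trans=2e-3,
    )


@pytest.fixture
def simple_iv_model():
    return PlasmaPKModel(name="simple", CL=1.0, Vc=10.0)


@pytest.fixture
def iv_bolus():
    return [DoseEvent(amount_ng=1000.0)]


def make_plasma_dataset(model, doses, times, n_subjects, dose_mg_kg, route,
                        seed, body_weight_kg=0.025):
    """Simulate a serial-sampling plasma dataset in the study CSV schema."""
    from cnspk.plasma import add_residual_error, simulate_plasma

    rng = np.random.default_rng(seed)
    sim = simulate_plasma(model, doses, times, n_subjects=n_subjects, rng=rng)
    rows = []
    for i in range(n_subjects):
        obs = add_residual_error(sim.total[i], model.residual, rng=rng)
        rows.extend(
            {"id": f"S{i}", "time_min": t, "matrix": "plasma",
             "conc_ng_ml": o, "bql": 0}
            for t, o in zip(times, obs)
        )
    dose_rows = [
        {"id": f"S{i}", "time_min": 0.0, "dose_mg_kg": dose_mg_kg, "route": route}
        for i in range(n_subjects)
    ]
    return StudyDataset(pd.DataFrame(rows), pd.DataFrame(dose_rows))
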