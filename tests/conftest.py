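import numpy as np
import pytest

from beamcea import SimulationConfig, apply_dropout, generate_trial
from beamcea.trial_data import CostLedger, ParticipantRecord, TrialDataset


def make_record(
    pid: str,
    arm: str,
    age: float = 50.0,
    mcs=(45.0, 47.0, 49.0),
    eq5d=(0.7, 0.72, 0.74),
    costs: float = 100.0,
    completed: bool = True,
) -> ParticipantRecord:
    """Fully observed record with flat per-component costs."""
    ledger = CostLedger.empty()
    for w in ledger.windows:
        for c in ("primary_care", "medications", "hospital", "social_care"):
            ledger.set(w, c, costs)
    return ParticipantRecord(
        participant_id=pid,
        arm=arm,
        age=age,
        sex="female",
        mcs=dict(zip(("week0", "week12", "week24"), mcs)),
        pcs=dict(zip(("week0", "week12", "week24"), mcs)),
        eq5d=dict(zip(("month0", "month3", "month6"), eq5d)),
        costs=ledger,
        completed_week24=completed,
        sessions_structured=10,
        sessions_education=5,
        minutes_structured=300.0,
    )


def make_dataset(n_per_arm: int = 4, rng: np.random.Generator | None = None) -> TrialDataset:
    rng = rng or np.random.default_rng(0)
    records = []
    for arm in ("intervention", "control"):
        for i in range(n_per_arm):
            base = float(rng.normal(45, 10))
            records.append(
                make_record(
                    f"{arm[:1]}{i}",
                    arm,
                    age=float(rng.uniform(30, 70)),
                    mcs=(base, base + rng.normal(0, 3), base + rng.normal(0, 3)),
                    eq5d=(min(1.0, float(rng.normal(0.7, 0.2))),
                          min(1.0, float(rng.normal(0.7, 0.2))),
                          min(1.0, float(rng.normal(0.7, 0.2)))),
                    costs=float(rng.gamma(2, 50)),
                )
            )
    return TrialDataset(records=records)


@pytest.fixture
def toy_dataset() -> TrialDataset:
    return make_dataset(4)


@pytest.fixture(scope="session")
def default_trial() -> TrialDataset:
    """Default-config synthetic trial with dropout applied (340 records)."""
    cfg = SimulationConfig()
    return apply_dropout(generate_trial(cfg), cfg)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()
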