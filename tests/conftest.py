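import numpy as np
import pandas as pd
import pytest

from emometa.simulate import SimConfig, simulate_2afc_experiment, simulate_rating_experiment


def make_rating_trials(ratings_by_participant, session=1):
    """Small rating-design table from {pid: dict of column -> list} specs."""
    rows = []
    for pid, cols in ratings_by_participant.items():
        n = len(next(iter(cols.values())))
        defaults = {  # every parameter varies by default
            "valence": [(30 + 7 * i) % 101 for i in range(n)],
            "arousal": [(60 + 13 * i) % 101 for i in range(n)],
            "valence_confidence": list(range(1, n + 1)),
            "arousal_confidence": [1 + (3 * i) % 100 for i in range(n)],
            "others_valence": [(40 + 11 * i) % 101 for i in range(n)],
            "others_arousal": [(45 + 17 * i) % 101 for i in range(n)],
            "familiarity": [(5 * i + 2) % 101 for i in range(n)],
        }
        defaults.update(cols)
        for i in range(n):
            rows.append(
                {
                    "participant_id": pid,
                    "session": session,
                    "stimulus_id": f"s{i + 1:03d}",
                    **{c: v[i] for c, v in defaults.items()},
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rating_trials():
    return make_rating_trials(
        {
            "p1": {"valence": [70, 40, 55, 20, 90], "others_valence": [60, 45, 50, 30, 80]},
            "p2": {"valence": [30, 45, 90, 60, 10], "others_valence": [35, 50, 85, 55, 20]},
        }
    )


@pytest.fixture
def stimulus_meta():
    rows = []
    classes = [("high", "high"), ("high", "low"), ("low", "low"), ("low", "high")]
    for i in range(8):
        v, a = classes[i % 4]
        rows.append(
            {
                "stimulus_id": f"s{i + 1:03d}",
                "database": "IAPS",
                "db_valence": 7.0 if v == "high" else 3.0,
                "db_arousal": 6.5 if a == "high" else 2.5,
                "valence_class": v,
                "arousal_class": a,
                "category": ("HV" if v == "high" else "LV") + ("HA" if a == "high" else "LA"),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def afc_trials(stimulus_meta):
    rows = []
    rng = np.random.default_rng(0)
    for pid in ("p1", "p2"):
        for _, s in stimulus_meta.iterrows():
            rows.append(
                {
                    "participant_id": pid,
                    "session": 1,
                    "stimulus_id": s["stimulus_id"],
                    "valence_response": "pleasant" if s["valence_class"] == "high" else "unpleasant",
                    "arousal_response": s["arousal_class"],
                    "valence_confidence": int(rng.integers(1, 101)),
                    "arousal_confidence": int(rng.integers(1, 101)),
                    "familiarity": int(rng.integers(0, 101)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_rating_sim():
    cfg = SimConfig(n_participants=12, n_stimuli=40, seed=123)
    return simulate_rating_experiment(cfg)


@pytest.fixture(scope="session")
def small_afc_sim():
    cfg = SimConfig(n_participants=8, n_stimuli=40, sigma_m=0.5, seed=321)
    return simulate_2afc_experiment(cfg)
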