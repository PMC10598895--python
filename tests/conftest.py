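import numpy as np
import pytest

from gadas import DEFAULT_CONFIG, default_spec_from_table1, validate_record

#: the favourable reference patient: full glottic exposure by construction
FAVOURABLE = dict(
    sex="male",
    age=40,
    height=170,
    weight=75,
    mouth_opening=4.5,
    mallampati=1,
    thyromental=9.0,
    head_up_grade=1,
    tongue_thickness=5.0,
    hyomental=5.5,
    tmj_rom=15.0,
    small_mandible=False,
)


def make_record(**overrides):
    """Favourable reference patient with selected fields overridden."""
    raw = dict(FAVOURABLE)
    raw.update(overrides)
    return validate_record(raw)


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def table1_spec():
    return default_spec_from_table1()


@pytest.fixture(scope="session")
def favourable_record():
    return make_record()


def random_records(n, seed):
    """Plausible random patients spanning the clinical measurement ranges."""
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n):
        recs.append(
            make_record(
                sex=("male", "female")[int(rng.integers(0, 2))],
                height=float(rng.uniform(145, 195)),
                mouth_opening=float(rng.uniform(2.0, 6.5)),
                thyromental=float(rng.uniform(4.5, 10.5)),
                hyomental=float(rng.uniform(3.0, 7.0)),
                tongue_thickness=float(rng.uniform(4.0, 8.5)),
                tmj_rom=float(rng.uniform(0.0, 25.0)),
                head_up_grade=int(rng.integers(1, 5)),
                small_mandible=bool(rng.random() < 0.1),
            )
        )
    return recs
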