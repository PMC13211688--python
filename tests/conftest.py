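from datetime import date

import pytest

from ecotransfer.datamodel import AnimalRecord, CohortDataset, Measurement


def make_animal(animal_id="W1", **kw):
    defaults = dict(
        animal_id=animal_id,
        sampling_date=date(2017, 5, 17),
        latitude=44.7,
        longitude=15.7,
        region="Central",
        age_years=2.0,
        sex="female",
        body_mass_kg=36.4,
        body_length_cm=120.0,
    )
    defaults.update(kw)
    return AnimalRecord(**defaults)


@pytest.fixture
def tiny_cohort():
    """Three animals, Cs-137 in muscle and heart, with hand-friendly values."""
    animals = [make_animal(f"W{i}") for i in (1, 2, 3)]
    values = {
        ("W1", "muscle"): 40.0,
        ("W1", "heart"): 20.0,
        ("W2", "muscle"): 10.0,
        ("W2", "heart"): 8.0,
        ("W3", "muscle"): 20.0,
        ("W3", "heart"): 5.0,
    }
    measurements = [
        Measurement(aid, tissue, "Cs137", v, "Bq/kg", "dry")
        for (aid, tissue), v in values.items()
    ]
    return CohortDataset(animals, measurements)
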