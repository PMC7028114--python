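import pytest

from chloroprene_iur.bioassay import AnimalRecord, TumorContext
from chloroprene_iur.independence import reconstruct_fourfold
from chloroprene_iur.simulate import default_ntp_design, simulate_bioassay


def make_record(
    animal_id="a1",
    group="g",
    conc=0.0,
    dose=0.0,
    time=104.0,
    tumor=False,
    context=TumorContext.INCIDENTAL,
):
    return AnimalRecord(
        animal_id=animal_id,
        group_label=group,
        external_conc=conc,
        internal_dose=dose,
        death_time=time,
        tumor_present=tumor,
        context=context,
    )


# A small deterministic two-group dataset with hand-checkable likelihood
# terms: doses 0 and 1, death times 52 or 104 weeks.
TOY_TABLE = [
    # (animal_id, dose, time, tumor)
    ("c1", 0.0, 104.0, 0),
    ("c2", 0.0, 104.0, 0),
    ("c3", 0.0, 104.0, 1),
    ("c4", 0.0, 52.0, 0),
    ("c5", 0.0, 52.0, 0),
    ("c6", 0.0, 104.0, 0),
    ("d1", 1.0, 104.0, 1),
    ("d2", 1.0, 104.0, 1),
    ("d3", 1.0, 104.0, 0),
    ("d4", 1.0, 52.0, 1),
    ("d5", 1.0, 52.0, 0),
    ("d6", 1.0, 104.0, 1),
]


@pytest.fixture
def toy_records():
    return [
        make_record(animal_id=a, group=f"{d:g}", conc=d, dose=d, time=t, tumor=bool(y))
        for a, d, t, y in TOY_TABLE
    ]


@pytest.fixture(scope="session")
def simulated_bioassay():
    """One default NTP-style simulated bioassay (4 x 50, seed 7)."""
    return simulate_bioassay(default_ntp_design(seed=7))


@pytest.fixture(scope="session")
def liver_lung_table():
    """Liver vs lung fourfold table reconstructed from the female-mouse
    marginals (200 animals, 96 liver, 108 lung, 61 with both)."""
    return reconstruct_fourfold(200, 96, 108, 61)
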