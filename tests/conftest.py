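import datetime as dt

import pytest

from amubench.ddd_catalog import AgeCategory, DDDCatalog, DDDEntry
from amubench.journal import FarmCensus, TreatmentRecord

APP = dt.date(2019, 3, 1)


def make_record(
    event_id="E1",
    farm_id="F1",
    age_category=AgeCategory.WEANED_PIGLET,
    substances=(("amoxicillin", 5000.0),),
    n_animals=20,
    n_days=3,
    application_date=APP,
    lag_days=1,
):
    return TreatmentRecord(
        event_id=event_id,
        farm_id=farm_id,
        age_category=age_category,
        substances=tuple(substances),
        n_animals=n_animals,
        n_days=n_days,
        application_date=application_date,
        entry_date=application_date + dt.timedelta(days=lag_days),
    )


@pytest.fixture
def catalog():
    return DDDCatalog(
        {
            "amoxicillin": DDDEntry(20.0, "penicillins"),
            "doxycycline": DDDEntry(10.0, "tetracyclines"),
            "colistin": DDDEntry(5.0, "polypeptides"),
        }
    )


@pytest.fixture
def census():
    return FarmCensus(
        counts={
            ("F1", AgeCategory.WEANED_PIGLET): 2000,
            ("F1", AgeCategory.FATTENING_PIG): 1050,
            ("F2", AgeCategory.WEANED_PIGLET): 500,
        }
    )
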