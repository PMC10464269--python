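import numpy as np
import pandas as pd
import pytest

from actimet.accel import EPOCHS_PER_MINUTE, ALL_LABELS, EpochStream
from actimet.synthetic import CohortConfig, generate_cohort

CODE = {lab: i for i, lab in enumerate(ALL_LABELS)}


def stream_from_minutes(minute_labels, participant_id="P1", start="2021-03-01"):
    """EpochStream with 12 identical epochs per listed minute label."""
    codes = np.repeat([CODE[lab] for lab in minute_labels], EPOCHS_PER_MINUTE).astype(np.int8)
    return EpochStream(participant_id, pd.Timestamp(start), codes)


def day_table(rows, participant_id="P1"):
    """DailyActivityMinutes-style frame from dicts of label minutes.

    Each row dict may give a ``date`` (default consecutive weekdays from a
    Monday) and label minutes; unstated labels get 0 and lying absorbs any
    shortfall to 1440.
    """
    base = pd.Timestamp("2021-03-01")  # a Monday
    records = []
    for i, row in enumerate(rows):
        row = dict(row)
        date = pd.Timestamp(row.pop("date", base + pd.Timedelta(days=i)))
        minutes = {lab: float(row.get(lab, 0.0)) for lab in ALL_LABELS}
        total = sum(minutes.values())
        minutes["lying"] += 1440.0 - total
        records.append(
            {
                "participant_id": participant_id,
                "date": date.date(),
                "is_weekend": date.weekday() >= 5,
                **minutes,
            }
        )
    return pd.DataFrame.from_records(records)


@pytest.fixture(scope="session")
def small_cohort():
    """A small epoch-materialised cohort shared across tests."""
    return generate_cohort(CohortConfig(n_sga=12, n_control=14, seed=7))
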