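from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from feverdq.cohort import reference_cohort
from feverdq.model import DiaryEntry
from feverdq.report import run_pipeline

T0 = datetime(2020, 3, 1, 8, 0)


def entries_at_hours(hours, profile_id="child1", **kwargs):
    """Diary entries at the given hour offsets from a fixed origin."""
    return [
        DiaryEntry(profile_id=profile_id, occurred_at=T0 + timedelta(hours=float(h)), **kwargs)
        for h in hours
    ]


@pytest.fixture(scope="session")
def reference():
    """The reconstructed study cohort (app export, office export)."""
    return reference_cohort()


@pytest.fixture(scope="session")
def reference_report(reference):
    app, office = reference
    return run_pipeline(app, office)
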