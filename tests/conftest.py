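import datetime as dt

import numpy as np
import pytest

from ctdemog import AnimalAnnotation, PhotoRecord
from ctdemog.event_detection import Event, aggregate_events


def ann(cat: str, ident=None, side=None):
    """Annotation from a category label like 'ADM', '1YF', 'JUV', 'UNK'."""
    if cat in ("JUV", "UNK"):
        age, sex = cat, "U"
    else:
        age, sex = cat[:-1], cat[-1]
    return AnimalAnnotation(
        age_class=age,
        sex=sex,
        individual_id=ident,
        side=(side or ("R" if ident else "NONE")),
    )


def record(camera, minutes, image_id, anns=(), day=0):
    """Photo record 'minutes' after 2018-02-01 00:00 (+day days)."""
    t = dt.datetime(2018, 2, 1) + dt.timedelta(days=day, minutes=minutes)
    return PhotoRecord(camera_id=camera, timestamp=t, image_id=image_id,
                       annotations=tuple(anns))


def single_event(cat_lists, camera="C1", start_minutes=600, day=0):
    """One event whose images carry the given per-image category lists."""
    recs = [
        record(camera, start_minutes + i, f"{camera}-{day}-{start_minutes}-{i}",
               [a if isinstance(a, AnimalAnnotation) else ann(a) for a in anns],
               day=day)
        for i, anns in enumerate(cat_lists)
    ]
    return Event(event_id=f"{camera}-{day}-{start_minutes}", camera_id=camera,
                 records=tuple(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def simple_events():
    """Three events: a mixed herd, a solitary male, an unsexed pair."""
    return [
        single_event([["ADM", "ADF", "JUV"], ["ADM", "ADF"]], start_minutes=100),
        single_event([["ADM"]], camera="C2", start_minutes=300),
        single_event([["UNK", "UNK"]], camera="C3", start_minutes=500),
    ]


def aggregate(records, minutes=60):
    return aggregate_events(records, gap=dt.timedelta(minutes=minutes))
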