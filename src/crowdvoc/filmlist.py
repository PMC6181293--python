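"""Film list of the cinema measurement campaign.

The winter 2013/2014 + 2015/2016 campaign measured 11 films over 135
screenings, partitioned into the four FSK age-recommendation classes.
This module encodes that published film/screening-count table so the split
enumeration and metadata arithmetic can be reproduced without the raw
ticket-sales files.
"""

from __future__ import annotations

import pandas as pd

from .io import ScreeningRecord

# (film title, FSK class, number of recorded screenings)
CAMPAIGN_FILMS: tuple[tuple[str, int, int], ...] = (
    ("Help I've shrunk my teacher", 0, 18),
    ("I'm off then", 0, 33),
    ("Buddy", 6, 10),
    ("Walking with Dinosaurs 3D", 6, 12),
    ("The Secret Life of Walter Mitty", 6, 13),
    ("The Starving Games", 12, 2),
    ("Hunger Games: Catching Fire", 12, 8),
    ("Star Wars: The Force Awakens", 12, 34),
    ("The Counselor", 16, 1),
    ("Machete Kills", 16, 1),
    ("Paranormal Activity: Ghost Dimension", 16, 3),
)

#: The two FSK-16 films measured only once; they always share a split side
#: and are evaluated together.
ALWAYS_TOGETHER: frozenset[str] = frozenset({"The Counselor", "Machete Kills"})


def campaign_screening_counts() -> dict[str, int]:
    return {title: n for title, _, n in CAMPAIGN_FILMS}


def campaign_class_totals() -> dict[int, int]:
    totals: dict[int, int] = {}
    for _, fsk, n in CAMPAIGN_FILMS:
        totals[fsk] = totals.get(fsk, 0) + n
    return totals


def campaign_screenings(viewer_count: int = 100) -> list[ScreeningRecord]:
    """Expand the film table into one placeholder record per screening.

    Times and viewer counts are schematic (one screening per evening slot);
    only film identity, class, and screening multiplicity are meaningful —
    which is all the split enumeration uses.
    """
    records = []
    t = pd.Timestamp("2013-12-01 20:00:00")
    i = 0
    for title, fsk, n in CAMPAIGN_FILMS:
        for _ in range(n):
            records.append(ScreeningRecord(
                screening_id=f"C{i:04d}",
                film_title=title,
                age_class=fsk,
                room_id="room1",
                start_time=t,
                end_time=t + pd.Timedelta(minutes=100),
                viewer_count=viewer_count,
            ))
            t += pd.Timedelta(days=1)
            i += 1
    return records
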