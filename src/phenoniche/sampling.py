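"""Temporal pseudoabsence generation and assembly of the labelled dataset.

A temporal pseudoabsence shares an event record's coordinates exactly but
carries a date drawn uniformly at random from the study span, sampling the
environmental conditions available over time at places where the event is
known to occur.  The labelled dataset contrasts these (label 0) with the
event observations (label 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import OccurrenceRecord


@dataclass
class LabeledRecord:
    """A presence (label 1) or temporal-pseudoabsence (label 0) row."""

    record_id: str
    lat: float
    lon: float
    date: Date
    label: int
    pair_id: str  # source event record id; equals record_id for presences

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def generate_pseudoabsences(
    events: Sequence[OccurrenceRecord],
    date_range: tuple[Date, Date],
    n_per: int = 12,
    seed: int = 0,
    collision: str = "allow",
) -> list[LabeledRecord]:
    """Draw ``n_per`` temporal pseudoabsences per event record.

    Dates are i.i.d. uniform over the calendar days of ``date_range``
    (inclusive); coordinates are copied verbatim from the source event.
    Under ``collision="redraw"`` a pseudoabsence landing on its source
    event's exact date is redrawn; the default ``"allow"`` keeps it.
    """
    if n_per < 1:
        raise ValueError("n_per must be >= 1")
    if collision not in ("allow", "redraw"):
        raise ValueError(f"unknown collision policy {collision!r}")
    first, last = date_range
    n_days = (last - first).days + 1
    if n_days < 1:
        raise ValueError("empty date_range")
    if collision == "redraw" and n_days == 1:
        raise ValueError("single-day date_range cannot satisfy the redraw policy")
    rng = np.random.default_rng(seed)
    out: list[LabeledRecord] = []
    for ev in events:
        offsets = rng.integers(0, n_days, size=n_per)
        if collision == "redraw":
            ev_off = (ev.event_date - first).days
            while True:
                clash = offsets == ev_off
                if not clash.any():
                    break
                offsets[clash] = rng.integers(0, n_days, size=int(clash.sum()))
        for j, off in enumerate(offsets):
            out.append(
                LabeledRecord(
                    record_id=f"pa_{ev.record_id}_{j}",
                    lat=ev.lat,
                    lon=ev.lon,
                    date=first + timedelta(days=int(off)),
                    label=0,
                    pair_id=ev.record_id,
                )
            )
    return out


def assemble_labeled(
    events: Sequence[OccurrenceRecord], pseudoabsences: Sequence[LabeledRecord]
) -> list[LabeledRecord]:
    """Presences followed by their pseudoabsences, as one labelled list."""
    rows = [
        LabeledRecord(ev.record_id, ev.lat, ev.lon, ev.event_date, 1, ev.record_id)
        for ev in events
    ]
    rows.extend(pseudoabsences)
    return rows


def labeled_to_frame(rows: Sequence[LabeledRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in rows],
            "pair_id": [r.pair_id for r in rows],
            "lat": [r.lat for r in rows],
            "lon": [r.lon for r in rows],
            "date": [r.date.isoformat() for r in rows],
            "label": [r.label for r in rows],
        }
    )


def frame_to_labeled(df: pd.DataFrame) -> list[LabeledRecord]:
    return [
        LabeledRecord(
            record_id=str(r.record_id),
            lat=float(r.lat),
            lon=float(r.lon),
            date=Date.fromisoformat(str(r.date)[:10]),
            label=int(r.label),
            pair_id=str(r.pair_id),
        )
        for r in df.itertuples()
    ]


def write_labeled_csv(rows: Sequence[LabeledRecord], path: str | Path) -> None:
    labeled_to_frame(rows).to_csv(path, index=False)
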