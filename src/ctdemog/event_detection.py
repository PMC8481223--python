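"""Independent detection events, trapping rate and naive occupancy.

Camera traps fire in bursts, so raw images wildly overcount visits.  The
standard fix is temporal aggregation: within a camera, a photo starts a new
*event* when at least a fixed gap (default 60 minutes) separates it from
the previous photo; shorter gaps extend the current event (rolling-gap
rule, measured from the previous record, not the event start).  All animals
recorded during one event are treated as one herd, and the per-event
composition is a *minimum* group size: for each age-sex category the count
is the larger of (a) the maximum number of that category visible on any
single image and (b) the number of distinct recognised individuals of that
category seen across the event's images.

From events and survey effort the module derives the two standard relative
indices: the trapping rate (events per 100 operational camera-days) and
naive occupancy (fraction of camera sites with at least one detection),
park-wide or restricted to a zone.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass
from functools import cached_property

import pandas as pd

from .records_io import PhotoRecord, SurveyEffort

DEFAULT_GAP = dt.timedelta(minutes=60)


@dataclass(frozen=True)
class Event:
    """An independent detection episode at one camera."""

    event_id: str
    camera_id: str
    records: tuple[PhotoRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("event with no records")
        cams = {r.camera_id for r in self.records}
        if cams != {self.camera_id}:
            raise ValueError("event records span cameras")

    @property
    def start(self) -> dt.datetime:
        return self.records[0].timestamp

    @property
    def end(self) -> dt.datetime:
        return self.records[-1].timestamp

    @cached_property
    def identified_ids(self) -> dict[str, str]:
        """Recognised individuals in this event, mapped to their category.

        If an individual is scored under several categories across images,
        the first non-UNK scoring wins.
        """
        out: dict[str, str] = {}
        for rec in self.records:
            for ann in rec.annotations:
                if ann.individual_id is None:
                    continue
                cur = out.get(ann.individual_id)
                if cur is None or (cur == "UNK" and ann.category != "UNK"):
                    out[ann.individual_id] = ann.category
        return out

    @cached_property
    def composition(self) -> dict[str, int]:
        """Minimum-group-size composition (see module docstring)."""
        max_simul: dict[str, int] = defaultdict(int)
        for rec in self.records:
            per_image: dict[str, int] = defaultdict(int)
            for ann in rec.annotations:
                per_image[ann.category] += 1
            for cat, n in per_image.items():
                max_simul[cat] = max(max_simul[cat], n)
        ids_per_cat: dict[str, int] = defaultdict(int)
        for cat in self.identified_ids.values():
            ids_per_cat[cat] += 1
        cats = set(max_simul) | set(ids_per_cat)
        return {c: max(max_simul.get(c, 0), ids_per_cat.get(c, 0)) for c in sorted(cats)}

    @property
    def group_size(self) -> int:
        return sum(self.composition.values())

    @property
    def n_images(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DetectionSummary:
    """Trapping rate and naive occupancy over one scope (park or zone)."""

    scope: str
    n_events: int
    effort_days: int
    n_sites: int
    n_detected_sites: int

    @property
    def trapping_rate(self) -> float:
        if self.effort_days <= 0:
            raise ValueError("no effort")
        return 100.0 * self.n_events / self.effort_days

    @property
    def naive_occupancy(self) -> float:
        return self.n_detected_sites / self.n_sites


def aggregate_events(records, gap: dt.timedelta = DEFAULT_GAP) -> list[Event]:
    """Split per-camera photo streams into independent events.

    ``records`` must already be sorted by time within each camera (readers
    guarantee this); unsorted input is an error rather than silently
    re-sorted.  A record opens a new event iff its timestamp is >= ``gap``
    after the previous record at the same camera — so two photos exactly
    ``gap`` apart fall in different events.
    """
    if gap <= dt.timedelta(0):
        raise ValueError("gap must be positive")
    by_camera: dict[str, list[PhotoRecord]] = defaultdict(list)
    for rec in records:
        stream = by_camera[rec.camera_id]
        if stream and rec.timestamp < stream[-1].timestamp:
            raise ValueError(
                f"records for camera {rec.camera_id!r} not sorted by time "
                f"({rec.image_id} before {stream[-1].image_id})"
            )
        stream.append(rec)
    events: list[Event] = []
    for camera_id in sorted(by_camera):
        chunk: list[PhotoRecord] = []
        for rec in by_camera[camera_id]:
            if chunk and rec.timestamp - chunk[-1].timestamp >= gap:
                events.append(_make_event(camera_id, chunk, len(events)))
                chunk = []
            chunk.append(rec)
        if chunk:
            events.append(_make_event(camera_id, chunk, len(events)))
    events.sort(key=lambda e: (e.start, e.camera_id))
    return [
        Event(event_id=f"E{i:04d}", camera_id=e.camera_id, records=e.records)
        for i, e in enumerate(events, start=1)
    ]


def _make_event(camera_id, chunk, k) -> Event:
    return Event(event_id=f"tmp{k}", camera_id=camera_id, records=tuple(chunk))


def event_composition(event: Event) -> dict[str, int]:
    """Per-category minimum counts for one event (see :class:`Event`)."""
    return event.composition


def trapping_rate(n_events: int, effort: SurveyEffort | int) -> float:
    """Events per 100 operational camera-days."""
    days = effort if isinstance(effort, int) else effort.total_days
    if days <= 0:
        raise ValueError("trapping_rate: zero effort")
    return 100.0 * n_events / days


def naive_occupancy(detected_sites: set, all_sites: set) -> float:
    """Fraction of camera sites with >= 1 detection (no detectability correction)."""
    if not all_sites:
        raise ValueError("naive_occupancy: no sites")
    stray = set(detected_sites) - set(all_sites)
    if stray:
        raise ValueError(f"detected sites not in site list: {sorted(stray)}")
    return len(set(detected_sites)) / len(set(all_sites))


def zone_summary(events, effort: SurveyEffort, deployments, zone: str | None = None) -> DetectionSummary:
    """Detection summary park-wide (``zone=None``) or for one named zone."""
    if zone is None:
        cams = {d.camera_id for d in deployments}
        scope = "park"
    else:
        cams = {d.camera_id for d in deployments if d.zone == zone}
        if not cams:
            raise ValueError(f"unknown zone {zone!r}")
        scope = zone
    zone_events = [ev for ev in events if ev.camera_id in cams]
    detected = {ev.camera_id for ev in zone_events}
    return DetectionSummary(
        scope=scope,
        n_events=len(zone_events),
        effort_days=effort.camera_days(cams),
        n_sites=len(cams),
        n_detected_sites=len(detected),
    )


def events_to_frame(events) -> pd.DataFrame:
    """One row per event: timing, group size, per-category counts, ids."""
    from .demography_vitals import CATEGORIES

    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "camera_id": ev.camera_id,
            "start": ev.start,
            "end": ev.end,
            "n_images": ev.n_images,
            "group_size": ev.group_size,
        }
        for cat in CATEGORIES:
            row[cat] = ev.composition.get(cat, 0)
        row["ids"] = ";".join(sorted(ev.identified_ids))
        rows.append(row)
    return pd.DataFrame(rows)
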