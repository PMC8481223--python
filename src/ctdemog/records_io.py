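"""Photo-record and detector-layout I/O for camera-trap surveys.

The survey data model is deliberately small:

* a :class:`PhotoRecord` is one time-stamped image together with the
  per-animal annotations made on it (age class, sex, optional individual
  identity and which flank was scored);
* a :class:`CameraDeployment` places a camera at planar projected
  coordinates (metres) with a calendar of deployment intervals and the
  subset of days it was actually operational;
* a :class:`SurveyEffort` summarises operational camera-days after the
  "minimum fraction of cameras working" day filter used when computing
  trapping rates.

All timestamps are naive local time; the day boundary is local midnight.
Deployment intervals are half-open ``[start, end)`` dates so adjacent
intervals never double count a day.  CSV is the single interchange format.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

AGE_CLASSES = frozenset({"AD", "2Y", "1Y", "JUV", "UNK"})
SEX_CODES = frozenset({"M", "F", "U"})
SIDE_CODES = frozenset({"L", "R", "BOTH", "NONE"})

PHOTO_COLUMNS = [
    "image_id",
    "camera_id",
    "timestamp",
    "age_class",
    "sex",
    "individual_id",
    "side",
]
DETECTOR_COLUMNS = ["detector_id", "x", "y"]


class RecordValidationError(ValueError):
    """A row in an input table violates the documented schema."""


@dataclass(frozen=True)
class AnimalAnnotation:
    """One animal scored on one image.

    ``age_class`` is one of AD (adult, >= 3 years), 2Y, 1Y, JUV (< 1 year)
    or UNK; ``sex`` is M, F or U (unspecified).  ``individual_id`` is set
    only when the animal was recognised from its coat pattern, in which
    case ``side`` records which flank(s) carried the match.
    """

    age_class: str
    sex: str
    individual_id: str | None = None
    side: str = "NONE"

    def __post_init__(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise RecordValidationError(
                f"unknown age class {self.age_class!r}; allowed: {sorted(AGE_CLASSES)}"
            )
        if self.sex not in SEX_CODES:
            raise RecordValidationError(
                f"unknown sex code {self.sex!r}; allowed: {sorted(SEX_CODES)}"
            )
        if self.side not in SIDE_CODES:
            raise RecordValidationError(
                f"unknown side code {self.side!r}; allowed: {sorted(SIDE_CODES)}"
            )
        if self.individual_id is not None and self.side == "NONE":
            raise RecordValidationError(
                f"annotation with individual_id {self.individual_id!r} must record "
                "the identified side (L, R or BOTH)"
            )

    @property
    def category(self) -> str:
        """Age-sex category label (ADM, ADF, ADU, 2YM, ..., JUV, UNK)."""
        if self.age_class in ("JUV", "UNK"):
            return self.age_class
        return self.age_class + self.sex


@dataclass(frozen=True)
class PhotoRecord:
    """One image: camera, timestamp and the animals annotated on it."""

    camera_id: str
    timestamp: dt.datetime
    image_id: str
    annotations: tuple[AnimalAnnotation, ...] = ()

    @property
    def n_animals(self) -> int:
        return len(self.annotations)


@dataclass
class CameraDeployment:
    """A camera's position and service calendar.

    ``intervals`` are half-open [start, end) date ranges; ``operational_days``
    is the subset of deployed days on which the camera actually worked
    (batteries, card space, vegetation occlusion all cause gaps).
    """

    camera_id: str
    x: float
    y: float
    zone: str | None = None
    intervals: list[tuple[dt.date, dt.date]] = field(default_factory=list)
    operational_days: set[dt.date] = field(default_factory=set)

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise RecordValidationError(
                f"detector {self.camera_id!r}: coordinates must be finite"
            )
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise RecordValidationError(
                    f"detector {self.camera_id!r}: overlapping deployment intervals"
                )
        for s, e in ivs:
            if e <= s:
                raise RecordValidationError(
                    f"detector {self.camera_id!r}: empty interval [{s}, {e})"
                )
        bad = [d for d in self.operational_days if not self.is_deployed(d)]
        if bad:
            raise RecordValidationError(
                f"detector {self.camera_id!r}: operational days outside deployment: "
                f"{sorted(bad)[:3]}..."
            )

    def is_deployed(self, day: dt.date) -> bool:
        return any(s <= day < e for s, e in self.intervals)

    @property
    def deployed_days(self) -> set[dt.date]:
        out: set[dt.date] = set()
        for s, e in self.intervals:
            d = s
            while d < e:
                out.add(d)
                d += dt.timedelta(days=1)
        return out


@dataclass(frozen=True)
class SurveyEffort:
    """Operational effort after the minimum-fraction day filter.

    ``per_camera_days`` maps camera id to its set of retained operational
    days; ``retained_days`` is the calendar-day set that survived the
    filter; ``total_days`` is the grand total of camera-days
    (sum over cameras of retained operational days).
    """

    per_camera_days: dict[str, frozenset[dt.date]]
    retained_days: frozenset[dt.date]
    min_fraction: float

    @property
    def total_days(self) -> int:
        return sum(len(v) for v in self.per_camera_days.values())

    def camera_days(self, camera_ids) -> int:
        """Camera-days restricted to a subset of cameras."""
        return sum(len(self.per_camera_days.get(c, ())) for c in camera_ids)


def _parse_timestamp(text: str, row: int):
    try:
        return dt.datetime.fromisoformat(text)
    except ValueError as exc:
        raise RecordValidationError(
            f"row {row}: malformed timestamp {text!r} (expected ISO-8601)"
        ) from exc


def read_photo_records(path) -> list[PhotoRecord]:
    """Read a photo-record CSV into :class:`PhotoRecord` objects.

    Expected columns: ``image_id,camera_id,timestamp,age_class,sex,
    individual_id,side`` — one row per annotated animal per image; an image
    with no animals is a single row with blank annotation fields.  Unknown
    extra columns are ignored with a warning.  Records are returned sorted
    by ``(camera_id, timestamp)``; duplicate image ids with conflicting
    camera/timestamp are rejected.
    """
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RecordValidationError(f"{path}: empty file, header expected")
        missing = [c for c in PHOTO_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise RecordValidationError(f"{path}: missing columns {missing}")
        extra = [c for c in reader.fieldnames if c not in PHOTO_COLUMNS]
        if extra:
            logger.warning("%s: ignoring unknown columns %s", path, extra)
        for i, row in enumerate(reader, start=2):
            image_id = (row["image_id"] or "").strip()
            if not image_id:
                raise RecordValidationError(f"row {i}: blank image_id")
            ts = _parse_timestamp(row["timestamp"].strip(), i)
            camera = row["camera_id"].strip()
            entry = rows.setdefault(
                image_id, {"camera_id": camera, "timestamp": ts, "annotations": []}
            )
            if entry["camera_id"] != camera or entry["timestamp"] != ts:
                raise RecordValidationError(
                    f"row {i}: image_id {image_id!r} duplicated with conflicting "
                    "camera or timestamp"
                )
            age = (row["age_class"] or "").strip()
            sex = (row["sex"] or "").strip()
            if age or sex:
                try:
                    ann = AnimalAnnotation(
                        age_class=age,
                        sex=sex or "U",
                        individual_id=(row["individual_id"] or "").strip() or None,
                        side=(row["side"] or "").strip() or "NONE",
                    )
                except RecordValidationError as exc:
                    raise RecordValidationError(f"row {i}: {exc}") from exc
                entry["annotations"].append(ann)
    records = [
        PhotoRecord(
            camera_id=e["camera_id"],
            timestamp=e["timestamp"],
            image_id=img,
            annotations=tuple(e["annotations"]),
        )
        for img, e in rows.items()
    ]
    records.sort(key=lambda r: (r.camera_id, r.timestamp, r.image_id))
    return records


def write_photo_records(records, path) -> None:
    """Write records in the same one-row-per-animal CSV schema."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PHOTO_COLUMNS)
        for rec in records:
            ts = rec.timestamp.isoformat()
            if not rec.annotations:
                writer.writerow([rec.image_id, rec.camera_id, ts, "", "", "", ""])
            for ann in rec.annotations:
                writer.writerow(
                    [
                        rec.image_id,
                        rec.camera_id,
                        ts,
                        ann.age_class,
                        ann.sex,
                        ann.individual_id or "",
                        ann.side if ann.individual_id else "",
                    ]
                )


def read_detectors(path) -> list[CameraDeployment]:
    """Read a detector layout CSV (``detector_id,x,y[,zone]``).

    Compatible in spirit with the plain-text trap layout files used by
    spatial capture-recapture software: one detector per row, planar
    coordinates in metres.
    """
    out: list[CameraDeployment] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RecordValidationError(f"{path}: empty file, header expected")
        missing = [c for c in DETECTOR_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise RecordValidationError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            det_id = row["detector_id"].strip()
            if det_id in seen:
                raise RecordValidationError(f"row {i}: duplicate detector id {det_id!r}")
            seen.add(det_id)
            try:
                x, y = float(row["x"]), float(row["y"])
            except ValueError as exc:
                raise RecordValidationError(
                    f"row {i}: non-numeric coordinate for {det_id!r}"
                ) from exc
            zone = (row.get("zone") or "").strip() or None
            out.append(CameraDeployment(camera_id=det_id, x=x, y=y, zone=zone))
    return out


def write_detectors(deployments, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTOR_COLUMNS + ["zone"])
        for d in deployments:
            writer.writerow([d.camera_id, d.x, d.y, d.zone or ""])


def effort_calendar(deployments, min_fraction: float = 0.75) -> SurveyEffort:
    """Apply the "fraction of cameras working" day filter and tally effort.

    A calendar day is retained iff the number of operational cameras that
    day divided by the number of deployed cameras that day is at least
    ``min_fraction``.  Per-camera operational days are then counted over
    retained days only.  With ``min_fraction = 0`` every deployed day is
    retained and the total equals the raw sum of operational days.
    """
    if not deployments:
        raise ValueError("effort_calendar: empty deployment set")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    deployed_count: Counter = Counter()
    operational_count: Counter = Counter()
    for dep in deployments:
        for day in dep.deployed_days:
            deployed_count[day] += 1
        for day in dep.operational_days:
            operational_count[day] += 1
    retained = frozenset(
        day
        for day, n_dep in deployed_count.items()
        if n_dep > 0 and operational_count.get(day, 0) / n_dep >= min_fraction
    )
    per_camera = {
        dep.camera_id: frozenset(dep.operational_days & retained) for dep in deployments
    }
    return SurveyEffort(
        per_camera_days=per_camera, retained_days=retained, min_fraction=min_fraction
    )


def with_operational_days(deployment: CameraDeployment, days) -> CameraDeployment:
    """Return a copy of ``deployment`` with ``operational_days`` replaced."""
    return replace(deployment, operational_days=set(days))
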