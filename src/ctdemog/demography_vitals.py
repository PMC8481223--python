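"""Population tallies, sex ratios, age structure and vital rates.

Animals on camera-trap images are scored into eleven age-sex categories:
ADM, ADF, ADU (adults by sex, U = sex not determined), 2YM/2YF/2YU and
1YM/1YF/1YU (sub-adults), JUV (juveniles, sex rarely determinable) and UNK
(age not determinable at all).  Per-event "minimum group size" compositions
are tallied into :class:`CategoryCounts`, from which the module derives

* sex ratios (overall and adult),
* age structure (percent JUV / 1Y / 2Y / AD, with or without UNK),
* the breeding rate (juveniles per adult female, unsexed adults allocated
  to the sexes in proportion to the sexed adult ratio), and
* annual mortality/survival under a stationary age distribution and equal
  detectability of all classes:

  .. math::

     M_{anJUV} = (N_{JUV} - N_{1Y}) / N_{JUV}

     M_{anADF} = N_{SUBF} (1 - M_{anJUV}) / N_{ADF}, \\qquad
     M_{anADM} = N_{SUBM} (1 - M_{anJUV}) / N_{ADM}

  where :math:`N_{1Y}` pools sexed and unsexed yearlings and
  :math:`N_{SUBF} = N_{2YF} + N_{1YF}` (sexed sub-adults only).

Rounding to printed precision is half-up and applied only at the reporting
layer; internal values keep full precision.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

#: The eleven age-sex categories, in reporting order.
CATEGORIES = (
    "ADM", "ADF", "ADU",
    "2YM", "2YF", "2YU",
    "1YM", "1YF", "1YU",
    "JUV", "UNK",
)

HERD_TYPES = ("MIX", "UNI-M", "UNI-F", "SOLITARY", "UNSEXED")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CategoryCounts:
    """Per-category animal tallies for one survey year (or pooled).

    ``counts`` maps category label to the number of animals recorded;
    ``identified`` maps category label to the number of those that were
    individually recognised.  ``n_events`` is the number of detection
    events the tally is built from (used for per-event means).
    """

    counts: dict[str, int] = field(default_factory=dict)
    identified: dict[str, int] = field(default_factory=dict)
    year: str | None = None
    n_events: int = 0

    def __post_init__(self) -> None:
        for cat in list(self.counts) + list(self.identified):
            if cat not in CATEGORIES:
                raise ValueError(f"unknown age-sex category {cat!r}")
        for cat, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cat}")

    def __getitem__(self, cat: str) -> int:
        if cat not in CATEGORIES:
            raise KeyError(cat)
        return self.counts.get(cat, 0)

    @property
    def total(self) -> int:
        return sum(self[c] for c in CATEGORIES)

    @property
    def n_1y(self) -> int:
        """Yearlings pooled over sexes, incl. unsexed (enters juvenile mortality)."""
        return self["1YM"] + self["1YF"] + self["1YU"]

    @property
    def n_2y(self) -> int:
        return self["2YM"] + self["2YF"] + self["2YU"]

    @property
    def n_ad(self) -> int:
        return self["ADM"] + self["ADF"] + self["ADU"]

    @property
    def n_subm(self) -> int:
        """Sexed male sub-adults (2YM + 1YM)."""
        return self["2YM"] + self["1YM"]

    @property
    def n_subf(self) -> int:
        """Sexed female sub-adults (2YF + 1YF)."""
        return self["2YF"] + self["1YF"]

    def per_event_mean(self, cat: str) -> float:
        if self.n_events == 0:
            raise ValueError("n_events not set")
        return self[cat] / self.n_events

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": CATEGORIES,
                "count": [self[c] for c in CATEGORIES],
                "identified": [self.identified.get(c, 0) for c in CATEGORIES],
            }
        )


@dataclass(frozen=True)
class VitalRates:
    """Breeding rate and annual mortality by class (survival = 1 - M)."""

    breeding_rate: float
    m_juv: float
    m_adf: float
    m_adm: float
    adf_adjusted: float

    @property
    def s_juv(self) -> float:
        return 1.0 - self.m_juv

    @property
    def s_adf(self) -> float:
        return 1.0 - self.m_adf

    @property
    def s_adm(self) -> float:
        return 1.0 - self.m_adm


@dataclass(frozen=True)
class HerdRecord:
    event_id: str
    herd_type: str
    group_size: int

    def __post_init__(self) -> None:
        if self.herd_type not in HERD_TYPES:
            raise ValueError(f"unknown herd type {self.herd_type!r}")
        if (self.herd_type == "SOLITARY") != (self.group_size == 1):
            raise ValueError("SOLITARY iff group_size == 1")


def load_reference_counts(year: str) -> CategoryCounts:
    """Packaged Niokolo Koba herd-composition tallies ('2017' or '2018').

    These are the published per-year totals (animal counts and individually
    recognised counts per category) that the survey arithmetic is checked
    against; 16 events in 2017 and 32 events in 2018 enter per-event means.
    """
    path = resources.files("ctdemog.data") / "niokolo_herd_composition.csv"
    df = pd.read_csv(path, dtype={"year": str})
    sub = df[df["year"] == str(year)]
    if sub.empty:
        raise KeyError(f"no packaged composition for year {year!r}")
    n_events = int(sub["n_events"].iloc[0])
    return CategoryCounts(
        counts=dict(zip(sub["category"], sub["count"].astype(int))),
        identified=dict(zip(sub["category"], sub["id_r"].astype(int))),
        year=str(year),
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# tallies


def tally(events, by_year: bool = False):
    """Sum event compositions into :class:`CategoryCounts`.

    With ``by_year`` returns ``{year: CategoryCounts}`` keyed by the event
    start year; otherwise a single pooled tally.  Identified counts are
    numbers of distinct recognised individuals per category (an individual
    recaptured in several events counts once).
    """
    if not events:
        raise ValueError("tally: no events")

    def _one(evs, label):
        counts: dict[str, int] = defaultdict(int)
        ids_by_cat: dict[str, set] = defaultdict(set)
        for ev in evs:
            for cat, n in ev.composition.items():
                counts[cat] += n
            for ind, cat in ev.identified_ids.items():
                ids_by_cat[cat].add(ind)
        return CategoryCounts(
            counts=dict(counts),
            identified={c: len(s) for c, s in ids_by_cat.items()},
            year=label,
            n_events=len(evs),
        )

    if not by_year:
        return _one(events, None)
    by: dict[str, list] = defaultdict(list)
    for ev in events:
        by[str(ev.start.year)].append(ev)
    return {yr: _one(evs, yr) for yr, evs in sorted(by.items())}


def sex_ratio(counts: CategoryCounts, scope: str = "overall") -> float:
    """Male:female ratio (the female side normalised to 1), half-up to 1 dp.

    ``overall`` pools all sexed animals (AD + 2Y + 1Y); ``adult`` uses
    adults only.
    """
    if scope == "overall":
        males = counts["ADM"] + counts["2YM"] + counts["1YM"]
        females = counts["ADF"] + counts["2YF"] + counts["1YF"]
    elif scope == "adult":
        males, females = counts["ADM"], counts["ADF"]
    else:
        raise ValueError("scope must be 'overall' or 'adult'")
    if females == 0:
        raise ValueError("sex_ratio: no females in scope")
    return round_half_up(males / females, 1)


def age_structure(counts: CategoryCounts, include_unknown: bool = False) -> pd.DataFrame:
    """Percent of the population per age class {JUV, 1Y, 2Y, AD}.

    With ``include_unknown=False`` the UNK row is dropped from the
    denominator (age structure of ageable animals).  Returns a frame with
    the class count, exact percentage and the half-up integer percentage;
    exact percentages sum to 100.
    """
    rows = {
        "JUV": counts["JUV"],
        "1Y": counts.n_1y,
        "2Y": counts.n_2y,
        "AD": counts.n_ad,
    }
    denom = sum(rows.values()) + (counts["UNK"] if include_unknown else 0)
    if denom == 0:
        raise ValueError("age_structure: empty tally")
    df = pd.DataFrame(
        {
            "age_class": list(rows),
            "count": list(rows.values()),
        }
    )
    df["percent"] = 100.0 * df["count"] / denom
    df["percent_rounded"] = [int(round_half_up(p)) for p in df["percent"]]
    return df


def adjusted_adult_females(counts: CategoryCounts) -> float:
    """Adult females after allocating unsexed adults by the adult sex ratio.

    ADU animals are real adults of unknown sex; they are split between the
    sexes in proportion to the sexed adult counts:
    ``ADF + ADU * ADF / (ADM + ADF)``.
    """
    adm, adf, adu = counts["ADM"], counts["ADF"], counts["ADU"]
    if adm + adf == 0:
        raise ValueError("no sexed adults to allocate against")
    return adf + adu * adf / (adm + adf)


def vital_rates(counts: CategoryCounts) -> VitalRates:
    """Breeding rate and annual mortality from a single year's tally.

    Juvenile mortality compares this year's juvenile cohort with the
    yearlings (next class) seen in the same cross-section — valid under a
    stationary age distribution.  Adult mortalities balance the recruitment
    of sexed sub-adults against standing adult numbers.  If more yearlings
    than juveniles were recorded (sampling noise in a small population),
    juvenile mortality is clamped at 0 with a warning.
    """
    n_juv = counts["JUV"]
    if n_juv <= 0:
        raise ValueError("vital_rates: no juveniles recorded")
    if counts["ADM"] <= 0 or counts["ADF"] <= 0:
        raise ValueError("vital_rates: need sexed adults of both sexes")
    n_1y = counts.n_1y
    m_juv = (n_juv - n_1y) / n_juv
    if m_juv < 0:
        logger.warning(
            "more yearlings (%d) than juveniles (%d): clamping juvenile "
            "mortality at 0", n_1y, n_juv,
        )
        m_juv = 0.0
    m_adf = counts.n_subf * (1.0 - m_juv) / counts["ADF"]
    m_adm = counts.n_subm * (1.0 - m_juv) / counts["ADM"]
    adf_adj = adjusted_adult_females(counts)
    return VitalRates(
        breeding_rate=n_juv / adf_adj,
        m_juv=m_juv,
        m_adf=m_adf,
        m_adm=m_adm,
        adf_adjusted=adf_adj,
    )


# ---------------------------------------------------------------------------
# group sizes, herd types, identification


def group_size_stats(events, exclusions: set | None = None) -> dict:
    """Mean, sample SD, range and n of event group sizes.

    ``exclusions`` is an explicit set of event ids dropped before the
    statistics (the published analysis used n = 48 of the recorded events
    without naming the excluded ones, so exclusion is caller-controlled).
    SD is reported as 0.0 when n = 1 (documented convention).
    """
    exclusions = exclusions or set()
    sizes = [ev.group_size for ev in events if ev.event_id not in exclusions]
    if not sizes:
        raise ValueError("group_size_stats: no events after exclusions")
    n = len(sizes)
    mean = sum(sizes) / n
    sd = 0.0 if n == 1 else math.sqrt(sum((s - mean) ** 2 for s in sizes) / (n - 1))
    return {"mean": mean, "sd": sd, "min": min(sizes), "max": max(sizes), "n": n}


def classify_herd(event) -> HerdRecord:
    """Classify an event's herd by its sexed, non-juvenile members.

    Single animals are SOLITARY regardless of sex; herds with both sexes
    present are MIX, single-sex herds UNI-M / UNI-F, and multi-animal herds
    with no sexable member UNSEXED.
    """
    comp = event.composition
    size = event.group_size
    if size == 1:
        return HerdRecord(event.event_id, "SOLITARY", 1)
    males = comp.get("ADM", 0) + comp.get("2YM", 0) + comp.get("1YM", 0)
    females = comp.get("ADF", 0) + comp.get("2YF", 0) + comp.get("1YF", 0)
    if males and females:
        t = "MIX"
    elif males:
        t = "UNI-M"
    elif females:
        t = "UNI-F"
    else:
        t = "UNSEXED"
    return HerdRecord(event.event_id, t, size)


def id_success_rate(events, category: str) -> float:
    """Identified animals / recorded animals in a category, pooled over events."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    total = sum(ev.composition.get(category, 0) for ev in events)
    if total == 0:
        raise ValueError(f"no animals recorded in category {category}")
    identified = sum(
        1
        for ev in events
        for ind, cat in ev.identified_ids.items()
        if cat == category
    )
    return identified / total


def id_success_from_counts(tallies, category: str) -> float:
    """Pooled identification success from per-year tallies.

    Sums identified and recorded animals in ``category`` over the supplied
    :class:`CategoryCounts` and divides.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    total = sum(c[category] for c in tallies)
    if total == 0:
        raise ValueError(f"no animals recorded in category {category}")
    identified = sum(c.identified.get(category, 0) for c in tallies)
    return identified / total


def recapture_summary(events) -> dict:
    """Recapture proportions per identified side and gap-day statistics.

    An individual is a recapture iff it appears in at least two events.
    Gaps are day differences between successive events of the same
    individual, pooled over individuals.
    """
    sightings: dict[str, list] = defaultdict(list)  # id -> [(start, side)]
    for ev in events:
        for rec in ev.records:
            for ann in rec.annotations:
                if ann.individual_id is not None:
                    sightings[ann.individual_id].append((ev.start, ev.event_id, ann.side))
    per_side = {}
    for side in ("L", "R"):
        ids = {
            ind
            for ind, obs in sightings.items()
            if any(s in (side, "BOTH") for _, _, s in obs)
        }
        recaptured = {
            ind for ind in ids if len({eid for _, eid, _ in sightings[ind]}) >= 2
        }
        per_side[side] = {
            "n_individuals": len(ids),
            "n_recaptured": len(recaptured),
            "proportion": len(recaptured) / len(ids) if ids else 0.0,
        }
    gaps: list[int] = []
    for ind, obs in sightings.items():
        starts = sorted({(start, eid) for start, eid, _ in obs})
        for (t0, _), (t1, _) in zip(starts, starts[1:]):
            gaps.append((t1.date() - t0.date()).days)
    gap_stats = {
        "n_gaps": len(gaps),
        "mean_days": sum(gaps) / len(gaps) if gaps else float("nan"),
        "min_days": min(gaps) if gaps else None,
        "max_days": max(gaps) if gaps else None,
    }
    return {"per_side": per_side, "gaps": gap_stats}
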