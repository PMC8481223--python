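"""Generative model of a camera-trap survey of a rare, social ungulate.

Two layers share one configuration:

* an **individual layer** for spatial capture-recapture: home-range
  centres from a 2-D Poisson process over a rectangular region, and
  per-occasion, per-detector Bernoulli detections with probability
  g(distance) — the exact data-generating process the SECR likelihood
  assumes;
* an **event layer** for the descriptive pipeline: detection events placed
  at detectors through time, with trimodal diel timing (a three-component
  von Mises mixture), overdispersed herd sizes (zero-truncated negative
  binomial — the field mean 7.58 with SD 8.90 rules out Poisson),
  multinomial age-sex composition (defaults are the normalised 2018 survey
  proportions), a Nov-Dec birth pulse that concentrates juvenile records
  in the following dry season, and category-dependent individual-ID
  success.  Every camera trigger emits a three-image sequence.

Each generator returns the emitted survey files *and* a truth record of
the parameters and latent states, so pipeline recovery is testable without
any field data.  All draws flow from one integer seed.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .demography_vitals import CATEGORIES
from .records_io import AnimalAnnotation, CameraDeployment, PhotoRecord
from .secr_density import CaptureHistory, DetFnParams, detection_probability

TWO_PI = 2.0 * math.pi

#: Normalised 2018 survey composition (counts /205) over the 11 categories.
DEFAULT_COMPOSITION = {
    "ADM": 30 / 205, "ADF": 32 / 205, "ADU": 12 / 205,
    "2YM": 15 / 205, "2YF": 2 / 205, "2YU": 8 / 205,
    "1YM": 8 / 205, "1YF": 6 / 205, "1YU": 8 / 205,
    "JUV": 48 / 205, "UNK": 36 / 205,
}

#: Identification succeeds mostly for large-bodied classes (adults),
#: rarely for yearlings and juveniles, never for unageable animals.
DEFAULT_ID_SUCCESS = {
    "ADM": 0.40, "ADF": 0.40, "ADU": 0.0,
    "2YM": 0.25, "2YF": 0.25, "2YU": 0.0,
    "1YM": 0.10, "1YF": 0.10, "1YU": 0.05,
    "JUV": 0.05, "UNK": 0.0,
}


@dataclass
class ActivityMixture:
    """Three von Mises components on the 24-h clock."""

    means_hhmm: tuple[str, ...] = ("09:30", "16:30", "23:30")
    kappas: tuple[float, ...] = (2.0, 3.0, 1.5)
    weights: tuple[float, ...] = (0.30, 0.45, 0.25)

    def __post_init__(self) -> None:
        if not (len(self.means_hhmm) == len(self.kappas) == len(self.weights)):
            raise ValueError("mixture components must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def mean_angles(self) -> np.ndarray:
        out = []
        for hhmm in self.means_hhmm:
            h, m = map(int, hhmm.split(":"))
            out.append(TWO_PI * (h * 60 + m) / 1440.0)
        return np.array(out)

    def sample_times(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Seconds since midnight for ``size`` events."""
        comp = rng.choice(len(self.weights), size=size, p=self.weights)
        angles = rng.vonmises(self.mean_angles[comp], np.asarray(self.kappas)[comp])
        return (angles % TWO_PI) / TWO_PI * 86400.0


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic survey."""

    seed: int = 0
    # spatial layer
    region_km: tuple[float, float] = (40.0, 40.0)
    density: float = 0.138                      # animals / km^2
    detfn: DetFnParams = field(
        default_factory=lambda: DetFnParams(kind="HN", g0=0.08, sigma=2000.0))
    n_detectors_side: int = 7                   # square grid, side count
    detector_spacing: float = 2315.0            # metres
    n_occasions: int = 50                       # daily occasions
    # event layer
    survey_start: dt.date = dt.date(2018, 1, 9)
    event_rate_per_detector_day: float = 0.02
    activity: ActivityMixture = field(default_factory=ActivityMixture)
    group_size_mean: float = 7.58
    group_size_sd: float = 8.90
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    id_success: dict = field(default_factory=lambda: dict(DEFAULT_ID_SUCCESS))
    birth_pulse_months: tuple[int, int] = (11, 12)
    images_per_trigger: int = 3
    id_pool_per_category: int = 60              # catalogue size for reused IDs

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        probs = np.array([self.composition.get(c, 0.0) for c in CATEGORIES])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("composition probabilities must sum to 1")
        for c, p in self.id_success.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"id_success[{c}] outside [0, 1]")

    @property
    def area(self) -> float:
        """Region area, km^2."""
        return self.region_km[0] * self.region_km[1]

    @property
    def juvenile_mortality(self) -> float:
        """Juvenile mortality implied by the composition probabilities.

        The cross-sectional tally estimator M = (N_JUV - N_1Y) / N_JUV has
        this as its large-sample target under the configured multinomial.
        """
        p_juv = self.composition["JUV"]
        p_1y = sum(self.composition[c] for c in ("1YM", "1YF", "1YU"))
        return (p_juv - p_1y) / p_juv


# ---------------------------------------------------------------------------
# spatial layer


def detector_grid(config: SimConfig) -> list[CameraDeployment]:
    """Square detector grid centred in the region."""
    m = config.n_detectors_side
    span = (m - 1) * config.detector_spacing
    cx, cy = config.region_km[0] * 500.0, config.region_km[1] * 500.0  # centre, m
    xs = cx - span / 2 + config.detector_spacing * np.arange(m)
    ys = cy - span / 2 + config.detector_spacing * np.arange(m)
    dets = []
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            dets.append(CameraDeployment(camera_id=f"D{j * m + i + 1:03d}",
                                         x=float(x), y=float(y)))
    return dets


def simulate_centres(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Home-range centres: Poisson(D x area) points uniform over the region."""
    rng = rng or np.random.default_rng(config.seed)
    n = rng.poisson(config.density * config.area)
    xy = rng.uniform(0.0, 1.0, size=(n, 2))
    xy[:, 0] *= config.region_km[0] * 1000.0
    xy[:, 1] *= config.region_km[1] * 1000.0
    return xy


def simulate_detections(centres: np.ndarray, detectors, detfn: DetFnParams,
                        n_occasions: int, rng: np.random.Generator,
                        collapse: str | None = "nearest"):
    """Bernoulli detections of each centre at each detector and occasion.

    With ``collapse="nearest"`` an individual detected at several detectors
    on one occasion keeps only the detection nearest its centre, matching
    the one-detection-per-occasion structure of the observed data;
    ``collapse=None`` keeps all (the raw proximity-detector process).
    Returns a :class:`CaptureHistory` of the detected individuals (or None
    if nothing was detected) plus the index of each detected individual in
    ``centres``.
    """
    det_xy = np.array([[d.x, d.y] for d in detectors], dtype=float)
    det_ids = [d.camera_id for d in detectors]
    n_ind = centres.shape[0]
    K = det_xy.shape[0]
    d = np.sqrt(((centres[:, None, :] - det_xy[None, :, :]) ** 2).sum(axis=2))
    g = detection_probability(d, detfn)          # (n_ind, K)
    hits = rng.random((n_ind, n_occasions, K)) < g[:, None, :]
    if collapse == "nearest":
        order = np.argsort(d, axis=1)            # per individual, detectors by distance
        for i in range(n_ind):
            for s in range(n_occasions):
                row = hits[i, s]
                if row.sum() > 1:
                    keep = next(k for k in order[i] if row[k])
                    row[:] = False
                    row[keep] = True
    elif collapse is not None:
        raise ValueError("collapse must be 'nearest' or None")
    detected = np.nonzero(hits.any(axis=(1, 2)))[0]
    if detected.size == 0:
        return None, detected
    ch = CaptureHistory(
        individuals=[f"I{i:04d}" for i in detected],
        occasions=list(range(n_occasions)),
        detector_ids=det_ids,
        detector_xy=det_xy,
        detections=hits[detected].astype(np.int8),
        usage=np.ones((K, n_occasions), dtype=np.int8),
    )
    return ch, detected


def simulate_secr_survey(config: SimConfig):
    """Centres + detections in one call; returns (capture_history, truth)."""
    rng = np.random.default_rng(config.seed)
    detectors = detector_grid(config)
    centres = simulate_centres(config, rng)
    ch, detected = simulate_detections(centres, detectors, config.detfn,
                                       config.n_occasions, rng)
    truth = {
        "density": config.density,
        "n_individuals": int(centres.shape[0]),
        "n_detected": int(detected.size),
        "detfn": asdict(config.detfn),
        "n_occasions": config.n_occasions,
    }
    return ch, detectors, centres, truth


# ---------------------------------------------------------------------------
# event layer


def _sample_group_sizes(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Zero-truncated negative binomial via rejection on the NB(mean, k)."""
    var = sd * sd
    if var <= mean:
        raise ValueError("group-size SD must exceed sqrt(mean) for the NB law")
    k = mean * mean / (var - mean)
    p = k / (k + mean)
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.negative_binomial(k, p, size=2 * (n - filled) + 8)
        draw = draw[draw > 0]
        take = min(draw.size, n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def simulate_photo_records(config: SimConfig):
    """Emit photo records for the full descriptive pipeline, plus truth.

    Events arrive at each detector-day with the configured rate; herd
    sizes, compositions, event clock times and individual identifications
    follow the configured laws.  Juvenile annotations only appear from the
    end of the birth-pulse window onward (calves too small to leave the
    herd's core are not photographed before).  Returns
    ``(records, detectors, truth)`` where truth carries the drawn group
    sizes and event times for oracle-style checks.
    """
    rng = np.random.default_rng(config.seed)
    detectors = detector_grid(config)
    days = [config.survey_start + dt.timedelta(days=i) for i in range(config.n_occasions)]
    arrivals = rng.poisson(config.event_rate_per_detector_day,
                           size=(len(detectors), len(days)))
    n_events = int(arrivals.sum())
    sizes = _sample_group_sizes(rng, n_events, config.group_size_mean,
                                config.group_size_sd)
    seconds = config.activity.sample_times(rng, n_events)
    probs = np.array([config.composition[c] for c in CATEGORIES])

    pulse_end = config.birth_pulse_months[1]
    records: list[PhotoRecord] = []
    truth_events = []
    e = 0
    img = 0
    # identities are spatially local: animals photographed at a camera are
    # drawn from the pool of its neighbourhood (a block ~2 sigma across),
    # so recaptures happen at the same or adjacent cameras as in the field
    block_size = 2.0 * config.detfn.sigma
    local_pool = max(4, config.id_pool_per_category // 10)
    for k, det in enumerate(detectors):
        block = (int(round(det.x / block_size)), int(round(det.y / block_size)))
        for s, day in enumerate(days):
            for _ in range(arrivals[k, s]):
                size = int(sizes[e])
                t0 = dt.datetime.combine(day, dt.time()) + dt.timedelta(
                    seconds=float(seconds[e]))
                cats = list(np.repeat(CATEGORIES, rng.multinomial(size, probs)))
                # no juvenile photos before the birth pulse has ended
                if day.month <= pulse_end and day.month >= config.birth_pulse_months[0]:
                    cats = ["UNK" if c == "JUV" else c for c in cats]
                anns = []
                for c in cats:
                    ident = None
                    side = "NONE"
                    if rng.random() < config.id_success.get(c, 0.0):
                        ident = (f"{c}-{block[0]}_{block[1]}-"
                                 f"{rng.integers(local_pool):03d}")
                        side = "R" if rng.random() < 0.55 else "L"
                    age = c[:-1] if c not in ("JUV", "UNK") else c
                    sex = c[-1] if c not in ("JUV", "UNK") else "U"
                    anns.append(AnimalAnnotation(age_class=age, sex=sex,
                                                 individual_id=ident, side=side))
                for j in range(config.images_per_trigger):
                    img += 1
                    records.append(PhotoRecord(
                        camera_id=det.camera_id,
                        timestamp=t0 + dt.timedelta(seconds=5 * j),
                        image_id=f"IMG{img:06d}",
                        annotations=tuple(anns),
                    ))
                truth_events.append({"camera_id": det.camera_id,
                                     "start": t0.isoformat(),
                                     "group_size": size})
                e += 1
    records.sort(key=lambda r: (r.camera_id, r.timestamp, r.image_id))
    truth = {
        "seed": config.seed,
        "n_events": n_events,
        "group_sizes": [int(x) for x in sizes],
        "juvenile_mortality": config.juvenile_mortality,
        "group_size_mean": config.group_size_mean,
        "events": truth_events,
    }
    return records, detectors, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
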