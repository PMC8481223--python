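"""Scenario life tables for a short age-class ladder (JUV, 1Y, 2Y, AD).

The survey observes cross-sectional class counts but not survival beyond
age two, so two anchored scenarios project recruitment into adulthood from
a reference mortality schedule (annual per-class mortality q_x from an
unpredated comparison population):

* ``JUV+1Y`` — juvenile and yearling counts are taken as observed; the
  two-year-old class is modelled as ``n_1Y * (1 - q_1Y)``;
* ``JUV+2Y`` — juvenile and two-year-old counts are observed; the yearling
  class is interpolated as ``n_JUV * (1 - q_JUV)``.

Annual recruits into adulthood are ``n_2Y * (1 - q_2Y)``.  Under a
stationary age distribution with constant adult survival s, standing adult
numbers satisfy N_AD = recruits / (1 - s); the expected adult stock under
the reference schedule uses s = 1 - q_AD, and inverting the same balance
against the *observed* adult count yields the implied adult survival
``s = 1 - recruits / N_AD``.

Unsexed animals (JUV entirely; 1YU/2YU/ADU partially) can be split between
the sex-specific tables proportionally to the sexed counts, evenly, or
dropped — the published supplementary allocation is not stated, so this is
a configuration choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .demography_vitals import CategoryCounts

logger = logging.getLogger(__name__)

SCENARIOS = ("JUV+1Y", "JUV+2Y")
AGE_CLASSES = ("JUV", "1Y", "2Y", "AD")
ALLOCATIONS = ("proportional", "even", "exclude")


@dataclass(frozen=True)
class MortalitySchedule:
    """Annual per-class mortality q_x by sex, from a reference population."""

    table: pd.DataFrame              # columns: age_class, sex, qx
    source: str = "unspecified"

    def __post_init__(self) -> None:
        t = self.table
        required = {"age_class", "sex", "qx"}
        if not required.issubset(t.columns):
            raise ValueError(f"schedule needs columns {sorted(required)}")
        if t.duplicated(["age_class", "sex"]).any():
            raise ValueError("duplicate (age_class, sex) rows in schedule")
        bad = t[(t["qx"] < 0) | (t["qx"] > 1)]
        if len(bad):
            raise ValueError("qx must lie in [0, 1]")

    def qx(self, age_class: str, sex: str) -> float:
        sub = self.table[(self.table["age_class"] == age_class) &
                         (self.table["sex"] == sex)]
        if sub.empty:
            raise KeyError(f"schedule has no row for ({age_class}, {sex})")
        return float(sub["qx"].iloc[0])

    @classmethod
    def from_csv(cls, path, source: str | None = None) -> "MortalitySchedule":
        return cls(table=pd.read_csv(path), source=source or str(path))


def load_example_schedule() -> MortalitySchedule:
    """Packaged *illustrative* schedule of an unpredated reference herd.

    Synthetic values chosen to be biologically plausible for a large,
    long-lived, unpredated antelope (moderate first-year losses, very low
    sub-adult losses, low adult losses, males slightly above females); they
    stand in for unpublished reference tables and carry no empirical
    authority.
    """
    path = resources.files("ctdemog.data") / "example_mortality_schedule_synthetic.csv"
    return MortalitySchedule.from_csv(path, source="illustrative synthetic schedule")


@dataclass(frozen=True)
class LifeTable:
    scenario: str
    sex: str
    rows: pd.DataFrame               # age_class, n_x, observed, qx, survivors_to_next
    expected_n_ad: float             # adult stock under the reference schedule
    observed_n_ad: float
    implied_adult_survival: float    # from observed adults and modelled recruits
    recruits_per_year: float


def _sex_split(counts: CategoryCounts, sex: str, allocation: str) -> dict[str, float]:
    """Per-class counts attributed to one sex under the chosen allocation."""
    if allocation not in ALLOCATIONS:
        raise ValueError(f"allocation must be one of {ALLOCATIONS}")
    out: dict[str, float] = {}
    for cls, (m_key, f_key, u_key) in {
        "1Y": ("1YM", "1YF", "1YU"),
        "2Y": ("2YM", "2YF", "2YU"),
        "AD": ("ADM", "ADF", "ADU"),
    }.items():
        m, f, u = counts[m_key], counts[f_key], counts[u_key]
        own = m if sex == "M" else f
        if allocation == "exclude" or u == 0:
            share = 0.0
        elif allocation == "even" or m + f == 0:
            share = u / 2.0
        else:
            share = u * own / (m + f)
        out[cls] = own + share
    # juveniles are never sexed in the field: always split evenly (an even
    # calf sex ratio is the standard assumption), even when unsexed older
    # animals are excluded
    out["JUV"] = counts["JUV"] / 2.0
    return out


def build_life_table(counts: CategoryCounts, schedule: MortalitySchedule,
                     scenario: str, sex: str,
                     allocation: str = "proportional") -> LifeTable:
    """Anchor observed classes, project the rest, and close at adulthood."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    obs = _sex_split(counts, sex, allocation)
    if obs["JUV"] <= 0:
        raise ValueError("life table needs a positive juvenile anchor")
    q = {cls: schedule.qx(cls, sex) for cls in AGE_CLASSES}

    n: dict[str, float] = {"JUV": obs["JUV"]}
    observed_flag = {"JUV": True}
    if scenario == "JUV+1Y":
        n["1Y"] = obs["1Y"]
        n["2Y"] = n["1Y"] * (1.0 - q["1Y"])
        observed_flag.update({"1Y": True, "2Y": False})
    else:  # JUV+2Y: interpolate the yearling class from the juvenile anchor
        n["1Y"] = obs["JUV"] * (1.0 - q["JUV"])
        n["2Y"] = obs["2Y"]
        observed_flag.update({"1Y": False, "2Y": True})

    recruits = n["2Y"] * (1.0 - q["2Y"])
    s_ad_ref = 1.0 - q["AD"]
    if q["AD"] <= 0:
        raise ValueError("reference adult mortality must be positive for the "
                         "stationary closure")
    expected_n_ad = recruits / (1.0 - s_ad_ref)
    n["AD"] = expected_n_ad
    observed_flag["AD"] = False

    rows = pd.DataFrame(
        {
            "age_class": AGE_CLASSES,
            "n_x": [n[c] for c in AGE_CLASSES],
            "observed": [observed_flag[c] for c in AGE_CLASSES],
            "qx": [q[c] for c in AGE_CLASSES],
        }
    )
    rows["survivors_to_next"] = rows["n_x"] * (1.0 - rows["qx"])

    observed_n_ad = obs["AD"]
    implied = implied_adult_survival(recruits, observed_n_ad) if observed_n_ad > 0 \
        else float("nan")
    return LifeTable(
        scenario=scenario,
        sex=sex,
        rows=rows,
        expected_n_ad=expected_n_ad,
        observed_n_ad=observed_n_ad,
        implied_adult_survival=implied,
        recruits_per_year=recruits,
    )


def implied_adult_survival(recruits_per_year: float, n_ad: float) -> float:
    """Solve the stationary balance N_AD = recruits / (1 - s) for s.

    s = 1 - recruits / N_AD, clamped to [0, 1).  More recruits than
    standing adults implies zero survival cannot balance the books; the
    value is clamped at 0 with a warning (sampling noise).
    """
    if recruits_per_year <= 0:
        raise ValueError("recruits_per_year must be positive")
    if n_ad <= 0:
        raise ValueError("observed adult count must be positive")
    s = 1.0 - recruits_per_year / n_ad
    if s < 0:
        logger.warning("recruits (%.1f) exceed standing adults (%.1f): "
                       "implied survival clamped at 0", recruits_per_year, n_ad)
        return 0.0
    return min(s, 1.0 - 1e-12)


def life_table_frame(tables: list[LifeTable]) -> pd.DataFrame:
    """Long export: one row per age class per scenario per sex."""
    parts = []
    for t in tables:
        df = t.rows.copy()
        df.insert(0, "sex", t.sex)
        df.insert(0, "scenario", t.scenario)
        df["expected_n_ad"] = t.expected_n_ad
        df["implied_adult_survival"] = t.implied_adult_survival
        parts.append(df)
    return pd.concat(parts, ignore_index=True)
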