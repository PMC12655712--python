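"""Per-dyad lactation measures from 24 h test-weighing feed diaries.

The test-weighing protocol records the infant's weight immediately before
and after every feed, plus any pump-expression weights, for "24 h plus one
feed". From such a diary this module derives:

* 24 h milk production (MP): the sum of all maternal-milk removal volumes
  (breastfeeds and pump expressions) excluding the first (anchor) event,
  rescaled to 24 h by the elapsed time T between the end of the first and
  the end of the last milk-removal event::

      MP = (sum_{i=2..N} v_i) * 24 / T     [T in hours]

* infant intake: breast milk fed directly or as expressed-milk bottles,
  formula intake, and their total, scaled by the same 24/T window;
* growth measures: weight-for-age z-scores (WAZ), the change since birth
  (delta WAZ), average daily weight gain adjusted for the ~8-day neonatal
  regain period, and the formula-to-growth ratio;
* maternal breast-volume change from bra sizes and the derived risk flags
  (overweight, advanced age, minimal breast growth).

Weights are grams throughout; volumes are millilitres via the 1.03 g/mL
milk density. Missing values propagate as ``None``/``NaN`` so that derived
flags are missing exactly when their inputs are.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataQualityWarning,
    DiaryInvalidError,
    InsufficientEventsError,
    InvalidInputError,
)
from .growth import GrowthReference, waz

log = logging.getLogger(__name__)

MILK_DENSITY_G_PER_ML = 1.03
SCALE_TOLERANCE_G = 2.0  # instrument accuracy of the baby scale
CLOTHING_ALLOWANCE_G = 200.0
MIN_BREAST_GROWTH_CM3 = 100.0
OVERWEIGHT_BMI = 25.0
ADVANCED_AGE_YEARS = 35.0
NEONATAL_REGAIN_DAYS = 8
DEFAULT_DIARY_WINDOW_H = (20.0, 30.0)

#: the five LPA indicator columns, in canonical order
INDICATOR_COLUMNS = [
    "mp_24h",
    "total_intake_24h",
    "formula_intake_24h",
    "waz_current",
    "delta_waz",
]

#: candidate maternal risk-factor flags (nullable boolean columns)
RISK_FACTOR_COLUMNS = [
    "ow",
    "advanced_age",
    "gdm",
    "minimal_breast_growth",
    "fertility_issues",
    "thyroid",
    "pcos",
    "nipple_piercing_or_surgery",
    "pph",
    "hdp",
]

#: confounders locked into every risk model
CONFOUNDER_COLUMNS = [
    "age_at_measurement_days",
    "infant_sex",
    "birth_weight_g",
    "birth_mode",
    "primiparous",
]


class FeedKind(str, Enum):
    BREASTFEED = "breastfeed"
    EXPRESSED_BOTTLE = "expressed_bottle"
    FORMULA_BOTTLE = "formula_bottle"
    PUMP_EXPRESSION = "pump_expression"


#: events that remove milk from the breast (enter the MP ledger)
MILK_REMOVAL_KINDS = frozenset({FeedKind.BREASTFEED, FeedKind.PUMP_EXPRESSION})
#: events the infant actually ingests (enter the intake ledger)
INTAKE_KINDS = frozenset(
    {FeedKind.BREASTFEED, FeedKind.EXPRESSED_BOTTLE, FeedKind.FORMULA_BOTTLE}
)


@dataclass(frozen=True)
class FeedEvent:
    """One diary event. Times are minutes from the diary origin."""

    start_time: float
    end_time: float
    kind: FeedKind
    pre_weight_g: Optional[float] = None
    post_weight_g: Optional[float] = None
    breast_side: Optional[str] = None

    def __post_init__(self):
        if not (self.end_time > self.start_time):
            raise InvalidInputError(
                f"event end {self.end_time} not after start {self.start_time}"
            )
        for w in (self.pre_weight_g, self.post_weight_g):
            if w is not None and (not math.isfinite(w) or w < 0):
                raise InvalidInputError(f"weight must be finite and >= 0, got {w}")


@dataclass
class FeedDiary:
    """A time-ordered 24 h + one-feed diary for one dyad."""

    dyad_id: str
    events: Sequence[FeedEvent]
    origin: Optional[str] = None

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.end_time)

    def events_of(self, kinds) -> list[FeedEvent]:
        return [e for e in self.events if e.kind in kinds]

    def elapsed_hours(self) -> float:
        """T of the production formula: end of first to end of last
        milk-removal event, in hours."""
        removal = self.events_of(MILK_REMOVAL_KINDS)
        if len(removal) < 2:
            raise InsufficientEventsError(
                f"diary {self.dyad_id}: need >= 2 milk-removal events, got {len(removal)}"
            )
        return (removal[-1].end_time - removal[0].end_time) / 60.0


class Intakes(NamedTuple):
    breastmilk: float
    formula: float
    total: float


def grams_to_ml(mass_g: float) -> float:
    """Convert a milk mass (g) to volume (mL) at 1.03 g/mL density.

    Negative inputs (scale jitter) clamp to 0 with a data-quality warning.
    """
    if mass_g is None or not math.isfinite(mass_g):
        raise InvalidInputError(f"mass must be finite, got {mass_g}")
    if mass_g < 0:
        warnings.warn(
            f"negative milk mass {mass_g:.1f} g clamped to 0", DataQualityWarning,
            stacklevel=2,
        )
        return 0.0
    return mass_g / MILK_DENSITY_G_PER_ML


def event_volume(e: FeedEvent) -> float:
    """Milk volume (mL) transferred in one event, from the weight difference.

    Negative differences within the 2 g scale tolerance clamp to 0 with a
    warning; larger negatives also clamp but flag a data-quality problem.
    Missing weights raise; callers exclude and log such events.
    """
    if e.pre_weight_g is None or e.post_weight_g is None:
        raise InvalidInputError(f"event lacks pre/post weight: {e}")
    diff = e.post_weight_g - e.pre_weight_g
    if diff < -SCALE_TOLERANCE_G:
        warnings.warn(
            f"weight loss {diff:.1f} g exceeds scale tolerance; clamped to 0",
            DataQualityWarning,
            stacklevel=2,
        )
        return 0.0
    return grams_to_ml(diff)


def _ledger_volumes(diary: FeedDiary, kinds) -> list[tuple[FeedEvent, float]]:
    out = []
    for e in diary.events_of(kinds):
        try:
            out.append((e, event_volume(e)))
        except InvalidInputError:
            log.warning("diary %s: event at t=%.1f excluded (missing weight)",
                        diary.dyad_id, e.end_time)
    return out


def compute_mp_24h(
    diary: FeedDiary, window_h: tuple[float, float] = DEFAULT_DIARY_WINDOW_H
) -> float:
    """24 h milk production (mL/24 h) from the diary.

    Sums breastfeed and pump-expression volumes, excluding the first
    (anchor) milk-removal event, and rescales by 24/T. Formula and
    expressed-milk bottle feeds never enter this ledger.
    """
    entries = _ledger_volumes(diary, MILK_REMOVAL_KINDS)
    if len(entries) < 2:
        raise InsufficientEventsError(
            f"diary {diary.dyad_id}: need >= 2 weighed milk-removal events"
        )
    T = (entries[-1][0].end_time - entries[0][0].end_time) / 60.0
    lo, hi = window_h
    if not (lo <= T <= hi):
        raise DiaryInvalidError(
            f"diary {diary.dyad_id}: span {T:.1f} h outside validity window [{lo}, {hi}] h"
        )
    total = sum(v for _, v in entries[1:])
    return total * 24.0 / T


def compute_intakes(
    diary: FeedDiary, window_h: tuple[float, float] = DEFAULT_DIARY_WINDOW_H
) -> Intakes:
    """Infant breast-milk, formula and total intake (mL/24 h).

    Pump expressions are excluded (milk removed but not ingested here);
    intake events ending at or before the anchor milk-removal event are
    excluded, and the same 24/T window as :func:`compute_mp_24h` scales the
    sums, so the two ledgers cover an identical span.
    """
    removal = _ledger_volumes(diary, MILK_REMOVAL_KINDS)
    if len(removal) < 2:
        raise InsufficientEventsError(
            f"diary {diary.dyad_id}: need >= 2 weighed milk-removal events"
        )
    anchor_end = removal[0][0].end_time
    T = (removal[-1][0].end_time - anchor_end) / 60.0
    lo, hi = window_h
    if not (lo <= T <= hi):
        raise DiaryInvalidError(
            f"diary {diary.dyad_id}: span {T:.1f} h outside validity window [{lo}, {hi}] h"
        )
    bm = 0.0
    formula = 0.0
    for e, v in _ledger_volumes(diary, INTAKE_KINDS):
        if e.end_time <= anchor_end:
            continue
        if e.kind is FeedKind.FORMULA_BOTTLE:
            formula += v
        else:
            bm += v
    scale = 24.0 / T
    bm *= scale
    formula *= scale
    return Intakes(bm, formula, bm + formula)


def infer_naked_weight(
    current_weight_naked: Optional[float], first_prefeed_weight: Optional[float]
) -> Optional[float]:
    """Naked infant weight (g): measured if available, otherwise the first
    pre-feed weight minus a 200 g clothing-and-diaper allowance."""
    if current_weight_naked is not None and not pd.isna(current_weight_naked):
        return float(current_weight_naked)
    if first_prefeed_weight is not None and not pd.isna(first_prefeed_weight):
        return float(first_prefeed_weight) - CLOTHING_ALLOWANCE_G
    return None


def delta_waz(waz_current: Optional[float], waz_birth: Optional[float]) -> Optional[float]:
    """Change in weight-for-age z-score since birth; missing if either is."""
    if waz_current is None or waz_birth is None:
        return None
    if pd.isna(waz_current) or pd.isna(waz_birth):
        return None
    return float(waz_current) - float(waz_birth)


def avg_daily_weight_gain(current_g: float, birth_g: float, age_days: float) -> float:
    """Average daily weight gain (g/day), with 8 days subtracted from the
    infant age to discount the early neonatal loss-and-regain period."""
    from .errors import UndefinedGainError

    if age_days <= NEONATAL_REGAIN_DAYS:
        raise UndefinedGainError(
            f"age {age_days} d is within the {NEONATAL_REGAIN_DAYS}-day regain period"
        )
    return (current_g - birth_g) / (age_days - NEONATAL_REGAIN_DAYS)


def formula_to_growth_ratio(formula_ml: float, gain_g_per_day: float) -> float:
    """Formula volume (mL/24 h) per gram of daily weight gain.

    Zero formula gives 0 regardless of gain. Supplementation with zero or
    negative gain returns +inf: the severest presentation, ranked above all
    finite ratios in ROC analyses.
    """
    if formula_ml == 0:
        return 0.0
    if gain_g_per_day <= 0:
        return math.inf
    return formula_ml / gain_g_per_day


# ---------------------------------------------------------------------------
# breast volume


def load_bra_volume_lookup(path=None) -> pd.DataFrame:
    """Bra (band, cup) -> single-breast volume (cm^3) lookup table.

    Without a path, loads the bundled synthetic placeholder table; supply
    your own CSV (columns band, cup, volume_cm3) to use a published mapping.
    """
    if path is None:
        from importlib import resources

        with resources.files("milksupply.data").joinpath(
            "bra_volume_synthetic.csv"
        ).open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def breast_volume(band, cup, lookup: pd.DataFrame) -> Optional[float]:
    """Breast volume (cm^3) for a bra size, or None if unmapped."""
    if band is None or cup is None or pd.isna(band) or pd.isna(cup):
        return None
    hit = lookup[
        (lookup["band"].astype(str) == str(band))
        & (lookup["cup"].astype(str).str.upper() == str(cup).upper())
    ]
    if hit.empty:
        log.warning("bra size (%s, %s) not in volume lookup", band, cup)
        return None
    return float(hit["volume_cm3"].iloc[0])


def bv_change(bv_pre: Optional[float], bv_post: Optional[float]) -> Optional[float]:
    """Pregnancy change in breast volume (cm^3); missing if either is."""
    if bv_pre is None or bv_post is None or pd.isna(bv_pre) or pd.isna(bv_post):
        return None
    return float(bv_post) - float(bv_pre)


# ---------------------------------------------------------------------------
# cohort-level derivation


def derive_risk_flags(cohort: pd.DataFrame) -> pd.DataFrame:
    """Recompute the threshold-defined risk flags from their source columns.

    ow = BMI >= 25; advanced_age = age >= 35; minimal_breast_growth =
    BV change < 100 cm^3. Each flag is missing (pd.NA) exactly when its
    source is, matching per-variable denominators in descriptive tables.
    """
    out = cohort.copy()

    def _flag(source, predicate):
        vals = out[source]
        flag = pd.array([pd.NA] * len(out), dtype="boolean")
        ok = vals.notna().to_numpy()
        flag[ok] = predicate(vals[ok].astype(float).to_numpy())
        return flag

    out["ow"] = _flag("bmi", lambda v: v >= OVERWEIGHT_BMI)
    out["advanced_age"] = _flag("maternal_age", lambda v: v >= ADVANCED_AGE_YEARS)
    out["minimal_breast_growth"] = _flag(
        "bv_change", lambda v: v < MIN_BREAST_GROWTH_CM3
    )
    return out


def derive_measures(
    cohort: pd.DataFrame,
    diaries: dict[str, FeedDiary],
    ref: GrowthReference,
    window_h: tuple[float, float] = DEFAULT_DIARY_WINDOW_H,
) -> pd.DataFrame:
    """Attach every diary- and growth-derived measure to a cohort table.

    ``cohort`` needs columns dyad_id, infant_sex, birth_weight_g,
    age_at_measurement_days, and optionally current_weight_naked_g /
    first_prefeed_weight_g, bmi, maternal_age, bv_change. Returns a copy
    with mp_24h, breastmilk_intake_24h, formula_intake_24h,
    total_intake_24h, waz_birth, waz_current, delta_waz, avg_daily_gain,
    formula_to_growth and the recomputed risk flags.
    """
    out = derive_risk_flags(cohort)
    out = out.set_index("dyad_id", drop=False)
    cols = {
        name: pd.Series(np.nan, index=out.index, dtype=float)
        for name in [
            "mp_24h", "breastmilk_intake_24h", "formula_intake_24h",
            "total_intake_24h", "waz_birth", "waz_current", "delta_waz",
            "avg_daily_gain", "formula_to_growth",
        ]
    }
    for dyad_id, row in out.iterrows():
        diary = diaries.get(dyad_id)
        if diary is not None:
            cols["mp_24h"][dyad_id] = compute_mp_24h(diary, window_h)
            bm, fm, tot = compute_intakes(diary, window_h)
            cols["breastmilk_intake_24h"][dyad_id] = bm
            cols["formula_intake_24h"][dyad_id] = fm
            cols["total_intake_24h"][dyad_id] = tot
        sex = row.get("infant_sex")
        age = row.get("age_at_measurement_days")
        birth_w = row.get("birth_weight_g")
        naked = infer_naked_weight(
            row.get("current_weight_naked_g"), row.get("first_prefeed_weight_g")
        )
        if sex is not None and not pd.isna(birth_w):
            cols["waz_birth"][dyad_id] = waz(float(birth_w), 0.0, sex, ref)
        if naked is not None and sex is not None and not pd.isna(age):
            cols["waz_current"][dyad_id] = waz(float(naked), float(age), sex, ref)
            d = delta_waz(cols["waz_current"][dyad_id], cols["waz_birth"][dyad_id])
            cols["delta_waz"][dyad_id] = np.nan if d is None else d
            if not pd.isna(birth_w) and age > NEONATAL_REGAIN_DAYS:
                gain = avg_daily_weight_gain(float(naked), float(birth_w), float(age))
                cols["avg_daily_gain"][dyad_id] = gain
                fm = cols["formula_intake_24h"][dyad_id]
                if not np.isnan(fm):
                    cols["formula_to_growth"][dyad_id] = formula_to_growth_ratio(fm, gain)
    for name, series in cols.items():
        out[name] = series
    return out.reset_index(drop=True)
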