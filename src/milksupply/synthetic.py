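"""Synthetic cohorts of breastfeeding dyads with known latent structure.

The study cohort this package is designed around is not publicly
available, so this module simulates one: 460 mother-infant dyads drawn from four latent
milk-supply classes (adequate, oversupply, extremely-low-production with
heavy formula use, and slow-growth), with class-conditional risk-factor
prevalences, realistic covariates, MCAR missingness, and full ground-truth
bookkeeping. Feed diaries are generated so that recomputing 24 h milk
production and intakes from the diary reproduces the intended indicator
values almost exactly, which makes the generator a self-checking oracle for
the measurement pipeline.

All randomness flows through a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SpecError
from .growth import GrowthReference, weight_for_waz
from .measures import (
    CLOTHING_ALLOWANCE_G,
    MILK_DENSITY_G_PER_ML,
    RISK_FACTOR_COLUMNS,
    FeedDiary,
    FeedEvent,
    FeedKind,
)


@dataclass(frozen=True)
class ClassSpec:
    """One latent milk-supply class.

    Centres are on the original measurement scales (mL/24 h and z-scores);
    ``formula_center_ml`` is the median formula intake among the class's
    formula users, and ``formula_user_prob`` the probability of any formula
    use (zero-inflation). ``risk_prevalence`` maps each risk-factor flag to
    its class-conditional Bernoulli probability.
    """

    label: int
    name: str
    proportion: float
    mp_center: float
    bm_intake_center: float
    formula_user_prob: float
    formula_center_ml: float
    waz_center: float
    dwaz_center: float
    mp_sd: float = 150.0
    intake_sd: float = 110.0
    waz_sd: float = 0.50
    dwaz_sd: float = 0.40
    formula_log_sd: float = 0.35
    risk_prevalence: dict = field(default_factory=dict)


#: Default four-class structure: proportions and indicator centres follow the
#: published cohort (class sizes 254/30/56/120 of 460; MP medians
#: 789/1171/427/604 mL/24 h), spreads calibrated so the pooled MP mean +- SD
#: approximates 734 +- 228 mL/24 h.
DEFAULT_CLASSES: tuple[ClassSpec, ...] = (
    ClassSpec(
        1, "adequate", 254 / 460, mp_center=789.0, bm_intake_center=780.0,
        formula_user_prob=0.04, formula_center_ml=220.0,
        waz_center=-0.05, dwaz_center=-0.50,
        risk_prevalence={
            "ow": 0.540, "advanced_age": 0.321, "gdm": 0.198,
            "minimal_breast_growth": 0.193, "fertility_issues": 0.107,
            "thyroid": 0.091, "pcos": 0.091,
            "nipple_piercing_or_surgery": 0.080, "pph": 0.086, "hdp": 0.086,
        },
    ),
    ClassSpec(
        2, "oversupply", 30 / 460, mp_center=1171.0, bm_intake_center=1032.0,
        formula_user_prob=0.0, formula_center_ml=0.0,
        waz_center=0.26, dwaz_center=-0.25,
        risk_prevalence={
            "ow": 0.182, "advanced_age": 0.273, "gdm": 0.182,
            "minimal_breast_growth": 0.273, "fertility_issues": 0.136,
            "thyroid": 0.136, "pcos": 0.136,
            "nipple_piercing_or_surgery": 0.0, "pph": 0.091, "hdp": 0.0,
        },
    ),
    ClassSpec(
        3, "severe_low_supply", 56 / 460, mp_center=427.0, bm_intake_center=410.0,
        formula_user_prob=1.0, formula_center_ml=354.0,
        waz_center=-0.35, dwaz_center=-0.65,
        risk_prevalence={
            "ow": 0.660, "advanced_age": 0.511, "gdm": 0.298,
            "minimal_breast_growth": 0.511, "fertility_issues": 0.149,
            "thyroid": 0.085, "pcos": 0.085,
            "nipple_piercing_or_surgery": 0.043, "pph": 0.106, "hdp": 0.021,
        },
    ),
    ClassSpec(
        4, "slow_growth", 120 / 460, mp_center=604.0, bm_intake_center=590.0,
        formula_user_prob=0.10, formula_center_ml=220.0,
        waz_center=-1.11, dwaz_center=-1.35,
        risk_prevalence={
            "ow": 0.487, "advanced_age": 0.250, "gdm": 0.329,
            "minimal_breast_growth": 0.171, "fertility_issues": 0.145,
            "thyroid": 0.079, "pcos": 0.092,
            "nipple_piercing_or_surgery": 0.066, "pph": 0.053, "hdp": 0.026,
        },
    ),
)

#: Default per-variable MCAR missingness rates (fractions of the cohort),
#: matching the published per-variable missing counts.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "bv_change": 0.161,
    "bmi": 0.111,
    "maternal_age": 0.009,
    "birth_mode": 0.037,
    "education": 0.002,
    "marital_status": 0.002,
}


@dataclass(frozen=True)
class CohortSpec:
    """Full simulation specification for one cohort draw."""

    n_dyads: int = 460
    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    age_range_days: tuple[float, float] = (28.0, 182.0)
    p_male: float = 0.45
    p_primiparous: float = 0.593
    p_vaginal: float = 0.603
    p_naked_weight_measured: float = 1.0 - 201.0 / 460.0
    #: draw class membership multinomially (default) or fix the class
    #: counts at round(n * proportion), emulating the one fixed cohort a
    #: study actually observes rather than a resampled population
    exact_class_counts: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        """Load a cohort specification from a YAML (or JSON) file.

        Scalar fields map directly; an optional ``classes`` list gives
        :class:`ClassSpec` fields per class."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "classes" in raw:
            raw["classes"] = tuple(ClassSpec(**c) for c in raw["classes"])
        for key in ("age_range_days",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.n_dyads <= 0:
            raise SpecError("n_dyads must be positive")
        props = np.array([c.proportion for c in self.classes])
        if abs(props.sum() - 1.0) > 1e-9:
            raise SpecError(f"class proportions sum to {props.sum()}, not 1")
        for c in self.classes:
            if c.mp_sd <= 0 or c.intake_sd <= 0 or c.waz_sd <= 0 or c.dwaz_sd <= 0:
                raise SpecError(f"class {c.label}: spreads must be positive")
            for k, p in c.risk_prevalence.items():
                if not 0 <= p <= 1:
                    raise SpecError(f"class {c.label}: prevalence {k}={p} outside [0,1]")
            if c.bm_intake_center <= 0 or c.mp_center < 0:
                raise SpecError(f"class {c.label}: infeasible indicator centres")
        for k, r in self.missingness.items():
            if not 0 <= r < 1:
                raise SpecError(f"missingness {k}={r} outside [0,1)")


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    """Draw by rejection from N(mean, sd) truncated to [lo, hi]."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    # rejection loop; falls back to clipping if the window is extreme
    for _ in range(100):
        n_bad = int(np.sum(bad))
        if n_bad == 0:
            break
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def generate_diary(
    target_mp: float,
    target_formula: float,
    n_feeds: int,
    seed=None,
    *,
    target_bm_intake: float | None = None,
    dyad_id: str = "dyad",
    infant_weight_g: float = 5500.0,
    rng: np.random.Generator | None = None,
) -> FeedDiary:
    """Generate a "24 h plus one feed" diary hitting the stated targets.

    The first breastfeed anchors the diary and is excluded from both
    ledgers; remaining volumes are drawn then rescaled so that the
    recomputed milk production, breast-milk intake and formula intake land
    on the targets (within weight-rounding error, well inside 1%). When the
    breast-milk intake target is below production, the shortfall becomes
    pump expressions; when above (stored milk), expressed-milk bottles.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if target_mp < 0 or target_formula < 0:
        raise SpecError("targets must be non-negative")
    if n_feeds < 2:
        raise SpecError("need at least 2 breastfeeds (anchor + one measured)")
    if target_bm_intake is None:
        target_bm_intake = target_mp

    T_h = rng.uniform(24.0, 25.5)
    T_min = T_h * 60.0
    anchor_end = 12.0
    last_end = anchor_end + T_min
    scale = T_h / 24.0  # window totals corresponding to per-24h targets

    bf_total = min(target_mp, target_bm_intake) * scale
    pump_total = max(0.0, target_mp - target_bm_intake) * scale
    ebm_total = max(0.0, target_bm_intake - target_mp) * scale
    formula_total = target_formula * scale

    events: list[FeedEvent] = []

    def _weights(vol_ml, base):
        pre = round(base + rng.normal(0.0, 25.0), 1)
        post = round(pre + vol_ml * MILK_DENSITY_G_PER_ML, 1)
        return pre, post

    # anchor breastfeed (excluded from both ledgers)
    pre, post = _weights(rng.uniform(40, 90), infant_weight_g)
    events.append(FeedEvent(0.0, anchor_end, FeedKind.BREASTFEED, pre, post,
                            breast_side="left"))

    n_counted = n_feeds - 1
    interior = np.sort(rng.uniform(anchor_end + 40.0, last_end - 40.0, n_counted - 1))
    ends = np.append(interior, last_end)
    raw = rng.gamma(4.0, 1.0, n_counted)
    vols = raw / raw.sum() * bf_total if bf_total > 0 else np.zeros(n_counted)
    for end, vol in zip(ends, vols):
        pre, post = _weights(vol, infant_weight_g)
        events.append(FeedEvent(end - rng.uniform(8, 25), end, FeedKind.BREASTFEED,
                                pre, post, breast_side=rng.choice(["left", "right"])))

    def _interior_sessions(total, per_session, kind, base_weight):
        if total <= 0:
            return
        k = max(1, int(round(total / per_session)))
        raw = rng.gamma(4.0, 1.0, k)
        session_vols = raw / raw.sum() * total
        session_ends = rng.uniform(anchor_end + 30.0, last_end - 30.0, k)
        for end, vol in zip(session_ends, session_vols):
            pre, post = _weights(vol, base_weight)
            events.append(FeedEvent(end - rng.uniform(10, 20), end, kind, pre, post))

    _interior_sessions(pump_total, 120.0, FeedKind.PUMP_EXPRESSION, 1200.0)
    _interior_sessions(ebm_total, 90.0, FeedKind.EXPRESSED_BOTTLE, infant_weight_g)
    _interior_sessions(formula_total, 90.0, FeedKind.FORMULA_BOTTLE, infant_weight_g)

    return FeedDiary(dyad_id=dyad_id, events=events)


def inject_missingness(
    cohort: pd.DataFrame, rates: dict[str, float], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask values completely at random, column by column.

    Returns the masked table and a boolean mask table (True = masked).
    """
    out = cohort.copy()
    mask = pd.DataFrame(False, index=cohort.index, columns=list(rates))
    for col, rate in rates.items():
        if col not in out.columns:
            continue
        hit = rng.random(len(out)) < rate
        mask[col] = hit
        out.loc[hit, col] = np.nan if out[col].dtype.kind == "f" else pd.NA
    return out, mask


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int | None = None,
    *,
    with_diaries: bool = True,
    ref: GrowthReference | None = None,
):
    """Draw a full synthetic cohort.

    Returns ``(cohort, diaries, ground_truth)``: the covariate table with
    missingness applied (plus diary-independent raw inputs), a dict of
    per-dyad :class:`FeedDiary` (empty when ``with_diaries=False``), and the
    ground-truth table holding the true class, the intended indicator
    values, and the pre-missingness risk flags.
    """
    spec = spec or CohortSpec()
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    ref = ref or GrowthReference.bundled()
    n = spec.n_dyads
    classes = spec.classes
    props = np.array([c.proportion for c in classes])

    if spec.exact_class_counts:
        # largest-remainder apportionment of n across the class proportions
        raw = props * n
        counts = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
            counts[i] += 1
        z = rng.permutation(np.repeat(np.arange(len(classes)), counts))
    else:
        z = rng.choice(len(classes), size=n, p=props)
    dyad_ids = [f"D{i:04d}" for i in range(n)]

    mp = np.empty(n)
    bm = np.empty(n)
    formula = np.zeros(n)
    waz_cur = np.empty(n)
    dwaz = np.empty(n)
    flags = {f: np.zeros(n, dtype=bool) for f in RISK_FACTOR_COLUMNS}
    for k, c in enumerate(classes):
        idx = np.where(z == k)[0]
        m = len(idx)
        if m == 0:
            continue
        mp[idx] = _trunc_normal(rng, c.mp_center, c.mp_sd, 60.0, 1800.0, m)
        bm[idx] = _trunc_normal(rng, c.bm_intake_center, c.intake_sd, 30.0, 1500.0, m)
        users = rng.random(m) < c.formula_user_prob
        if users.any() and c.formula_center_ml > 0:
            formula[idx[users]] = c.formula_center_ml * np.exp(
                rng.normal(0.0, c.formula_log_sd, int(users.sum()))
            )
        waz_cur[idx] = rng.normal(c.waz_center, c.waz_sd, m)
        dwaz[idx] = rng.normal(c.dwaz_center, c.dwaz_sd, m)
        for f in RISK_FACTOR_COLUMNS:
            p = c.risk_prevalence.get(f, 0.0)
            flags[f][idx] = rng.random(m) < p

    waz_birth = waz_cur - dwaz
    # keep z-scores inside the LMS support and the printed data range
    waz_cur = np.clip(waz_cur, -3.5, 3.2)
    waz_birth = np.clip(waz_birth, -3.0, 3.4)
    dwaz = waz_cur - waz_birth

    sex = np.where(rng.random(n) < spec.p_male, "male", "female")
    age_days = np.round(rng.uniform(*spec.age_range_days, n), 0)
    birth_w = np.empty(n)
    naked_w = np.empty(n)
    for s in ("male", "female"):
        grp = ref.table[ref.table["sex"] == s]
        ages = grp["age_days"].to_numpy(float)
        sel = sex == s
        L = np.interp(age_days[sel], ages, grp["L"].to_numpy(float))
        M = np.interp(age_days[sel], ages, grp["M"].to_numpy(float))
        S = np.interp(age_days[sel], ages, grp["S"].to_numpy(float))
        naked_w[sel] = M * (1 + L * S * waz_cur[sel]) ** (1 / L)
        L0, M0, S0 = grp.iloc[0][["L", "M", "S"]].astype(float)
        birth_w[sel] = M0 * (1 + L0 * S0 * waz_birth[sel]) ** (1 / L0)

    # covariates drawn consistently with their class-assigned flags
    mat_age = np.where(
        flags["advanced_age"],
        _trunc_normal(rng, 38.0, 2.5, 35.0, 46.0, n),
        _trunc_normal(rng, 31.3, 2.8, 22.5, 34.99, n),
    )
    bmi = np.where(
        flags["ow"],
        29.0 + rng.gamma(2.0, 2.2, n),
        _trunc_normal(rng, 22.3, 1.8, 17.0, 24.99, n),
    )
    bmi = np.clip(bmi, 17.0, 62.5)
    bvc = np.where(
        flags["minimal_breast_growth"],
        _trunc_normal(rng, 40.0, 60.0, -230.0, 99.0, n),
        _trunc_normal(rng, 235.0, 110.0, 100.0, 660.0, n),
    )
    bv_pre = _trunc_normal(rng, 450.0, 150.0, 120.0, 900.0, n)
    height = _trunc_normal(rng, 1.66, 0.07, 1.45, 1.90, n)

    naked_measured = rng.random(n) < spec.p_naked_weight_measured

    cohort = pd.DataFrame(
        {
            "dyad_id": dyad_ids,
            "maternal_age": np.round(mat_age, 1),
            "height_m": np.round(height, 2),
            "bmi": np.round(bmi, 1),
            "pre_pregnancy_weight_kg": np.round(bmi * height**2, 1),
            "bv_pre": np.round(bv_pre, 0),
            "bv_post": np.round(bv_pre + bvc, 0),
            "bv_change": np.round(bvc, 0),
            "primiparous": rng.random(n) < spec.p_primiparous,
            "birth_mode": np.where(rng.random(n) < spec.p_vaginal, "vaginal", "cesarean"),
            "education": np.where(rng.random(n) < 0.721, "bachelor_or_above", "other"),
            "marital_status": np.where(rng.random(n) < 0.954, "married_or_defacto", "other"),
            "infant_sex": sex,
            "birth_gestation_wk": np.round(_trunc_normal(rng, 39.3, 1.1, 37.0, 42.4, n), 1),
            "birth_weight_g": np.round(birth_w, 0),
            "age_at_measurement_days": np.round(age_days, 0),
            "current_weight_naked_g": np.where(naked_measured, np.round(naked_w, 0), np.nan),
            "first_prefeed_weight_g": np.where(
                naked_measured, np.nan, np.round(naked_w + CLOTHING_ALLOWANCE_G, 0)
            ),
        }
    )
    for f in ["gdm", "fertility_issues", "thyroid", "pcos",
              "nipple_piercing_or_surgery", "pph", "hdp"]:
        cohort[f] = pd.array(flags[f], dtype="boolean")

    ground_truth = pd.DataFrame(
        {
            "dyad_id": dyad_ids,
            "true_class": z + 1,
            "true_class_name": [classes[k].name for k in z],
            "true_mp_24h": mp,
            "true_breastmilk_intake_24h": bm,
            "true_formula_intake_24h": formula,
            "true_total_intake_24h": bm + formula,
            "true_waz_current": waz_cur,
            "true_waz_birth": waz_birth,
            "true_delta_waz": dwaz,
        }
    )
    for f in RISK_FACTOR_COLUMNS:
        ground_truth[f"true_{f}"] = flags[f]

    diaries: dict[str, FeedDiary] = {}
    if with_diaries:
        n_feeds = rng.integers(8, 15, n)
        for i, did in enumerate(dyad_ids):
            diaries[did] = generate_diary(
                mp[i], formula[i], int(n_feeds[i]),
                target_bm_intake=bm[i], dyad_id=did,
                infant_weight_g=float(naked_w[i]) + CLOTHING_ALLOWANCE_G, rng=rng,
            )
    else:
        # indicator columns attached directly when diaries are skipped
        cohort["mp_24h"] = mp
        cohort["breastmilk_intake_24h"] = bm
        cohort["formula_intake_24h"] = formula
        cohort["total_intake_24h"] = bm + formula

    cohort, mask = inject_missingness(cohort, spec.missingness, rng)
    cohort.attrs["missingness_mask"] = mask
    return cohort, diaries, ground_truth
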