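"""Infant growth z-scores by the lambda-mu-sigma (LMS) method.

A weight-for-age standard is supplied as a table of (sex, age_days, L, M, S)
rows; the z-score of a weight ``W`` at a given age is

    z = ((W / M)**L - 1) / (L * S)        (L != 0)
    z = ln(W / M) / S                     (L -> 0 limit)

with L, M and S linearly interpolated on the age grid for the infant's sex.
The package ships a small synthetic reference grid for tests and simulation;
any reference in the same CSV layout (e.g. one exported from a national
standard) can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AgeOutOfRangeError, InvalidInputError

_L_ZERO_TOL = 1e-7


@dataclass(frozen=True)
class GrowthReference:
    """Weight-for-age LMS parameter grid with per-sex linear interpolation.

    ``table`` must have columns sex, age_days, L, M, S with M (grams) > 0,
    S > 0 and a strictly increasing age grid within each sex.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"sex", "age_days", "L", "M", "S"}
        missing = required - set(t.columns)
        if missing:
            raise InvalidInputError(f"growth reference missing columns: {sorted(missing)}")
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise InvalidInputError("growth reference requires M > 0 and S > 0")
        for sex, grp in t.groupby("sex"):
            ages = grp["age_days"].to_numpy(float)
            if not np.all(np.diff(ages) > 0):
                raise InvalidInputError(f"age grid not strictly increasing for sex={sex!r}")

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    @classmethod
    def bundled(cls) -> "GrowthReference":
        """The synthetic reference grid shipped with the package."""
        with resources.files("milksupply.data").joinpath(
            "growth_reference_synthetic.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh))

    def lms_at(self, sex: str, age_days: float) -> tuple[float, float, float]:
        """Interpolated (L, M, S) at ``age_days`` for ``sex``."""
        grp = self.table[self.table["sex"] == sex]
        if grp.empty:
            raise InvalidInputError(f"sex {sex!r} not in growth reference")
        ages = grp["age_days"].to_numpy(float)
        if not (ages[0] <= age_days <= ages[-1]):
            raise AgeOutOfRangeError(
                f"age {age_days} d outside reference grid [{ages[0]}, {ages[-1]}]"
            )
        L = float(np.interp(age_days, ages, grp["L"].to_numpy(float)))
        M = float(np.interp(age_days, ages, grp["M"].to_numpy(float)))
        S = float(np.interp(age_days, ages, grp["S"].to_numpy(float)))
        return L, M, S


def waz(weight_g: float, age_days: float, sex: str, ref: GrowthReference) -> float:
    """Weight-for-age z-score of ``weight_g`` (grams) by the LMS method."""
    if not np.isfinite(weight_g) or weight_g <= 0:
        raise InvalidInputError(f"weight must be positive and finite, got {weight_g}")
    L, M, S = ref.lms_at(sex, age_days)
    ratio = weight_g / M
    if abs(L) < _L_ZERO_TOL:
        return float(np.log(ratio) / S)
    return float((ratio**L - 1.0) / (L * S))


def weight_for_waz(z: float, age_days: float, sex: str, ref: GrowthReference) -> float:
    """Inverse of :func:`waz`: the weight (grams) with the given z-score."""
    L, M, S = ref.lms_at(sex, age_days)
    if abs(L) < _L_ZERO_TOL:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise InvalidInputError(f"z={z} outside the support of the LMS transform")
    return float(M * base ** (1.0 / L))
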