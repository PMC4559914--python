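"""Anthropometric Z-scores, SGA and EUGR classification.

A Z-score places a measurement (weight, length or head circumference)
relative to a sex- and gestational-age-indexed reference chart, either
as ``(value - mean) / sd`` or through the LMS (skewness L, median M,
coefficient of variation S) transformation.  The chart is pluggable:
any reference in the documented CSV schema can be loaded, and a
synthetic parametric chart (smooth median in GA, constant coefficient
of variation; NOT a clinical reference) is bundled so the pipeline runs
without external data.

Classification, on weight:

* SGA (small for gestational age): birth weight below the 10th
  percentile of the reference.
* EUGR (extra-uterine growth retardation): NOT born SGA, but weight
  below the 10th percentile at 36 weeks postconceptional age or
  discharge.  SGA and EUGR are therefore disjoint, and together they
  partition the infants below the 10th percentile at 36 weeks.

The 10th percentile corresponds to the normal quantile
Z = -1.2816 under both parameterizations (the LMS Z is a normal score);
the comparison is strict ``<``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthReference",
    "GrowthAssessment",
    "P10_Z_CUTOFF",
    "default_reference",
    "zscore",
    "value_from_z",
    "classify_sga",
    "classify_eugr",
    "delta_zscore",
    "max_weight_loss",
    "assess_growth",
]

MEASURES = ("weight", "length", "hc")

#: Standard-normal 10th-percentile quantile used as the SGA/EUGR cutoff.
P10_Z_CUTOFF = float(stats.norm.ppf(0.10))


class GrowthReference:
    """Sex- and GA-indexed growth chart, mean/SD or LMS parameterized.

    Parameters
    ----------
    table
        Long-format frame with columns ``sex`` ('M'/'F'), ``ga_days``,
        ``measure`` ('weight'/'length'/'hc') and either ``mean``/``sd``
        or ``L``/``M``/``S``.  Parameters are interpolated linearly in
        ``ga_days`` within each (sex, measure) block; queries outside
        the tabulated GA range raise.
    """

    def __init__(self, table: pd.DataFrame, parameterization: Optional[str] = None):
        cols = set(table.columns)
        if parameterization is None:
            if {"mean", "sd"} <= cols:
                parameterization = "mean_sd"
            elif {"L", "M", "S"} <= cols:
                parameterization = "lms"
            else:
                raise ValueError("table must carry mean/sd or L/M/S columns")
        self.parameterization = parameterization
        self._params = ("mean", "sd") if parameterization == "mean_sd" else ("L", "M", "S")
        table = table.sort_values(["sex", "measure", "ga_days"]).reset_index(drop=True)
        for (sex, measure), block in table.groupby(["sex", "measure"]):
            ga = block["ga_days"].to_numpy(float)
            if np.any(np.diff(ga) <= 0):
                raise ValueError(f"ga grid not strictly increasing for {sex}/{measure}")
            if parameterization == "mean_sd":
                if (block["sd"] <= 0).any():
                    raise ValueError("sd must be positive")
            else:
                if (block["S"] <= 0).any() or (block["M"] <= 0).any():
                    raise ValueError("M and S must be positive")
        self.table = table

    # -- construction -------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        """Load a chart CSV; mean/sd vs LMS dialect detected from the header."""
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    # -- parameter lookup ---------------------------------------------

    def params_at(self, sex: str, ga_days: float, measure: str) -> tuple[float, ...]:
        block = self.table[(self.table["sex"] == sex) & (self.table["measure"] == measure)]
        if block.empty:
            raise ValueError(f"reference has no rows for sex={sex!r}, measure={measure!r}")
        ga = block["ga_days"].to_numpy(float)
        if not ga[0] <= ga_days <= ga[-1]:
            raise ValueError(
                f"GA {ga_days} d outside reference domain [{ga[0]}, {ga[-1]}] "
                f"for {sex}/{measure}"
            )
        return tuple(
            float(np.interp(ga_days, ga, block[p].to_numpy(float))) for p in self._params
        )

    # -- transforms ----------------------------------------------------

    def zscore(self, value: float, sex: str, ga_days: float, measure: str) -> float:
        if self.parameterization == "mean_sd":
            mean, sd = self.params_at(sex, ga_days, measure)
            return (value - mean) / sd
        L, M, S = self.params_at(sex, ga_days, measure)
        if value <= 0:
            raise ValueError("measurement must be positive under LMS")
        if abs(L) < 1e-12:
            return math.log(value / M) / S
        return ((value / M) ** L - 1.0) / (L * S)

    def value_from_z(self, z: float, sex: str, ga_days: float, measure: str) -> float:
        """Inverse of :meth:`zscore`; used to materialise synthetic cohorts."""
        if self.parameterization == "mean_sd":
            mean, sd = self.params_at(sex, ga_days, measure)
            return mean + z * sd
        L, M, S = self.params_at(sex, ga_days, measure)
        if abs(L) < 1e-12:
            return M * math.exp(S * z)
        return M * (1.0 + L * S * z) ** (1.0 / L)


def _synthetic_rows() -> pd.DataFrame:
    # Smooth medians with a constant coefficient of variation per
    # measure; magnitudes chosen to be anatomically plausible for
    # preterm charts.  Synthetic, for pipeline use only — not clinical.
    ga_weeks = np.arange(24, 45)
    rows = []
    for sex, f in (("M", 1.03), ("F", 0.97)):
        d = 40.0 - ga_weeks
        weight = 3500.0 * f * np.exp(-0.065 * d - 0.0033 * d**2)
        length = (50.0 - 1.15 * d) * (1 + (f - 1) / 3)
        hc = (35.0 - 0.80 * d) * (1 + (f - 1) / 3)
        for measure, mean, cv in (("weight", weight, 0.13), ("length", length, 0.055), ("hc", hc, 0.045)):
            for g, m in zip(ga_weeks, mean):
                rows.append(
                    {"sex": sex, "ga_days": g * 7, "measure": measure, "mean": m, "sd": cv * m}
                )
    return pd.DataFrame(rows)


_DEFAULT: Optional[GrowthReference] = None


def default_reference() -> GrowthReference:
    """Bundled synthetic mean/SD chart (24-44 weeks, both sexes)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = GrowthReference(_synthetic_rows(), parameterization="mean_sd")
    return _DEFAULT


def zscore(
    value: float, sex: str, ga_days: float, measure: str,
    ref: Optional[GrowthReference] = None,
) -> float:
    """Z-score of a measurement against a reference (default: bundled chart)."""
    return (ref or default_reference()).zscore(value, sex, ga_days, measure)


def value_from_z(
    z: float, sex: str, ga_days: float, measure: str,
    ref: Optional[GrowthReference] = None,
) -> float:
    return (ref or default_reference()).value_from_z(z, sex, ga_days, measure)


def classify_sga(z_birth_weight: float, cutoff: float = P10_Z_CUTOFF) -> bool:
    """Small for gestational age: birth-weight Z strictly below the cutoff."""
    if not math.isfinite(z_birth_weight):
        raise ValueError("z_birth_weight must be finite")
    return z_birth_weight < cutoff


def classify_eugr(sga: bool, below_p10_at36: bool) -> bool:
    """EUGR: below the 10th percentile at 36 weeks PCA/DC without being born SGA."""
    return (not sga) and below_p10_at36


def delta_zscore(z_birth: float, z_36: float) -> float:
    """Change in Z-score from birth to 36 weeks PCA/DC."""
    if not (math.isfinite(z_birth) and math.isfinite(z_36)):
        raise ValueError("Z-scores must be finite")
    return z_36 - z_birth


def max_weight_loss(weights_g: Sequence[float], birth_weight_g: float) -> float:
    """Maximal postnatal weight loss as a percentage of birth weight.

    Zero when the series never dips below the birth weight.
    """
    if birth_weight_g <= 0:
        raise ValueError("birth weight must be positive")
    arr = np.asarray(list(weights_g), dtype=float)
    if arr.size == 0:
        raise ValueError("weight series is empty")
    nadir = min(float(arr.min()), birth_weight_g)
    return 100.0 * (birth_weight_g - nadir) / birth_weight_g


@dataclass(frozen=True)
class GrowthAssessment:
    """Weight-growth summary for one infant, birth to 36 weeks PCA/DC."""

    z_birth: float
    z_36: float
    delta_z: float
    sga: bool
    below_p10_at36: bool
    eugr: bool
    max_weight_loss_pct: Optional[float] = None


def assess_growth(
    birth_weight_g: float,
    weight36_g: float,
    sex: str,
    ga_days: float,
    pca36_days: float,
    ref: Optional[GrowthReference] = None,
    weight_series_g: Optional[Sequence[float]] = None,
) -> GrowthAssessment:
    """Full weight-growth classification for one infant.

    Measurements taken at discharge before 36 weeks PCA are Z-scored at
    the actual PCA of measurement (``pca36_days``).
    """
    ref = ref or default_reference()
    zb = ref.zscore(birth_weight_g, sex, ga_days, "weight")
    z36 = ref.zscore(weight36_g, sex, pca36_days, "weight")
    sga = classify_sga(zb)
    below = z36 < P10_Z_CUTOFF
    return GrowthAssessment(
        z_birth=zb,
        z_36=z36,
        delta_z=delta_zscore(zb, z36),
        sga=sga,
        below_p10_at36=below,
        eugr=classify_eugr(sga, below),
        max_weight_loss_pct=(
            max_weight_loss(weight_series_g, birth_weight_g)
            if weight_series_g is not None
            else None
        ),
    )
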