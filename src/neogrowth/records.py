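"""Per-infant record: demographics, anthropometry and feeding milestones.

All timing is in integer days of life (DOL), with DOL1 the day of
birth; postconceptional age (PCA) is carried in days.  The cohort
covers moderately preterm infants born at 30-33 completed weeks of
gestation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["InfantRecord", "GA_GROUPS", "ga_group"]

GA_GROUPS = ("30-31", "32-33")


def ga_group(ga_weeks: int) -> str:
    """Gestational-age stratum label used throughout the audit."""
    if ga_weeks in (30, 31):
        return "30-31"
    if ga_weeks in (32, 33):
        return "32-33"
    raise ValueError(f"gestational age {ga_weeks} outside the 30-33 week cohort")


@dataclass
class InfantRecord:
    """One infant's demographic, anthropometric and feeding-history record."""

    infant_id: str
    unit_id: str
    ga_weeks: int
    sex: str  # 'M' or 'F'
    birth_weight_g: float
    birth_length_cm: Optional[float] = None
    birth_hc_cm: Optional[float] = None
    # anthropometry at 36 weeks PCA or discharge (whichever first)
    weight36_g: Optional[float] = None
    length36_cm: Optional[float] = None
    hc36_cm: Optional[float] = None
    pca36_days: Optional[int] = None  # PCA in days at that measurement
    # feeding milestones and venous access
    enteral_init_dol: Optional[int] = None
    full_feed_dol: Optional[int] = None
    aa_start_dol: Optional[int] = None
    lipid_start_dol: Optional[int] = None
    aa_dol1_g_kg: Optional[float] = None  # parenteral AA dose on DOL1
    pn_dol1: Optional[bool] = None
    cvl_dol1: Optional[bool] = None
    max_weight_loss_pct: Optional[float] = None
    # antenatal / clinical covariates (0/1 indicators or numeric)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ga_group(self.ga_weeks)  # validates range
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.birth_weight_g <= 0:
            raise ValueError("birth_weight_g must be positive")
        for name in ("enteral_init_dol", "full_feed_dol", "aa_start_dol", "lipid_start_dol"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1 (DOL1 is the day of birth)")

    @property
    def ga_group(self) -> str:
        return ga_group(self.ga_weeks)

    @property
    def ga_days(self) -> int:
        return self.ga_weeks * 7
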