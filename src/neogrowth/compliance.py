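"""Guideline-compliance scoring and intended-vs-actual practice comparison.

Actual nutrition practice is scored against three criteria derived from
current European parenteral-nutrition recommendations:

i)   amino-acid initiation dose >= 1.5 g/kg/d given on DOL1;
ii)  amino-acid target dose >= 3.5 g/kg/d attained by DOL7;
iii) energy target dose >= 120 kcal/kg/d attained by DOL7.

Thresholds are compared with ``>=`` exactly as stated, no tolerance
band.  "Attained by DOL7" is evaluated on the DOL7 observation, the
only day near that deadline present in the sparse sampling scheme.

Intended practice comes from a per-unit questionnaire (one row per
GA stratum); :func:`compare_intended_actual` lines the two up in the
shape of the published comparison table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intake import DailyIntake
from .records import GA_GROUPS, InfantRecord

__all__ = [
    "GuidelineTargets",
    "ComplianceResult",
    "UnitQuestionnaire",
    "PracticeSummary",
    "assess_compliance",
    "summarize_actual_practice",
    "summarize_intended_practice",
    "compare_intended_actual",
]


@dataclass(frozen=True)
class GuidelineTargets:
    """Guideline dose thresholds, optionally overridden per GA week."""

    aa_init_dose_min: float = 1.5  # g/kg/d, on aa_init_day
    aa_init_day: int = 1
    aa_target_dose: float = 3.5  # g/kg/d, by attainment_day
    energy_target_dose: float = 120.0  # kcal/kg/d, by attainment_day
    attainment_day: int = 7
    per_ga_overrides: Optional[Mapping[int, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        for name in ("aa_init_dose_min", "aa_target_dose", "energy_target_dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.attainment_day < self.aa_init_day:
            raise ValueError("attainment_day must be >= aa_init_day")

    def targets_for(self, ga_weeks: Optional[int]) -> tuple[float, float]:
        """(AA target, energy target) for a GA week, applying overrides."""
        if self.per_ga_overrides and ga_weeks in self.per_ga_overrides:
            return tuple(self.per_ga_overrides[ga_weeks])  # type: ignore[return-value]
        return self.aa_target_dose, self.energy_target_dose


@dataclass(frozen=True)
class ComplianceResult:
    crit_aa_init: bool
    crit_aa_target: bool
    crit_energy_target: bool

    @property
    def fully_compliant(self) -> bool:
        return self.crit_aa_init and self.crit_aa_target and self.crit_energy_target


@dataclass(frozen=True)
class UnitQuestionnaire:
    """One unit's declared (intended) practice for one GA stratum."""

    unit_id: str
    ga_group: str  # '30-31' or '32-33'
    written_guidelines: bool
    pn_dol1: bool
    cvl_for_pn: bool
    aa_init_dol: float
    aa_init_dose: float
    lipid_init_dol: float
    enteral_init_dol: float
    enteral_advance_ml_kg_d: float
    fortification: bool

    def __post_init__(self) -> None:
        if self.ga_group not in GA_GROUPS:
            raise ValueError(f"ga_group must be one of {GA_GROUPS}")
        for name in ("aa_init_dol", "lipid_init_dol", "enteral_init_dol"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.aa_init_dose < 0 or self.enteral_advance_ml_kg_d < 0:
            raise ValueError("doses must be >= 0")


@dataclass(frozen=True)
class PracticeSummary:
    """Practice rates for one GA stratum (percentages in [0, 100])."""

    ga_group: str
    n: int
    cvl_for_pn_pct: float
    pn_dol1_pct: float
    aa_init_dol1_pct: float
    aa_init_dose_ge_1_5_pct: float
    lipid_le_dol2_pct: float
    enteral_init_dol_mean: float


def assess_compliance(
    intake_dol1: DailyIntake,
    intake_dol7: DailyIntake,
    targets: GuidelineTargets = GuidelineTargets(),
    ga_weeks: Optional[int] = None,
) -> ComplianceResult:
    """Score one infant's intake against the three guideline criteria."""
    if intake_dol1 is None or intake_dol7 is None:
        raise ValueError("both DOL1 and DOL7 intakes are required")
    if intake_dol1.dol != targets.aa_init_day or intake_dol7.dol != targets.attainment_day:
        raise ValueError(
            f"expected intakes at DOL{targets.aa_init_day} and DOL{targets.attainment_day}, "
            f"got DOL{intake_dol1.dol} and DOL{intake_dol7.dol}"
        )
    aa_target, energy_target = targets.targets_for(ga_weeks)
    return ComplianceResult(
        crit_aa_init=intake_dol1.aa_g_kg_d >= targets.aa_init_dose_min,
        crit_aa_target=intake_dol7.aa_g_kg_d >= aa_target,
        crit_energy_target=intake_dol7.energy_kcal_kg_d >= energy_target,
    )


def _rate(flags: Sequence[bool]) -> float:
    return 100.0 * sum(flags) / len(flags)


def summarize_actual_practice(
    records: Sequence[InfantRecord],
    aa_init_dose_min: float = 1.5,
) -> dict[str, PracticeSummary]:
    """Record-derived practice rates per GA stratum.

    Rates: central line on DOL1, parenteral nutrition started DOL1, AA
    started DOL1, AA DOL1 dose >= ``aa_init_dose_min``, lipids started
    on or before DOL2, and the mean enteral-initiation day.  Lipid
    timing comes from the recorded start day, not the sampled rates
    (which skip DOL2).  Empty strata are flagged with a warning and NaN
    rates.
    """
    if not records:
        raise ValueError("cohort is empty")
    out: dict[str, PracticeSummary] = {}
    for group in GA_GROUPS:
        recs = [r for r in records if r.ga_group == group]
        if not recs:
            warnings.warn(f"no infants in GA group {group}; rates undefined")
            out[group] = PracticeSummary(group, 0, *([float("nan")] * 6))
            continue
        out[group] = PracticeSummary(
            ga_group=group,
            n=len(recs),
            cvl_for_pn_pct=_rate([bool(r.cvl_dol1) for r in recs]),
            pn_dol1_pct=_rate([bool(r.pn_dol1) for r in recs]),
            aa_init_dol1_pct=_rate([r.aa_start_dol == 1 for r in recs]),
            aa_init_dose_ge_1_5_pct=_rate(
                [(r.aa_dol1_g_kg or 0.0) >= aa_init_dose_min for r in recs]
            ),
            lipid_le_dol2_pct=_rate(
                [r.lipid_start_dol is not None and r.lipid_start_dol <= 2 for r in recs]
            ),
            enteral_init_dol_mean=float(
                np.mean([r.enteral_init_dol for r in recs if r.enteral_init_dol is not None])
            ),
        )
    return out


_ROWS = [
    ("cvl_for_pn_pct", "CVL for PN (%)"),
    ("enteral_init_dol_mean", "Enteral feeding initiation DOL (mean)"),
    ("pn_dol1_pct", "PN started on DOL1 (%)"),
    ("aa_init_dol1_pct", "AA parenteral initiation at DOL1 (%)"),
    ("aa_init_dose_ge_1_5_pct", "AA parenteral initiation dose >= 1.5 g/kg/d (%)"),
    ("lipid_le_dol2_pct", "Lipid parenteral initiation <= DOL2 (%)"),
]


def summarize_intended_practice(
    questionnaires: Iterable[UnitQuestionnaire],
    aa_init_dose_min: float = 1.5,
) -> dict[str, PracticeSummary]:
    """Questionnaire-declared practice rates per GA stratum, unit-weighted."""
    qs = list(questionnaires)
    out: dict[str, PracticeSummary] = {}
    for group in GA_GROUPS:
        gq = [q for q in qs if q.ga_group == group]
        if not gq:
            warnings.warn(f"no questionnaires for GA group {group}")
            out[group] = PracticeSummary(group, 0, *([float("nan")] * 6))
            continue
        out[group] = PracticeSummary(
            ga_group=group,
            n=len(gq),
            cvl_for_pn_pct=_rate([q.cvl_for_pn for q in gq]),
            pn_dol1_pct=_rate([q.pn_dol1 for q in gq]),
            aa_init_dol1_pct=_rate([q.aa_init_dol <= 1 for q in gq]),
            aa_init_dose_ge_1_5_pct=_rate([q.aa_init_dose >= aa_init_dose_min for q in gq]),
            lipid_le_dol2_pct=_rate([q.lipid_init_dol <= 2 for q in gq]),
            enteral_init_dol_mean=float(np.mean([q.enteral_init_dol for q in gq])),
        )
    return out


def compare_intended_actual(
    intended: Mapping[str, PracticeSummary],
    actual: Mapping[str, PracticeSummary],
) -> pd.DataFrame:
    """Side-by-side intended vs actual practice per GA stratum.

    Returns a tidy frame with one row per (metric, GA group):
    intended value, actual value and their difference (actual minus
    intended).  Strata missing on either side yield NaN rows.
    """
    rows = []
    for group in GA_GROUPS:
        i = intended.get(group)
        a = actual.get(group)
        for attr, label in _ROWS:
            iv = getattr(i, attr) if i is not None and i.n > 0 else float("nan")
            av = getattr(a, attr) if a is not None and a.n > 0 else float("nan")
            rows.append(
                {
                    "ga_group": group,
                    "metric": label,
                    "intended": iv,
                    "actual": av,
                    "difference": av - iv,
                }
            )
    return pd.DataFrame(rows)
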