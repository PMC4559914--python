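"""Daily nutrient intake arithmetic for parenteral and enteral routes.

Converts raw bedside records — parenteral prescriptions in g/kg/d of
dextrose, amino acids (AA) and lipids, and enteral milk volumes in
ml/kg/d — into the two axes the audit works on: protein/AA (g/kg/d) and
energy (kcal/kg/d).  Parenteral AA and milk protein are pooled into a
single protein axis because the downstream cumulative-intake analysis
mixes both routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Line",
    "EnergyFactors",
    "ParenteralPrescription",
    "MilkComposition",
    "EnteralFeed",
    "DailyIntake",
    "HUMAN_MILK",
    "parenteral_daily_intake",
    "enteral_daily_intake",
    "total_daily_intake",
]


class Line(str, Enum):
    """Venous access used for parenteral nutrition on a given day."""

    CENTRAL = "central"
    PERIPHERAL = "peripheral"
    NONE = "none"


@dataclass(frozen=True)
class EnergyFactors:
    """Energy yield of parenteral substrates, kcal per gram.

    The defaults (3.4 for dextrose monohydrate, 4.0 for amino acids,
    9.0 for lipid) are the conventional parenteral conversion factors;
    they are configurable because units differ in the dextrose value
    they use (3.4 vs 4.0 kcal/g).
    """

    dextrose_kcal_g: float = 3.4
    aa_kcal_g: float = 4.0
    lipid_kcal_g: float = 9.0

    def __post_init__(self) -> None:
        for name in ("dextrose_kcal_g", "aa_kcal_g", "lipid_kcal_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"energy factor {name} must be positive")


@dataclass(frozen=True)
class ParenteralPrescription:
    """One day's parenteral prescription, all rates in g/kg/d."""

    dol: int
    dextrose_g_kg_d: float = 0.0
    aa_g_kg_d: float = 0.0
    lipid_g_kg_d: float = 0.0
    line: Line = Line.NONE

    def __post_init__(self) -> None:
        if self.dol < 1:
            raise ValueError(f"dol must be >= 1, got {self.dol}")
        for name in ("dextrose_g_kg_d", "aa_g_kg_d", "lipid_g_kg_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.line is Line.NONE and (
            self.dextrose_g_kg_d or self.aa_g_kg_d or self.lipid_g_kg_d
        ):
            raise ValueError("line='none' requires all parenteral rates to be 0")


@dataclass(frozen=True)
class MilkComposition:
    """Milk (or formula) composition per decilitre."""

    name: str
    energy_kcal_dl: float
    protein_g_dl: float
    fat_g_dl: float
    carb_g_dl: float

    def __post_init__(self) -> None:
        for name in ("energy_kcal_dl", "protein_g_dl", "fat_g_dl", "carb_g_dl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def __add__(self, other: "MilkComposition") -> "MilkComposition":
        return MilkComposition(
            name=f"{self.name}+{other.name}",
            energy_kcal_dl=self.energy_kcal_dl + other.energy_kcal_dl,
            protein_g_dl=self.protein_g_dl + other.protein_g_dl,
            fat_g_dl=self.fat_g_dl + other.fat_g_dl,
            carb_g_dl=self.carb_g_dl + other.carb_g_dl,
        )


#: Assumed mean human-milk content: 64 kcal/dl, 1.4 g/dl protein,
#: 3.2 g/dl fat, 7.0 g/dl carbohydrate.
HUMAN_MILK = MilkComposition("human_milk", 64.0, 1.4, 3.2, 7.0)


@dataclass(frozen=True)
class EnteralFeed:
    """One day's enteral feed: a volume of a given milk, optionally fortified.

    ``fortifier_add`` is an additive per-decilitre composition (what the
    fortifier contributes to each dl of milk), keyed off a product table.
    """

    dol: int
    volume_ml_kg_d: float
    milk: MilkComposition = HUMAN_MILK
    fortifier_add: Optional[MilkComposition] = None

    def __post_init__(self) -> None:
        if self.dol < 1:
            raise ValueError(f"dol must be >= 1, got {self.dol}")
        if self.volume_ml_kg_d < 0:
            raise ValueError("volume_ml_kg_d must be >= 0")

    @property
    def effective_milk(self) -> MilkComposition:
        if self.fortifier_add is None:
            return self.milk
        return self.milk + self.fortifier_add


@dataclass(frozen=True)
class DailyIntake:
    """Total intake for one day of life on the pooled protein/energy axes."""

    dol: int
    aa_g_kg_d: float
    energy_kcal_kg_d: float
    parenteral_fraction_energy: float = 0.0

    def __post_init__(self) -> None:
        if self.aa_g_kg_d < 0 or self.energy_kcal_kg_d < 0:
            raise ValueError("intake rates must be >= 0")
        if not 0.0 <= self.parenteral_fraction_energy <= 1.0:
            raise ValueError("parenteral_fraction_energy must be in [0, 1]")

    def __add__(self, other: "DailyIntake") -> "DailyIntake":
        if self.dol != other.dol:
            raise ValueError(
                f"cannot add intakes for different days ({self.dol} vs {other.dol})"
            )
        energy = self.energy_kcal_kg_d + other.energy_kcal_kg_d
        pn_energy = (
            self.parenteral_fraction_energy * self.energy_kcal_kg_d
            + other.parenteral_fraction_energy * other.energy_kcal_kg_d
        )
        frac = pn_energy / energy if energy > 0 else 0.0
        return DailyIntake(
            dol=self.dol,
            aa_g_kg_d=self.aa_g_kg_d + other.aa_g_kg_d,
            energy_kcal_kg_d=energy,
            parenteral_fraction_energy=min(frac, 1.0),
        )


def parenteral_daily_intake(
    rx: ParenteralPrescription, factors: EnergyFactors = EnergyFactors()
) -> DailyIntake:
    """Protein and energy contributed by one day's parenteral prescription.

    AA contribute gram-for-gram to the protein axis; energy is the sum of
    the three substrates times their kcal/g factors.
    """
    energy = (
        rx.dextrose_g_kg_d * factors.dextrose_kcal_g
        + rx.aa_g_kg_d * factors.aa_kcal_g
        + rx.lipid_g_kg_d * factors.lipid_kcal_g
    )
    return DailyIntake(
        dol=rx.dol,
        aa_g_kg_d=rx.aa_g_kg_d,
        energy_kcal_kg_d=energy,
        parenteral_fraction_energy=1.0 if energy > 0 else 0.0,
    )


def enteral_daily_intake(feed: EnteralFeed) -> DailyIntake:
    """Protein and energy contributed by one day's enteral feed.

    100 ml/kg/d of default human milk gives 64 kcal/kg/d and
    1.4 g/kg/d of protein; fortifier composition adds per-dl.
    """
    milk = feed.effective_milk
    dl = feed.volume_ml_kg_d / 100.0
    return DailyIntake(
        dol=feed.dol,
        aa_g_kg_d=dl * milk.protein_g_dl,
        energy_kcal_kg_d=dl * milk.energy_kcal_dl,
        parenteral_fraction_energy=0.0,
    )


def total_daily_intake(
    rx: Optional[ParenteralPrescription],
    feed: Optional[EnteralFeed],
    factors: EnergyFactors = EnergyFactors(),
) -> DailyIntake:
    """Combined intake from both routes for one day of life.

    ``parenteral_fraction_energy`` is the parenteral share of total
    energy (0 when total energy is 0).  Either route may be ``None``.
    """
    if rx is None and feed is None:
        raise ValueError("at least one of rx and feed is required")
    if rx is not None and feed is not None and rx.dol != feed.dol:
        raise ValueError(f"mismatched day of life: rx dol {rx.dol} vs feed dol {feed.dol}")
    dol = rx.dol if rx is not None else feed.dol  # type: ignore[union-attr]
    parts = []
    if rx is not None:
        parts.append(parenteral_daily_intake(rx, factors))
    if feed is not None:
        parts.append(enteral_daily_intake(feed))
    total = parts[0]
    for p in parts[1:]:
        total = total + p
    return total
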