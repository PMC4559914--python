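"""Seeded synthetic cohorts of moderately preterm infants.

Generates cohorts with the statistical structure the audit analyses:
per-infant 14-day amino-acid and energy intake trajectories (piecewise
linear between knot days 1/3/7/14 plus daily noise), growth Z-scores at
birth and 36 weeks PCA, feeding milestones, practice flags and per-unit
questionnaires.  Defaults reproduce the published cohort conditions:
276 infants at 30-33 weeks (64/68/76/68 per week), birth-weight Z
-0.17 +/- 0.88, DOL1 amino acids 1.1 +/- 0.7 g/kg/d rising to
2.9 +/- 0.9 by DOL7, cumulative 14-day totals of 37.0 +/- 8.3 g/kg
(amino acids) and 1201 +/- 166 kcal/kg (energy), enteral feeding from
DOL 1.7 +/- 1.2 and full feeds at DOL 11.7 +/- 6.9.

Knot values across days are drawn from an equicorrelated multivariate
normal (a shared per-infant random effect); the correlation is solved,
given the marginal knot SDs, so the between-infant SD of the 14-day
cumulative sum matches the configured target.  Negative draws are
truncated at zero.  The change in weight Z-score is generated from the
same linear model the analysis fits (tertile of cumulative amino-acid
intake and day of full enteral feeding), which makes parameter recovery
a meaningful end-to-end check.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from the cohort spec, so a fixed seed reproduces the cohort
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cumulative import SparseScheme, estimate_cumulative, subsample_daily
from .growth import GrowthReference, default_reference
from .records import InfantRecord
from .analysis import assign_tertiles
from .compliance import UnitQuestionnaire

__all__ = [
    "KnotDistribution",
    "DeltaZGenerator",
    "CohortSpec",
    "SyntheticCohort",
    "solve_knot_correlation",
    "generate_daily_trajectories",
    "generate_growth",
    "generate_cohort",
]


def solve_knot_correlation(
    knot_sds: tuple[float, ...],
    target_cum_sd: float,
    weights: tuple[float, ...] = (1.5, 3.0, 5.5, 4.0),
) -> float:
    """Equicorrelation that gives the weighted knot sum a target SD.

    With weights w, marginal SDs s and common correlation rho, the
    variance of sum(w*s) is (1-rho)*sum((w s)^2) + rho*(sum(w s))^2;
    solving for rho is linear.  Raises if the target is unreachable in
    [0, 1).
    """
    ws = np.asarray(weights) * np.asarray(knot_sds)
    a = float(np.sum(ws**2))
    b = float(np.sum(ws)) ** 2
    rho = (target_cum_sd**2 - a) / (b - a)
    if not 0.0 <= rho < 1.0:
        raise ValueError(
            f"target cumulative SD {target_cum_sd} unreachable with knot SDs {knot_sds} "
            f"(implied correlation {rho:.3f})"
        )
    return rho


@dataclass(frozen=True)
class KnotDistribution:
    """Between-infant distribution of intake rates at the four knot days."""

    means: tuple[float, float, float, float]
    sds: tuple[float, float, float, float]
    daily_noise_sd: float
    target_cum_sd: Optional[float] = None
    correlation: Optional[float] = None  # solved from target_cum_sd when None

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.means) or any(s < 0 for s in self.sds):
            raise ValueError("knot means and sds must be >= 0")
        if self.daily_noise_sd < 0:
            raise ValueError("daily_noise_sd must be >= 0")
        if self.correlation is None and self.target_cum_sd is None:
            raise ValueError("give either correlation or target_cum_sd")

    def rho(self, weights: tuple[float, ...] = (1.5, 3.0, 5.5, 4.0)) -> float:
        if self.correlation is not None:
            return self.correlation
        return solve_knot_correlation(self.sds, self.target_cum_sd, weights)


#: Amino acids, g/kg/d.  DOL1 and DOL7 moments are the published ones;
#: DOL3/DOL14 are calibrated so the cumulative mean is 37.0 g/kg and
#: (via the solved correlation) the cumulative SD is 8.3 g/kg.
AA_KNOTS = KnotDistribution(
    means=(1.1, 1.7, 2.9, 3.575),
    sds=(0.7, 0.77, 0.9, 1.0),
    daily_noise_sd=0.44,
    target_cum_sd=8.3,
)

#: Energy, kcal/kg/d.  DOL7 moments published (94 +/- 18); the rest
#: calibrated to a 1201 +/- 166 kcal/kg cumulative total.
ENERGY_KNOTS = KnotDistribution(
    means=(40.0, 70.0, 94.0, 103.5),
    sds=(15.0, 16.0, 18.0, 20.0),
    daily_noise_sd=10.0,
    target_cum_sd=166.0,
)


@dataclass(frozen=True)
class DeltaZGenerator:
    """Linear model generating the change in weight Z-score.

    delta = intercept + tertile_effect * tertile(cumulative AA)
          + full_feed_day_effect * DOL(full enteral feeding) + noise.

    The default intercept makes the mean change -0.80 at the default
    covariate means (tertile 2, full feeds at DOL 11.7).
    """

    intercept: float = -0.943
    tertile_effect: float = 0.13
    full_feed_day_effect: float = -0.01
    noise_sd: float = 0.45

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """All parameters of one synthetic cohort, with published defaults."""

    n_infants: int = 276
    n_units: int = 25
    ga_counts: tuple[tuple[int, int], ...] = ((30, 64), (31, 68), (32, 76), (33, 68))
    p_male: float = 0.489
    birth_z_mean: float = -0.17
    birth_z_sd: float = 0.88
    z36_marginal_mean: float = -1.00
    z36_marginal_sd: float = 0.82
    delta_z: DeltaZGenerator = DeltaZGenerator()
    aa_knots: KnotDistribution = AA_KNOTS
    energy_knots: KnotDistribution = ENERGY_KNOTS
    enteral_init_mean: float = 1.7
    enteral_init_sd: float = 1.2
    full_feed_mean: float = 11.7
    full_feed_sd: float = 6.9
    p_pn_dol1: float = 0.92
    p_cvl: float = 0.76
    p_aa_dol1: float = 0.93
    p_lipid_le_dol2: float = 0.47
    pca36_days: int = 252  # 36 weeks PCA at the follow-up measurement
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_male", "p_pn_dol1", "p_cvl", "p_aa_dol1", "p_lipid_le_dol2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_cvl > self.p_pn_dol1 > 0 and self.p_cvl / self.p_pn_dol1 > 1:
            raise ValueError("p_cvl cannot exceed p_pn_dol1")
        total = sum(n for _, n in self.ga_counts)
        if total != self.n_infants:
            raise ValueError(
                f"ga_counts sum to {total}, but n_infants is {self.n_infants}"
            )
        for sd_name in ("birth_z_sd", "enteral_init_sd", "full_feed_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "delta_z" in d and isinstance(d["delta_z"], dict):
            d["delta_z"] = DeltaZGenerator(**d["delta_z"])
        for key in ("aa_knots", "energy_knots"):
            if key in d and isinstance(d[key], dict):
                kd = dict(d[key])
                for tup in ("means", "sds"):
                    kd[tup] = tuple(kd[tup])
                d[key] = KnotDistribution(**kd)
        if "ga_counts" in d:
            d["ga_counts"] = tuple((int(g), int(n)) for g, n in d["ga_counts"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


KNOT_DAYS = (1, 3, 7, 14)


def generate_daily_trajectories(
    knots: KnotDistribution,
    n: int,
    rng: np.random.Generator,
    horizon: int = 14,
) -> np.ndarray:
    """(n, horizon) daily-rate series from the knot distribution.

    Per infant: draw correlated knot values (shared random effect plus
    independent deviations), truncate at zero, interpolate linearly
    between knot days, then add independent zero-mean noise on the
    non-knot days, again truncated at zero.  Knot days stay exactly at
    their drawn values, so sparse observations are an exact subsample.
    """
    rho = knots.rho()
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, 4))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    knot_vals = np.asarray(knots.means) + np.asarray(knots.sds) * z
    knot_vals = np.maximum(knot_vals, 0.0)

    days = np.arange(1, horizon + 1)
    traj = np.empty((n, horizon))
    for i in range(n):
        traj[i] = np.interp(days, KNOT_DAYS, knot_vals[i])
    non_knot = ~np.isin(days, KNOT_DAYS)
    noise = rng.normal(0.0, knots.daily_noise_sd, size=(n, int(non_knot.sum())))
    traj[:, non_knot] += noise
    return np.maximum(traj, 0.0)


def generate_growth(
    n: int,
    rng: np.random.Generator,
    spec: CohortSpec,
    tertile_labels: np.ndarray,
    full_feed_dol: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-infant (z_birth, z_36) from the configured linear change model."""
    zb = rng.normal(spec.birth_z_mean, spec.birth_z_sd, size=n)
    dz = spec.delta_z
    delta = (
        dz.intercept
        + dz.tertile_effect * tertile_labels
        + dz.full_feed_day_effect * full_feed_dol
        + rng.normal(0.0, dz.noise_sd, size=n)
    )
    return zb, zb + delta


@dataclass
class SyntheticCohort:
    """A generated cohort: records, questionnaires, trajectories, provenance."""

    spec: CohortSpec
    records: list[InfantRecord]
    questionnaires: list[UnitQuestionnaire]
    trajectories: pd.DataFrame  # long: infant_id, dol, aa_g_kg_d, energy_kcal_kg_d
    growth: pd.DataFrame  # infant_id, z_birth, z_36, tertile_aa, ...

    def sparse_observations(self, nutrient: str = "aa"):
        """Per-infant sparse observations, exactly the knot-day samples."""
        col = "aa_g_kg_d" if nutrient == "aa" else "energy_kcal_kg_d"
        wide = self.trajectories.pivot(index="infant_id", columns="dol", values=col)
        return {
            iid: subsample_daily(wide.loc[iid].to_numpy(), nutrient=nutrient)
            for iid in wide.index
        }

    def write_csvs(self, outdir) -> dict[str, str]:
        """Write patients/questionnaires/trajectories CSVs plus the spec."""
        from . import io as _io

        return _io.write_cohort(self, outdir)


def _unit_questionnaires(spec: CohortSpec, rng: np.random.Generator) -> list[UnitQuestionnaire]:
    # Intended-practice distributions per GA stratum (survey moments).
    params = {
        "30-31": dict(written=0.72, pn=0.88, cvl=0.44, aa_dol=(1.08, 0.4),
                      aa_dose=(1.39, 0.59), lipid=(2.0, 0.6), ent=(1.3, 0.5),
                      adv=(18.2, 5.0), fort=0.92),
        "32-33": dict(written=0.76, pn=0.56, cvl=0.16, aa_dol=(1.13, 0.6),
                      aa_dose=(1.31, 0.58), lipid=(2.1, 0.4), ent=(1.2, 0.4),
                      adv=(19.6, 5.6), fort=0.76),
    }
    out = []
    for u in range(spec.n_units):
        for group, p in params.items():
            out.append(
                UnitQuestionnaire(
                    unit_id=f"U{u + 1:02d}",
                    ga_group=group,
                    written_guidelines=bool(rng.random() < p["written"]),
                    pn_dol1=bool(rng.random() < p["pn"]),
                    cvl_for_pn=bool(rng.random() < p["cvl"]),
                    aa_init_dol=float(max(1.0, rng.normal(*p["aa_dol"]))),
                    aa_init_dose=float(max(0.0, rng.normal(*p["aa_dose"]))),
                    lipid_init_dol=float(max(1.0, rng.normal(*p["lipid"]))),
                    enteral_init_dol=float(max(1.0, rng.normal(*p["ent"]))),
                    enteral_advance_ml_kg_d=float(max(0.0, rng.normal(*p["adv"]))),
                    fortification=bool(rng.random() < p["fort"]),
                )
            )
    return out


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    ref: Optional[GrowthReference] = None,
) -> SyntheticCohort:
    """Assemble a full synthetic cohort from a :class:`CohortSpec`.

    Order of construction: intake trajectories first, then the tertile
    of the estimated cumulative amino-acid intake and the feeding
    milestones, then the Z-score change generated from those covariates,
    and finally weights back-transformed through the growth reference.
    """
    ref = ref or default_reference()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_infants

    ga_weeks = np.repeat(
        [g for g, _ in spec.ga_counts], [c for _, c in spec.ga_counts]
    )
    sex = np.where(rng.random(n) < spec.p_male, "M", "F")
    unit_ids = np.array([f"U{(i % spec.n_units) + 1:02d}" for i in range(n)])

    aa_traj = generate_daily_trajectories(spec.aa_knots, n, rng)
    energy_traj = generate_daily_trajectories(spec.energy_knots, n, rng)
    aa_cum = np.array(
        [estimate_cumulative(subsample_daily(aa_traj[i])) for i in range(n)]
    )
    tertiles = assign_tertiles(aa_cum, "aa_cumulative").labels

    enteral_init = np.maximum(
        1, np.rint(rng.normal(spec.enteral_init_mean, spec.enteral_init_sd, n))
    ).astype(int)
    full_feed = np.maximum(
        enteral_init,
        np.rint(rng.normal(spec.full_feed_mean, spec.full_feed_sd, n)).astype(int),
    )

    zb, z36 = generate_growth(n, rng, spec, tertiles.astype(float), full_feed.astype(float))

    pn = rng.random(n) < spec.p_pn_dol1
    # central lines only occur where PN is given; conditional probability
    # chosen so the marginal CVL rate matches the configured one
    p_cvl_given_pn = spec.p_cvl / spec.p_pn_dol1 if spec.p_pn_dol1 > 0 else 0.0
    cvl = pn & (rng.random(n) < p_cvl_given_pn)
    aa_dol1_flag = rng.random(n) < spec.p_aa_dol1
    lipid_start = np.where(rng.random(n) < spec.p_lipid_le_dol2, 2, 3)

    records: list[InfantRecord] = []
    rows_growth = []
    for i in range(n):
        iid = f"P{i + 1:04d}"
        ga_days = int(ga_weeks[i]) * 7
        bw = ref.value_from_z(zb[i], sex[i], ga_days, "weight")
        w36 = ref.value_from_z(z36[i], sex[i], spec.pca36_days, "weight")
        records.append(
            InfantRecord(
                infant_id=iid,
                unit_id=str(unit_ids[i]),
                ga_weeks=int(ga_weeks[i]),
                sex=str(sex[i]),
                birth_weight_g=float(bw),
                weight36_g=float(w36),
                pca36_days=spec.pca36_days,
                enteral_init_dol=int(enteral_init[i]),
                full_feed_dol=int(full_feed[i]),
                aa_start_dol=1 if aa_dol1_flag[i] else 2,
                lipid_start_dol=int(lipid_start[i]),
                aa_dol1_g_kg=float(aa_traj[i, 0]) if aa_dol1_flag[i] else 0.0,
                pn_dol1=bool(pn[i]),
                cvl_dol1=bool(cvl[i]),
            )
        )
        rows_growth.append(
            {
                "infant_id": iid,
                "z_birth": float(zb[i]),
                "z_36": float(z36[i]),
                "delta_z": float(z36[i] - zb[i]),
                "tertile_aa": int(tertiles[i]),
                "full_feed_dol": int(full_feed[i]),
                "aa_cumulative": float(aa_cum[i]),
            }
        )

    traj_rows = []
    for i in range(n):
        iid = f"P{i + 1:04d}"
        for d in range(14):
            traj_rows.append(
                {
                    "infant_id": iid,
                    "dol": d + 1,
                    "aa_g_kg_d": float(aa_traj[i, d]),
                    "energy_kcal_kg_d": float(energy_traj[i, d]),
                }
            )

    return SyntheticCohort(
        spec=spec,
        records=records,
        questionnaires=_unit_questionnaires(spec, rng),
        trajectories=pd.DataFrame(traj_rows),
        growth=pd.DataFrame(rows_growth),
    )
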