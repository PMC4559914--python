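"""CSV schemas, run configuration and the end-to-end pipeline.

All tabular interchange is UTF-8 comma-separated CSV with a header row;
repeated measures (daily trajectories) are long-format.  Timing is in
integer days of life (DOL1 = day of birth) — no calendar dates anywhere.

The pipeline stages are: cohort in (read or simulated) -> daily and
cumulative intakes with guideline deficits -> compliance scoring and
intended-vs-actual comparison -> growth Z-scores / SGA / EUGR ->
screened regressions for the change in weight Z-score and for the
cumulative protein deficit -> a run manifest (config hash, seed,
library versions) so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import DeltaZModel, assign_tertiles, paired_change_test
from .compliance import (
    GuidelineTargets,
    UnitQuestionnaire,
    assess_compliance,
    compare_intended_actual,
    summarize_actual_practice,
    summarize_intended_practice,
)
from .cumulative import (
    SparseScheme,
    cumulative_deficit,
    estimate_cumulative,
    subsample_daily,
)
from .growth import GrowthReference, assess_growth, default_reference
from .intake import DailyIntake
from .records import InfantRecord
from .simulate import CohortSpec, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_patient_records",
    "read_questionnaires",
    "read_trajectories",
    "write_cohort",
    "run_pipeline",
]

PATIENT_COLUMNS = [
    "infant_id", "unit_id", "ga_weeks", "sex", "birth_weight_g",
    "birth_length_cm", "birth_hc_cm", "weight36_g", "length36_cm", "hc36_cm",
    "pca36_days", "enteral_init_dol", "full_feed_dol", "aa_start_dol",
    "lipid_start_dol", "aa_dol1_g_kg", "pn_dol1", "cvl_dol1",
    "max_weight_loss_pct",
]

TRAJECTORY_COLUMNS = ["infant_id", "dol", "aa_g_kg_d", "energy_kcal_kg_d"]


# ---------------------------------------------------------------------------
# readers


def _opt(row, name, cast):
    v = row.get(name)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return cast(v)


def read_patient_records(path) -> tuple[list[InfantRecord], list[str]]:
    """Read the patient-record CSV; invalid rows are rejected, not fatal.

    Returns the validated records and a list of row-level error
    messages carrying 1-based data line numbers (infants with GA
    outside 30-33 weeks are rejected per the cohort's inclusion rules).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = set(df.columns) - set(PATIENT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
    if df.empty:
        logger.warning("patient file %s is empty", path)
        return [], []
    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 1
        try:
            records.append(
                InfantRecord(
                    infant_id=str(row["infant_id"]),
                    unit_id=str(row["unit_id"]),
                    ga_weeks=int(row["ga_weeks"]),
                    sex=str(row["sex"]),
                    birth_weight_g=float(row["birth_weight_g"]),
                    birth_length_cm=_opt(row, "birth_length_cm", float),
                    birth_hc_cm=_opt(row, "birth_hc_cm", float),
                    weight36_g=_opt(row, "weight36_g", float),
                    length36_cm=_opt(row, "length36_cm", float),
                    hc36_cm=_opt(row, "hc36_cm", float),
                    pca36_days=_opt(row, "pca36_days", int),
                    enteral_init_dol=_opt(row, "enteral_init_dol", int),
                    full_feed_dol=_opt(row, "full_feed_dol", int),
                    aa_start_dol=_opt(row, "aa_start_dol", int),
                    lipid_start_dol=_opt(row, "lipid_start_dol", int),
                    aa_dol1_g_kg=_opt(row, "aa_dol1_g_kg", float),
                    pn_dol1=_opt(row, "pn_dol1", lambda v: bool(int(v))),
                    cvl_dol1=_opt(row, "cvl_dol1", lambda v: bool(int(v))),
                    max_weight_loss_pct=_opt(row, "max_weight_loss_pct", float),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
            logger.warning("rejected patient row %d: %s", line, exc)
    return records, errors


def read_questionnaires(path) -> list[UnitQuestionnaire]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        out.append(
            UnitQuestionnaire(
                unit_id=str(row["unit_id"]),
                ga_group=str(row["ga_group"]),
                written_guidelines=bool(int(row["written_guidelines"])),
                pn_dol1=bool(int(row["pn_dol1"])),
                cvl_for_pn=bool(int(row["cvl_for_pn"])),
                aa_init_dol=float(row["aa_init_dol"]),
                aa_init_dose=float(row["aa_init_dose"]),
                lipid_init_dol=float(row["lipid_init_dol"]),
                enteral_init_dol=float(row["enteral_init_dol"]),
                enteral_advance_ml_kg_d=float(row["enteral_advance_ml_kg_d"]),
                fortification=bool(int(row["fortification"])),
            )
        )
    return out


def read_trajectories(path) -> pd.DataFrame:
    """Long-format daily trajectory CSV (infant_id, dol, aa, energy)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    if (df[["aa_g_kg_d", "energy_kcal_kg_d"]] < 0).any().any():
        raise ValueError("trajectory rates must be >= 0")
    return df[TRAJECTORY_COLUMNS]


# ---------------------------------------------------------------------------
# writers


def _record_row(r: InfantRecord) -> dict:
    d = {c: getattr(r, c) for c in PATIENT_COLUMNS if c not in ("pn_dol1", "cvl_dol1")}
    d["pn_dol1"] = None if r.pn_dol1 is None else int(r.pn_dol1)
    d["cvl_dol1"] = None if r.cvl_dol1 is None else int(r.cvl_dol1)
    return d


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write a cohort's CSVs plus its generating spec (with seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    patients = pd.DataFrame([_record_row(r) for r in cohort.records])[PATIENT_COLUMNS]
    paths["patients"] = str(outdir / "patients.csv")
    patients.to_csv(paths["patients"], index=False)

    qrows = []
    for q in cohort.questionnaires:
        d = dataclasses.asdict(q)
        for b in ("written_guidelines", "pn_dol1", "cvl_for_pn", "fortification"):
            d[b] = int(d[b])
        qrows.append(d)
    paths["questionnaires"] = str(outdir / "questionnaires.csv")
    pd.DataFrame(qrows).to_csv(paths["questionnaires"], index=False)

    paths["trajectories"] = str(outdir / "trajectories.csv")
    cohort.trajectories.to_csv(paths["trajectories"], index=False)

    paths["spec"] = str(outdir / "cohort_spec.json")
    cohort.spec.to_json(paths["spec"])
    return paths


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    # either simulate a cohort ...
    simulate: bool = True
    cohort_spec_path: Optional[str] = None
    # ... or read one
    patients_path: Optional[str] = None
    questionnaires_path: Optional[str] = None
    trajectories_path: Optional[str] = None
    reference_path: Optional[str] = None
    targets: GuidelineTargets = field(default_factory=GuidelineTargets)
    scheme: SparseScheme = field(default_factory=SparseScheme)
    alpha: float = 0.10

    def __post_init__(self) -> None:
        if not self.simulate:
            for name in ("patients_path", "questionnaires_path", "trajectories_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} required (and must exist) when simulate=False: {p}")
        for name in ("cohort_spec_path", "reference_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "targets" in raw and isinstance(raw["targets"], dict):
            raw["targets"] = GuidelineTargets(**raw["targets"])
        if "scheme" in raw and isinstance(raw["scheme"], dict):
            s = raw["scheme"]
            raw["scheme"] = SparseScheme(
                tuple(s["sample_days"]), tuple(s["weights"]), s["horizon_days"]
            )
        return cls(**raw)

    def manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = dataclasses.asdict(self.targets)
        d["scheme"] = dataclasses.asdict(self.scheme)
        return d


# ---------------------------------------------------------------------------
# pipeline


def _daily_intake(traj_row, dol: int) -> DailyIntake:
    return DailyIntake(
        dol=dol,
        aa_g_kg_d=float(traj_row["aa_g_kg_d"]),
        energy_kcal_kg_d=float(traj_row["energy_kcal_kg_d"]),
    )


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Outputs: the cohort CSVs (when simulated), per-infant intake and
    deficit table, compliance and practice tables, growth table and
    summary, both regression tables, and ``manifest.json``.  Any stage
    failure aborts with the stage named in the exception.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    ref = (
        GrowthReference.from_csv(config.reference_path)
        if config.reference_path
        else default_reference()
    )

    stage = "cohort"
    try:
        if config.simulate:
            spec = (
                CohortSpec.from_json(config.cohort_spec_path)
                if config.cohort_spec_path
                else CohortSpec(seed=config.seed)
            )
            if spec.seed != config.seed:
                spec = dataclasses.replace(spec, seed=config.seed)
            cohort = generate_cohort(spec, ref=ref)
            records = cohort.records
            questionnaires = cohort.questionnaires
            traj = cohort.trajectories
            paths.update(write_cohort(cohort, out / "cohort"))
        else:
            records, errors = read_patient_records(config.patients_path)
            if errors:
                (out / "rejected_rows.log").write_text("\n".join(errors) + "\n")
            questionnaires = read_questionnaires(config.questionnaires_path)
            traj = read_trajectories(config.trajectories_path)

        stage = "intake"
        wide_aa = traj.pivot(index="infant_id", columns="dol", values="aa_g_kg_d")
        wide_en = traj.pivot(index="infant_id", columns="dol", values="energy_kcal_kg_d")
        rec_by_id = {r.infant_id: r for r in records}
        intake_rows = []
        for iid in wide_aa.index:
            if iid not in rec_by_id:
                continue
            r = rec_by_id[iid]
            aa_obs = subsample_daily(wide_aa.loc[iid].to_numpy(), config.scheme, "aa")
            en_obs = subsample_daily(wide_en.loc[iid].to_numpy(), config.scheme, "energy")
            aa_cum = estimate_cumulative(aa_obs, config.scheme)
            en_cum = estimate_cumulative(en_obs, config.scheme)
            aa_t, en_t = config.targets.targets_for(r.ga_weeks)
            aa_def = cumulative_deficit(aa_cum, aa_t, config.scheme.horizon_days)
            en_def = cumulative_deficit(en_cum, en_t, config.scheme.horizon_days)
            c = assess_compliance(
                DailyIntake(1, aa_obs.dol1, en_obs.dol1),
                DailyIntake(7, aa_obs.dol7, en_obs.dol7),
                config.targets,
                r.ga_weeks,
            )
            intake_rows.append(
                {
                    "infant_id": iid,
                    "aa_dol1": aa_obs.dol1, "aa_dol3": aa_obs.dol3,
                    "aa_dol7": aa_obs.dol7, "aa_dol14": aa_obs.dol14,
                    "energy_dol1": en_obs.dol1, "energy_dol7": en_obs.dol7,
                    "aa_cumulative": aa_cum, "aa_deficit": aa_def.cumulative_deficit,
                    "energy_cumulative": en_cum, "energy_deficit": en_def.cumulative_deficit,
                    "crit_aa_init": c.crit_aa_init,
                    "crit_aa_target": c.crit_aa_target,
                    "crit_energy_target": c.crit_energy_target,
                    "fully_compliant": c.fully_compliant,
                }
            )
        intake_df = pd.DataFrame(intake_rows).set_index("infant_id")
        paths["intake"] = str(out / "intake.csv")
        intake_df.to_csv(paths["intake"])

        stage = "compliance"
        actual = summarize_actual_practice(records, config.targets.aa_init_dose_min)
        intended = summarize_intended_practice(questionnaires, config.targets.aa_init_dose_min)
        comparison = compare_intended_actual(intended, actual)
        paths["practice_comparison"] = str(out / "practice_comparison.csv")
        comparison.to_csv(paths["practice_comparison"], index=False)
        crit_cols = ["crit_aa_init", "crit_aa_target", "crit_energy_target", "fully_compliant"]
        summary = (100.0 * intake_df[crit_cols].mean()).rename("pct_compliant").to_frame()
        paths["compliance_summary"] = str(out / "compliance_summary.csv")
        summary.to_csv(paths["compliance_summary"])

        stage = "growth"
        growth_rows = []
        for r in records:
            if r.weight36_g is None or r.pca36_days is None:
                continue
            a = assess_growth(
                r.birth_weight_g, r.weight36_g, r.sex, r.ga_days, r.pca36_days, ref
            )
            growth_rows.append(
                {
                    "infant_id": r.infant_id,
                    "z_birth": a.z_birth, "z_36": a.z_36, "delta_z": a.delta_z,
                    "sga": a.sga, "below_p10_at36": a.below_p10_at36, "eugr": a.eugr,
                }
            )
        growth_df = pd.DataFrame(growth_rows).set_index("infant_id")
        paths["growth"] = str(out / "growth.csv")
        growth_df.to_csv(paths["growth"])
        ptest = paired_change_test(growth_df["z_birth"], growth_df["z_36"])
        gsum = pd.DataFrame(
            [
                {
                    "measure": "weight",
                    "z_birth_mean": growth_df["z_birth"].mean(),
                    "z_birth_sd": growth_df["z_birth"].std(),
                    "z36_mean": growth_df["z_36"].mean(),
                    "z36_sd": growth_df["z_36"].std(),
                    "delta_z_mean": growth_df["delta_z"].mean(),
                    "delta_z_sd": growth_df["delta_z"].std(),
                    "paired_p": ptest.pvalue,
                    "sga_pct": 100.0 * growth_df["sga"].mean(),
                    "eugr_pct": 100.0 * growth_df["eugr"].mean(),
                    "below_p10_at36_pct": 100.0 * growth_df["below_p10_at36"].mean(),
                }
            ]
        )
        paths["growth_summary"] = str(out / "growth_summary.csv")
        gsum.to_csv(paths["growth_summary"], index=False)

        stage = "analysis"
        df = growth_df.join(intake_df[["aa_cumulative", "aa_deficit", "energy_cumulative"]])
        df["tertile_aa"] = assign_tertiles(df["aa_cumulative"], "aa_cumulative").labels
        meta = pd.DataFrame(
            {
                "infant_id": [r.infant_id for r in records],
                "unit_id": [r.unit_id for r in records],
                "ga_weeks": [r.ga_weeks for r in records],
                "full_feed_dol": [r.full_feed_dol for r in records],
                "enteral_init_dol": [r.enteral_init_dol for r in records],
                "cvl_dol1": [int(bool(r.cvl_dol1)) for r in records],
            }
        ).set_index("infant_id")
        df = df.join(meta)
        unit_mean = df.groupby("unit_id")["aa_cumulative"].transform("mean")
        df["center_tertile_aa"] = assign_tertiles(unit_mean, "center_mean_aa").labels
        df["sga_int"] = df["sga"].astype(int)

        dz_candidates = [
            "tertile_aa", "center_tertile_aa", "energy_cumulative",
            "full_feed_dol", "enteral_init_dol", "sga_int", "ga_weeks", "cvl_dol1",
        ]
        dz_res = DeltaZModel.from_dataframe(
            df.reset_index(), "delta_z", dz_candidates, alpha=config.alpha
        ).fit()
        paths["regression_delta_z"] = str(out / "regression_delta_z.csv")
        dz_res.to_frame().to_csv(paths["regression_delta_z"], index=False)

        def_candidates = [
            "center_tertile_aa", "cvl_dol1", "full_feed_dol",
            "enteral_init_dol", "ga_weeks", "sga_int",
        ]
        def_res = DeltaZModel.from_dataframe(
            df.reset_index(), "aa_deficit", def_candidates, alpha=config.alpha
        ).fit()
        paths["regression_deficit"] = str(out / "regression_deficit.csv")
        def_res.to_frame().to_csv(paths["regression_deficit"], index=False)

        stage = "manifest"
        cfg = config.manifest_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "n_records": len(records),
            "versions": {
                "neogrowth": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": sorted(paths),
            "delta_z_summary": dz_res.summary(),
            "deficit_summary": def_res.summary(),
        }
        paths["manifest"] = str(out / "manifest.json")
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths
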