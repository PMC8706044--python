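"""End-to-end orchestration: simulate or load a study, run QC, consensus
alignment, blank subtraction, partitioning, calibration, screening,
identification and OPLS-DA, and write a machine-readable manifest.

The on-disk study layout written by :func:`simulate_study_to_disk` is
exactly what :func:`run_pipeline` consumes, so a simulated study is
immediately runnable.
"""

from __future__ import annotations

import json
import logging
import re
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import io as psio
from .features import (
    ConsensusFeature,
    Tolerances,
    blank_subtract,
    consensus_features,
    consensus_to_frame,
    partition_by_column,
    qc_internal_standards,
)
from .identify import ReferenceStandardResult, confirm_with_standard, deviation_table
from .opls import build_data_matrix, cross_validated_q2, fit_opls_da, s_plot, splot_frame
from .records import (
    InstrumentProfile,
    StudyDesign,
    spectrum_for,
)
from .rti import CalibrationStandard, fit_calibration
from .scoring import ChemotaxonomyFilter, ScoringConfig, successive_elimination
from .synthetic import (
    SimulatedStudy,
    calibration_standards_table,
    default_internal_standards,
    generate_compound_db,
    generate_decoys,
    make_ground_truth,
    simulate_feature_tables,
)

log = logging.getLogger("polarscreen")


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9.-]+", "-", text)


class SimulationSettings(BaseModel):
    n_compounds: int = 50
    n_decoys: int = 100
    decoy_family: str = "Fabaceae"
    n_injections: int = 3
    solvents: list[str] = ["100% MeOH", "50% MeOH", "100% H2O"]
    instruments: list[str] = ["A", "B"]


class IdentificationSettings(BaseModel):
    rt_tol: float = 0.5
    ppm_tol: float = 5.0
    min_frag_overlap: int = 1


class OplsSettings(BaseModel):
    n_predictive: int = 1
    n_orthogonal: int = 1
    folds: int = 7
    scaling: str = "uv"
    log_transform: bool = True
    pcorr_max: float = 0.1


class PipelineConfig(BaseModel):
    """Paths, tolerances and settings of a full pipeline run."""

    study_dir: str
    out_dir: str = "polarscreen-out"
    seed: int = 0
    tolerances: dict = Field(default_factory=dict)
    scoring: dict = Field(default_factory=dict)
    identification: IdentificationSettings = IdentificationSettings()
    opls: OplsSettings = OplsSettings()
    simulation: SimulationSettings = SimulationSettings()
    allowed_families: list[str] = ["Lemnaceae"]
    blank_mode: str = "coordinate"

    def tol(self) -> Tolerances:
        d = dict(self.tolerances)
        if "rt_window" in d:
            d["rt_window"] = tuple(d["rt_window"])
        return Tolerances(**d)

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(**self.scoring)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


#: Tolerances preset mirroring vendor peak-picking settings for
#: single-TOF data (coarser ppm window, wide RT matching).  The vendor
#: semantics are not reproduced; this only widens the matching windows.
SYSTEM_A_PRESET = Tolerances(ppm_tol=10.0, rt_tol=3.0, noise_threshold=1000.0)


def default_study(seed: int = 0, n_compounds: int = 50, n_decoys: int = 100,
                  decoy_family: str = "Fabaceae") -> tuple[SimulatedStudy, list]:
    """The default synthetic study and its screening database.

    50 truth compounds, all annotated to the studied family (Lemnaceae)
    as a curated taxon database would be, plus 100 mass/LogD-matched
    decoys from a disallowed family; three solvents, instruments A and
    B, triplicate injections.
    """
    design = StudyDesign(n_injections=3, seed=seed)
    db = generate_compound_db(n_compounds, family_pool=("Lemnaceae",), seed=seed)
    decoys = generate_decoys(db, n_decoys, decoy_family=decoy_family, seed=seed + 1)
    truth = make_ground_truth(design, db)
    study = simulate_feature_tables(design, db, truth)
    return study, list(db) + list(decoys)


def simulate_study_to_disk(study_dir, seed: int = 0,
                           settings: SimulationSettings | None = None) -> Path:
    """Write a complete simulated study (tables, blanks, spectra, truth).

    The directory is immediately consumable by :func:`run_pipeline`.
    """
    settings = settings or SimulationSettings()
    study_dir = Path(study_dir)
    study, screen_db = default_study(seed=seed,
                                     n_compounds=settings.n_compounds,
                                     n_decoys=settings.n_decoys,
                                     decoy_family=settings.decoy_family)
    (study_dir / "tables").mkdir(parents=True, exist_ok=True)
    (study_dir / "blanks").mkdir(exist_ok=True)
    (study_dir / "spectra").mkdir(exist_ok=True)

    for (solvent, instr, inj), df in study.sample_tables.items():
        psio.write_feature_table(df, study_dir / "tables" / f"{instr}_{_slug(solvent)}_inj{inj}.csv")
    for (solvent, instr), df in study.blank_tables.items():
        psio.write_feature_table(df, study_dir / "blanks" / f"{instr}_{_slug(solvent)}.csv")
    for (solvent, instr), spectra in study.spectra.items():
        base = study_dir / "spectra" / f"{instr}_{_slug(solvent)}"
        psio.write_mgf(spectra, base.with_suffix(".mgf"))
        psio.write_msp(spectra, base.with_suffix(".msp"))

    psio.write_compound_db_csv(screen_db, study_dir / "compound_db.csv")
    psio.write_compound_db_json(screen_db, study_dir / "compound_db.json")
    psio.write_standards_csv(study.standards, study_dir / "internal_standards.csv")
    calibration_standards_table().to_csv(study_dir / "calibration_standards.csv", index=False)

    # reference standards for confirmation: noise-free coordinates of the
    # truth compounds, as a target injection of the standards would yield
    from .synthetic import elution_model
    ref_rows = [{
        "name": c.name, "rt_min": elution_model(c.logd_ph7),
        "mz": c.adduct_mass, "fragments": ";".join(f"{f:.5f}" for f in c.fragments),
    } for c in study.db]
    pd.DataFrame(ref_rows).to_csv(study_dir / "reference_standards.csv", index=False)

    truth_json = {
        "abundances": [{"solvent": s, "compound_id": c, "abundance": a}
                       for (s, c), a in study.truth.abundances.items()],
        "contaminants": {s: v for s, v in study.truth.contaminants.items()},
    }
    (study_dir / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    design = study.design
    (study_dir / "design.json").write_text(json.dumps({
        "solvents": list(design.solvents),
        "n_injections": design.n_injections,
        "seed": design.seed,
        "instruments": [vars(i) for i in design.instruments],
    }, indent=2))
    return study_dir


def load_study_inputs(study_dir) -> dict:
    """Read a study directory back into in-memory inputs."""
    study_dir = Path(study_dir)
    design = json.loads((study_dir / "design.json").read_text())
    instruments = [InstrumentProfile(**d) for d in design["instruments"]]
    tables = {}
    for path in sorted((study_dir / "tables").glob("*.csv")):
        df = psio.read_feature_table(path)
        solvent = str(df["sample"].iloc[0])
        instr = str(df["instrument"].iloc[0])
        inj = int(df["injection"].iloc[0])
        tables[(solvent, instr, inj)] = df
    blanks = {}
    for path in sorted((study_dir / "blanks").glob("*.csv")):
        df = psio.read_feature_table(path)
        solvent = str(df["sample"].iloc[0]).removeprefix("blank_")
        blanks[(solvent, str(df["instrument"].iloc[0]))] = df
    spectra = {}
    for path in sorted((study_dir / "spectra").glob("*.mgf")):
        instr, solvent_slug = path.stem.split("_", 1)
        solvent = next((s for s in design["solvents"] if _slug(s) == solvent_slug), solvent_slug)
        spectra[(solvent, instr)] = psio.read_mgf(path)
    return {
        "solvents": design["solvents"],
        "n_injections": design["n_injections"],
        "instruments": instruments,
        "tables": tables,
        "blanks": blanks,
        "spectra": spectra,
        "db": psio.read_compound_db_csv(study_dir / "compound_db.csv"),
        "internal_standards": psio.read_standards_csv(study_dir / "internal_standards.csv"),
        "calibration": pd.read_csv(study_dir / "calibration_standards.csv")
        if (study_dir / "calibration_standards.csv").exists() else None,
        "reference_standards": pd.read_csv(study_dir / "reference_standards.csv")
        if (study_dir / "reference_standards.csv").exists() else None,
    }


def _stage(manifest: dict, name: str, t0: float, **counts) -> None:
    # elapsed time goes to the log only, so the manifest is reproducible
    elapsed = time.perf_counter() - t0
    manifest["stages"].append({"stage": name, **counts})
    log.info("stage=%s elapsed=%.2fs %s", name, elapsed,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the run manifest.

    Stage order: QC -> consensus -> blank subtraction -> RT window +
    column partition -> RT/LogD calibration -> successive-elimination
    screening -> standard confirmation -> OPLS-DA statistics.  A QC
    failure flags the manifest but does not stop the run; missing
    calibration standards degrade RPLC scoring to mass + MS/MS with a
    warning.
    """
    study_dir = Path(config.study_dir)
    if not study_dir.exists():
        raise FileNotFoundError(f"study directory not found: {study_dir}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tol = config.tol()
    cfg = config.scoring_config()
    taxonomy = ChemotaxonomyFilter(frozenset(config.allowed_families))
    inputs = load_study_inputs(study_dir)

    manifest: dict = {"seed": config.seed, "study_dir": str(study_dir), "stages": []}

    t0 = time.perf_counter()
    qc = qc_internal_standards(
        list(inputs["tables"].values()) + list(inputs["blanks"].values()),
        inputs["internal_standards"], tol)
    (out_dir / "qc_report.json").write_text(qc.to_json())
    manifest["qc_passed"] = qc.passed
    _stage(manifest, "qc", t0, standards=len(qc.standards), passed=int(qc.passed))

    t0 = time.perf_counter()
    consensus: dict[tuple[str, str], list[ConsensusFeature]] = {}
    keys = sorted({(s, i) for (s, i, _) in inputs["tables"]})
    n_cons = 0
    for (solvent, instr) in keys:
        inj_tables = [inputs["tables"][(solvent, instr, j)]
                      for j in range(inputs["n_injections"])]
        consensus[(solvent, instr)] = consensus_features(inj_tables, tol)
        n_cons += len(consensus[(solvent, instr)])
    _stage(manifest, "consensus", t0, features=n_cons)

    t0 = time.perf_counter()
    n_after = 0
    for key in consensus:
        blank = inputs["blanks"].get(key)
        if blank is None:
            raise FileNotFoundError(f"missing blank table for {key}")
        consensus[key] = blank_subtract(consensus[key], blank, tol, mode=config.blank_mode)
        n_after += len(consensus[key])
    _stage(manifest, "blank_subtraction", t0, features=n_after)

    t0 = time.perf_counter()
    partitioned: dict[tuple[str, str], dict[str, list[ConsensusFeature]]] = {}
    n_h = n_r = 0
    for key, feats in consensus.items():
        hilic, rplc = partition_by_column(feats, tol)
        partitioned[key] = {"HILIC": hilic, "RPLC": rplc}
        n_h += len(hilic)
        n_r += len(rplc)
    _stage(manifest, "partition", t0, hilic=n_h, rplc=n_r)

    t0 = time.perf_counter()
    calib = None
    if inputs["calibration"] is not None:
        stds = [CalibrationStandard(str(r.iloc[0]), float(r.iloc[1]), float(r.iloc[2]))
                for _, r in inputs["calibration"].iterrows()]
        calib = fit_calibration(stds)
        (out_dir / "calibration.json").write_text(calib.to_json())
        _stage(manifest, "calibration", t0, n_points=calib.n_points,
               r_squared=round(calib.r_squared, 4))
    else:
        log.warning("no calibration standards; RPLC scoring degrades to mass+MS/MS")
        manifest["stages"].append({"stage": "calibration", "skipped": True})

    t0 = time.perf_counter()
    screening = {}
    stage_totals: dict[str, int] = {}
    all_hits_frames = []
    for (solvent, instr), cols in sorted(partitioned.items()):
        spectra = inputs["spectra"].get((solvent, instr), [])
        for column, feats in cols.items():
            res = successive_elimination(
                feats, inputs["db"], cfg,
                calibration=calib if column == "RPLC" else None,
                spectra=spectra, taxonomy=taxonomy, column=column)
            screening[(solvent, instr, column)] = res
            for k, v in res.stage_counts.items():
                stage_totals[k] = stage_totals.get(k, 0) + v
            frame = res.to_frame()
            if len(frame):
                frame.insert(0, "solvent", solvent)
                frame.insert(1, "instrument", instr)
                frame.insert(2, "column", column)
                all_hits_frames.append(frame)
    hits_df = pd.concat(all_hits_frames, ignore_index=True) if all_hits_frames \
        else pd.DataFrame()
    hits_df.to_csv(out_dir / "screening_hits.csv", index=False)
    manifest["screening_counts"] = stage_totals
    _stage(manifest, "screening", t0, **stage_totals)

    t0 = time.perf_counter()
    records = []
    ref_df = inputs["reference_standards"]
    if ref_df is not None:
        by_name = {}
        for _, r in ref_df.iterrows():
            frags = tuple(float(x) for x in str(r["fragments"]).split(";") if x) \
                if pd.notna(r["fragments"]) else ()
            by_name[str(r["name"])] = ReferenceStandardResult(
                str(r["name"]), float(r["rt_min"]), float(r["mz"]), frags)
        best_by_name: dict[str, object] = {}
        for (solvent, instr, column), res in sorted(screening.items()):
            spectra = inputs["spectra"].get((solvent, instr), [])
            for hit in res.survivors:
                std = by_name.get(hit.compound.name)
                if std is None:
                    continue
                sp = spectrum_for(hit.feature.mz, hit.feature.rt, spectra,
                                  ppm_tol=2 * cfg.ppm_window, rt_tol=0.3)
                rec = confirm_with_standard(
                    hit, std,
                    rt_tol=config.identification.rt_tol,
                    ppm_tol=config.identification.ppm_tol,
                    min_frag_overlap=config.identification.min_frag_overlap,
                    spectrum=sp, cfg=cfg)
                prev = best_by_name.get(rec.compound_name)
                if prev is None or (rec.level, abs(rec.delta_rt)) < (prev.level, abs(prev.delta_rt)):
                    best_by_name[rec.compound_name] = rec
        records = list(best_by_name.values())
    dev = deviation_table(records)
    dev.to_csv(out_dir / "deviation_table.csv", index=False)
    n_level1 = sum(1 for r in records if r.level == 1)
    manifest["identification"] = {"records": len(records), "level1": n_level1}
    _stage(manifest, "identification", t0, records=len(records), level1=n_level1)

    t0 = time.perf_counter()
    stats: dict = {}
    try:
        dm = build_data_matrix(consensus, tol)
        dm.to_csv(out_dir / "data_matrix.csv")
        for contrast in ("solvent", "instrument"):
            classes = dm.classes(contrast)
            if len(set(classes)) < 2:
                continue
            model = fit_opls_da(dm, classes,
                                n_predictive=config.opls.n_predictive,
                                n_orthogonal=config.opls.n_orthogonal,
                                scaling=config.opls.scaling,
                                log_transform=config.opls.log_transform)
            model.q2_cum = cross_validated_q2(
                dm, classes, folds=config.opls.folds, seed=config.seed,
                n_predictive=config.opls.n_predictive,
                n_orthogonal=config.opls.n_orthogonal,
                scaling=config.opls.scaling,
                log_transform=config.opls.log_transform)
            stats[contrast] = model.summary()
            if contrast == "instrument":
                pts = s_plot(model)
                splot_frame(pts).to_csv(out_dir / "s_plot.csv", index=False)
    except ValueError as exc:  # e.g. single class or too few samples
        log.warning("OPLS-DA skipped: %s", exc)
        stats["skipped"] = str(exc)
    (out_dir / "opls_summary.json").write_text(json.dumps(stats, indent=2))
    manifest["opls"] = stats
    _stage(manifest, "statistics", t0, models=len([k for k in stats if k != "skipped"]))

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
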