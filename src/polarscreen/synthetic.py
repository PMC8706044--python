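"""Synthetic study generator for polarity-extended LC-MS screening.

Emulates the statistical structure the downstream analysis assumes:
triplicate injections with RT jitter and ppm-scale mass error, blank
contaminants shared with samples, two instruments of different
sensitivity, bimodal elution (HILIC-eluting polar compounds before the
15-min column switch, RPLC-eluting nonpolar after), and log-normal
abundances that differ between extraction solvents.

Features are simulated directly as (m/z, RT, intensity) triples; there is
no scan-level chromatogram or isotope-pattern simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import (
    COLUMN_SWITCH_RT,
    CompoundRecord,
    GroundTruth,
    InstrumentProfile,
    InternalStandard,
    MsmsSpectrum,
    StudyDesign,
)

DEFAULT_FAMILY_POOL = ("Lemnaceae", "Poaceae", "Brassicaceae", "Nymphaeaceae")

#: Gradient endpoints (min) of the serial coupling.
RT_MIN, RT_MAX = 5.0, 34.0

#: LogD change per minute of RPLC retention in the noise-free elution
#: model; its inverse (0.25 LogD/min) is what the RT-index calibration
#: recovers from the standard mixture.
RPLC_MIN_PER_LOGD = 4.0

#: Slope (min per LogD unit) of the schematic HILIC branch; HILIC
#: retention carries no calibration information downstream, the branch
#: only has to keep polar compounds inside [5, 15) monotonically.
HILIC_MIN_PER_LOGD = 10.0 / 6.0

FEATURE_COLUMNS = ["feature_id", "mz", "rt_min", "intensity", "sample", "injection", "instrument"]


def elution_model(logd_ph7: float) -> float:
    """Noise-free retention time (min) of a compound on the serial coupling.

    Polar compounds (LogD < 0) elute from the HILIC column inside
    [5, 15) min; nonpolar compounds (LogD >= 0) from the RPLC column at
    15 min + 4 min per LogD unit, capped at the 34-min gradient end.  Both
    branches are monotone increasing, so the RPLC branch is exactly
    invertible by a linear RT-LogD calibration in the noise-free case.
    """
    if logd_ph7 < 0:
        rt = COLUMN_SWITCH_RT + HILIC_MIN_PER_LOGD * logd_ph7
        return float(min(max(rt, RT_MIN), COLUMN_SWITCH_RT - 1e-9))
    rt = COLUMN_SWITCH_RT + RPLC_MIN_PER_LOGD * logd_ph7
    return float(min(rt, RT_MAX))


def generate_compound_db(
    n_compounds: int,
    family_pool: tuple[str, ...] = DEFAULT_FAMILY_POOL,
    seed: int = 0,
    polar_weight: float = 0.5,
    mass_range: tuple[float, float] = (100.0, 600.0),
) -> list[CompoundRecord]:
    """Draw a small screening database with bimodal LogD.

    With probability ``polar_weight`` a compound is polar (LogD drawn
    uniformly in [-5.5, -0.2], HILIC-eluting), otherwise nonpolar (LogD in
    [0.1, 4.6], RPLC-eluting).  Each record carries 1-2 families from the
    pool and 2-8 characteristic fragments strictly below its [M+H]+ mass.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    if not family_pool:
        raise ValueError("family_pool must be non-empty")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_compounds):
        mass = float(rng.uniform(*mass_range))
        if rng.random() < polar_weight:
            logd = float(rng.uniform(-5.5, -0.2))
        else:
            logd = float(rng.uniform(0.1, 4.6))
        fams = {family_pool[int(rng.integers(len(family_pool)))]}
        if len(family_pool) > 1 and rng.random() < 0.3:
            fams.add(family_pool[int(rng.integers(len(family_pool)))])
        n_frag = int(rng.integers(2, 9))
        adduct = mass + 1.00728
        frags = tuple(sorted(float(m) for m in rng.uniform(50.0, adduct - 10.0, size=n_frag)))
        records.append(
            CompoundRecord(
                compound_id=f"C{i:04d}",
                name=f"compound-{i:04d}",
                monoisotopic_mass=mass,
                logd_ph7=logd,
                families=frozenset(fams),
                fragments=frags,
                literature_tag="synthetic",
            )
        )
    return records


def generate_decoys(
    db: list[CompoundRecord],
    n_decoys: int,
    decoy_family: str = "Fabaceae",
    seed: int = 0,
    same_fragments: bool = False,
) -> list[CompoundRecord]:
    """Decoy records matching true compounds in mass and LogD.

    Each decoy copies the mass/LogD of a (cyclically chosen) template so
    it passes mass screening and the LogD-sign filter, but belongs to
    ``decoy_family`` only, so the chemotaxonomy filter must remove it.  By
    default fragments are re-drawn, emulating an isobaric compound with a
    different structure; ``same_fragments=True`` yields decoys differing
    in family alone.
    """
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n_decoys):
        tpl = db[i % len(db)]
        if same_fragments:
            frags = tpl.fragments
        else:
            n_frag = int(rng.integers(2, 9))
            frags = tuple(sorted(float(m) for m in rng.uniform(50.0, tpl.adduct_mass - 10.0, size=n_frag)))
        decoys.append(
            replace(
                tpl,
                compound_id=f"Z{i:04d}",
                name=f"decoy-{i:04d}",
                families=frozenset({decoy_family}),
                fragments=frags,
                literature_tag="decoy",
            )
        )
    return decoys


def default_internal_standards() -> list[InternalStandard]:
    """The 12-substance QC mixture spiked into every sample and blank.

    Names follow a commonly used screening mixture; m/z and RT values are
    synthetic coordinates spread over both column regimes (this module
    simulates instruments, it does not reproduce any vendor list).
    """
    names = [
        "6-amino-1,3-dimethyl-5-(formylamino)uracil", "etilefrine", "sotalol",
        "vidarabine", "famotidine", "2,4-diamino-6-(hydroxymethyl)pteridine",
        "monuron", "carbetamide", "chlortoluron", "metobromuron",
        "chlorbromuron", "metconazol",
    ]
    mzs = [199.0826, 182.1176, 273.1267, 268.1040, 338.0519, 193.0832,
           199.0638, 237.1234, 213.0789, 259.0077, 292.9879, 320.1524]
    rts = [6.0, 7.5, 9.0, 10.5, 12.0, 13.5, 17.0, 19.5, 22.0, 25.0, 28.0, 31.0]
    return [InternalStandard(n, m, r) for n, m, r in zip(names, mzs, rts)]


#: Median abundance per extraction solvent (arbitrary units); solvents
#: extract the same metabolome at different efficiency.
DEFAULT_SOLVENT_MEDIANS = {"100% MeOH": 5000.0, "50% MeOH": 3500.0, "100% H2O": 2500.0}


def make_ground_truth(
    design: StudyDesign,
    db: list[CompoundRecord],
    seed: int | None = None,
    abundance_sigma: float = 1.0,
    n_contaminants: int = 15,
    solvent_medians: dict[str, float] | None = None,
) -> GroundTruth:
    """Draw log-normal abundances and blank contaminants for a study.

    Every database compound is present in every solvent (as in a real
    extract, where intensity rather than presence varies with solvent);
    abundance ~ LogNormal(ln median_solvent, ``abundance_sigma``).
    """
    if not db:
        raise ValueError("db must be non-empty")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    medians = solvent_medians or DEFAULT_SOLVENT_MEDIANS
    abundances = {}
    for solvent in design.solvents:
        mu = np.log(medians.get(solvent, 3000.0))
        for c in db:
            abundances[(solvent, c.compound_id)] = float(rng.lognormal(mu, abundance_sigma))
    contaminants = {}
    for solvent in design.solvents:
        cont = []
        for _ in range(n_contaminants):
            cont.append((float(rng.uniform(100.0, 600.0)),
                         float(rng.uniform(RT_MIN, RT_MAX)),
                         float(rng.lognormal(np.log(2000.0), 0.5))))
        contaminants[solvent] = cont
    return GroundTruth(abundances=abundances, contaminants=contaminants)


@dataclass
class SimulatedStudy:
    """Everything one simulated experiment produced."""

    design: StudyDesign
    db: list[CompoundRecord]
    truth: GroundTruth
    standards: list[InternalStandard]
    #: (solvent, instrument label, injection index) -> per-injection table
    sample_tables: dict[tuple[str, str, int], pd.DataFrame]
    #: (solvent, instrument label) -> blank table
    blank_tables: dict[tuple[str, str], pd.DataFrame]
    #: (solvent, instrument label) -> acquired fragment spectra (MS/MS instruments only)
    spectra: dict[tuple[str, str], list[MsmsSpectrum]] = field(default_factory=dict)

    def injection_tables(self, solvent: str, instrument: str) -> list[pd.DataFrame]:
        n = self.design.n_injections
        return [self.sample_tables[(solvent, instrument, i)] for i in range(n)]

    def all_tables(self) -> list[pd.DataFrame]:
        return list(self.sample_tables.values()) + list(self.blank_tables.values())


def _jitter_mz(rng: np.random.Generator, mz: float, sigma_ppm: float) -> float:
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6) if sigma_ppm > 0 else mz


def _jitter_rt(rng: np.random.Generator, rt: float, sigma: float) -> float:
    return rt + rng.normal(0.0, sigma) if sigma > 0 else rt


STANDARD_ABUNDANCE = 10000.0


def simulate_feature_tables(
    design: StudyDesign,
    db: list[CompoundRecord],
    truth: GroundTruth,
    standards: list[InternalStandard] | None = None,
    intensity_jitter_sigma: float = 0.2,
    msms_noise_peaks: int = 5,
) -> SimulatedStudy:
    """Simulate per-injection sample tables, blanks, and fragment spectra.

    Each truth compound appears in an injection with the instrument's
    ``detection_prob``; m/z is perturbed by Gaussian ppm noise, RT by
    Gaussian jitter, and intensity by a log-normal factor.  Internal
    standards go into every table (samples and blanks) at fixed abundance;
    blank contaminants appear in both the blank and the paired sample
    tables.  MS/MS-capable instruments additionally yield one fragment
    spectrum per truth compound per solvent.
    """
    if not db:
        raise ValueError("db must be non-empty")
    standards = default_internal_standards() if standards is None else standards
    db_by_id = {c.compound_id: c for c in db}
    rng = np.random.default_rng(design.seed)

    sample_tables: dict[tuple[str, str, int], pd.DataFrame] = {}
    blank_tables: dict[tuple[str, str], pd.DataFrame] = {}
    spectra: dict[tuple[str, str], list[MsmsSpectrum]] = {}

    for instr in design.instruments:
        for solvent in design.solvents:
            cont = truth.contaminants.get(solvent, [])
            for inj in range(design.n_injections):
                rows = []
                k = 0
                for cid in truth.compounds_in(solvent):
                    comp = db_by_id[cid]
                    if rng.random() >= instr.detection_prob:
                        continue
                    abundance = truth.abundances[(solvent, cid)]
                    inten = abundance * instr.intensity_scale
                    if intensity_jitter_sigma > 0:
                        inten *= float(np.exp(rng.normal(0.0, intensity_jitter_sigma)))
                    rows.append((
                        f"{instr.label}:{solvent}:i{inj}:{k:05d}",
                        _jitter_mz(rng, comp.adduct_mass, instr.mass_sigma_ppm),
                        _jitter_rt(rng, elution_model(comp.logd_ph7), instr.rt_sigma),
                        inten, solvent, inj, instr.label,
                    ))
                    k += 1
                for std in standards:
                    rows.append((
                        f"{instr.label}:{solvent}:i{inj}:{k:05d}",
                        _jitter_mz(rng, std.expected_mz, instr.mass_sigma_ppm),
                        _jitter_rt(rng, std.expected_rt, instr.rt_sigma),
                        STANDARD_ABUNDANCE * instr.intensity_scale, solvent, inj, instr.label,
                    ))
                    k += 1
                for mz, rt, inten in cont:
                    rows.append((
                        f"{instr.label}:{solvent}:i{inj}:{k:05d}",
                        _jitter_mz(rng, mz, instr.mass_sigma_ppm),
                        _jitter_rt(rng, rt, instr.rt_sigma),
                        inten * instr.intensity_scale, solvent, inj, instr.label,
                    ))
                    k += 1
                sample_tables[(solvent, instr.label, inj)] = pd.DataFrame(
                    rows, columns=FEATURE_COLUMNS)

            blank_rows = []
            k = 0
            blank_name = f"blank_{solvent}"
            for std in standards:
                blank_rows.append((
                    f"{instr.label}:{blank_name}:i0:{k:05d}",
                    _jitter_mz(rng, std.expected_mz, instr.mass_sigma_ppm),
                    _jitter_rt(rng, std.expected_rt, instr.rt_sigma),
                    STANDARD_ABUNDANCE * instr.intensity_scale, blank_name, 0, instr.label,
                ))
                k += 1
            for mz, rt, inten in cont:
                blank_rows.append((
                    f"{instr.label}:{blank_name}:i0:{k:05d}",
                    _jitter_mz(rng, mz, instr.mass_sigma_ppm),
                    _jitter_rt(rng, rt, instr.rt_sigma),
                    inten * instr.intensity_scale, blank_name, 0, instr.label,
                ))
                k += 1
            blank_tables[(solvent, instr.label)] = pd.DataFrame(
                blank_rows, columns=FEATURE_COLUMNS)

            if instr.has_msms:
                acquired = []
                for cid in truth.compounds_in(solvent):
                    comp = db_by_id[cid]
                    if not comp.fragments:
                        continue
                    sp = simulate_msms(
                        comp,
                        noise_peaks=msms_noise_peaks,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    acquired.append(replace(
                        sp,
                        precursor_mz=_jitter_mz(rng, comp.adduct_mass, instr.mass_sigma_ppm),
                        rt=_jitter_rt(rng, elution_model(comp.logd_ph7), instr.rt_sigma),
                    ))
                spectra[(solvent, instr.label)] = acquired

    return SimulatedStudy(design=design, db=db, truth=truth, standards=standards,
                          sample_tables=sample_tables, blank_tables=blank_tables,
                          spectra=spectra)


def simulate_msms(
    compound: CompoundRecord,
    noise_peaks: int = 0,
    seed: int = 0,
    signal_intensity: tuple[float, float] = (200.0, 1000.0),
    noise_intensity_max: float = 49.0,
) -> MsmsSpectrum:
    """Fragment spectrum of one compound: true fragments plus noise.

    True fragments get intensities in ``signal_intensity`` (above any
    sensible intensity threshold); noise peaks are uniform in m/z below
    the precursor with intensity below ``noise_intensity_max``, so a
    threshold of 50 counts removes them.
    """
    if not compound.fragments:
        raise ValueError(f"{compound.compound_id} has no fragments to simulate")
    rng = np.random.default_rng(seed)
    peaks = [(mz, float(rng.uniform(*signal_intensity))) for mz in compound.fragments]
    for _ in range(noise_peaks):
        peaks.append((float(rng.uniform(50.0, compound.adduct_mass)),
                      float(rng.uniform(1.0, noise_intensity_max))))
    peaks.sort()
    return MsmsSpectrum(precursor_mz=compound.adduct_mass,
                        rt=elution_model(compound.logd_ph7),
                        peaks=tuple(peaks),
                        source_id=compound.compound_id)


def calibration_standards_table(
    db_logd_range: tuple[float, float] = (0.25, 4.5),
    n_standards: int = 12,
    rt_noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference mixture for the RT-LogD calibration (RPLC regime).

    Standards with fixed LogD are placed evenly over the nonpolar range
    and given their noise-free elution RT (plus optional jitter), i.e.
    the calibration curve a target analysis of the mixture would yield.
    Columns: ``name, rt_min, logd_ph7``.
    """
    rng = np.random.default_rng(seed)
    logds = np.linspace(*db_logd_range, n_standards)
    rows = []
    for i, logd in enumerate(logds):
        rt = elution_model(float(logd))
        if rt_noise_sigma > 0:
            rt += float(rng.normal(0.0, rt_noise_sigma))
        rows.append((f"rti-standard-{i:02d}", rt, float(logd)))
    return pd.DataFrame(rows, columns=["name", "rt_min", "logd_ph7"])
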