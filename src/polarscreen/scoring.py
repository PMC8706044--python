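"""Hidden-target screening core: mass screening, MS/MS matching,
composite scoring and the successive elimination filters.

Scoring weights follow the two column regimes: HILIC candidates are
scored from mass screening and MS/MS at 50% each; RPLC candidates from
mass screening, RTI screening and MS/MS at one third each.  Candidates
are never deleted by a filter -- they are tagged with the stage that
eliminated them, so the per-stage audit trail can be recounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .features import ConsensusFeature, ppm_deviation
from .records import CompoundRecord, MsmsSpectrum, spectrum_for
from .rti import CalibrationModel, predict_logd, rti_subscore

HILIC_WEIGHTS = {"mass": 0.5, "msms": 0.5}
RPLC_WEIGHTS = {"mass": 1.0 / 3.0, "rti": 1.0 / 3.0, "msms": 1.0 / 3.0}


@dataclass(frozen=True)
class ScoringConfig:
    """Tolerances and weighting for candidate scoring.

    ``renormalize_missing``: when a sub-score is unavailable (e.g. no
    MS/MS on a single-TOF system) the default is to let it contribute 0
    at full weight; with renormalization the remaining weights are
    rescaled to sum to 1 instead.
    """

    ppm_window: float = 5.0
    msms_mz_tol: float = 0.05
    msms_intensity_threshold: float = 50.0
    rti_scale: float = 2.0
    renormalize_missing: bool = False

    def weights(self, column: str) -> dict[str, float]:
        if column == "HILIC":
            return dict(HILIC_WEIGHTS)
        if column == "RPLC":
            return dict(RPLC_WEIGHTS)
        raise ValueError(f"unknown column regime: {column}")


@dataclass
class CandidateHit:
    """One (feature, compound) pairing with its evidence scores."""

    feature: ConsensusFeature
    compound: CompoundRecord
    ppm: float
    mass_subscore: float
    msms_subscore: Optional[float] = None
    rti_subscore: Optional[float] = None
    composite: float = 0.0
    look_at: bool = False
    eliminated_by: Optional[str] = None

    @property
    def retained(self) -> bool:
        return self.eliminated_by is None


def mass_screen(
    feature: ConsensusFeature,
    db: Sequence[CompoundRecord],
    cfg: ScoringConfig = ScoringConfig(),
) -> list[CandidateHit]:
    """Database compounds whose [M+H]+ lies within the ppm window.

    The mass sub-score falls linearly from 1 at exact agreement to 0 at
    the edge of the window (still a candidate at exactly the edge).
    """
    if not db:
        raise ValueError("compound database is empty")
    hits = []
    for comp in db:
        ppm = ppm_deviation(comp.adduct_mass, feature.mz)
        if abs(ppm) <= cfg.ppm_window:
            hits.append(CandidateHit(
                feature=feature, compound=comp, ppm=ppm,
                mass_subscore=1.0 - abs(ppm) / cfg.ppm_window,
            ))
    return hits


def msms_subscore(
    spectrum: MsmsSpectrum,
    compound: CompoundRecord,
    cfg: ScoringConfig = ScoringConfig(),
) -> Optional[float]:
    """Fraction of the compound's characteristic fragments found in a spectrum.

    Peaks below the intensity threshold are discarded first; each
    surviving peak may explain at most one fragment, with assignment by
    closest m/z.  ``None`` (not 0) when the compound carries no fragment
    list, so the caller can treat the evidence as absent.
    """
    if not compound.fragments:
        return None
    peaks = [(mz, inten) for mz, inten in spectrum.peaks
             if inten >= cfg.msms_intensity_threshold]
    # closest-m/z one-to-one assignment between peaks and fragments
    pairs = []
    for pi, (pmz, _) in enumerate(peaks):
        for fi, fmz in enumerate(compound.fragments):
            d = abs(pmz - fmz)
            if d <= cfg.msms_mz_tol:
                pairs.append((d, pi, fi))
    pairs.sort()
    used_peaks: set[int] = set()
    matched: set[int] = set()
    for _, pi, fi in pairs:
        if pi in used_peaks or fi in matched:
            continue
        used_peaks.add(pi)
        matched.add(fi)
    return len(matched) / len(compound.fragments)


def composite_and_flag(
    hits: Sequence[CandidateHit],
    cfg: ScoringConfig,
    column: str,
) -> list[CandidateHit]:
    """Combine sub-scores into a percent composite and mark 'look at'.

    All hits must belong to one feature.  The composite is 100 x the
    weighted sum of available sub-scores (absent sub-scores contribute 0
    unless renormalization is configured).  Exactly one hit per feature
    gets ``look_at=True``: the maximal composite, ties broken by smaller
    |ppm|, then lexicographic compound id.
    """
    hits = list(hits)
    if not hits:
        return hits
    if len({h.feature.feature_id for h in hits}) > 1:
        raise ValueError("composite_and_flag expects hits of a single feature")
    weights = cfg.weights(column)
    for h in hits:
        sub = {"mass": h.mass_subscore, "msms": h.msms_subscore, "rti": h.rti_subscore}
        avail = {k: w for k, w in weights.items() if sub.get(k) is not None}
        if cfg.renormalize_missing and avail:
            total = sum(avail.values())
            score = sum(w / total * sub[k] for k, w in avail.items())
        else:
            score = sum(w * sub[k] for k, w in avail.items())
        h.composite = 100.0 * score
        h.look_at = False
    best = min(hits, key=lambda h: (-h.composite, abs(h.ppm), h.compound.compound_id))
    best.look_at = True
    return hits


def logd_sign_filter(hits: Sequence[CandidateHit], column: str) -> list[CandidateHit]:
    """Eliminate candidates whose LogD sign contradicts the column regime.

    HILIC features come from the hydrophilic column, so candidates with
    LogD > 0 are eliminated (LogD = 0 retained); RPLC features are
    nonpolar, so candidates with LogD <= 0 are eliminated.  Elimination
    is a tag; hits stay in the list for the audit trail.
    """
    for h in hits:
        if h.eliminated_by is not None:
            continue
        logd = h.compound.logd_ph7
        if (column == "HILIC" and logd > 0) or (column == "RPLC" and logd <= 0):
            h.eliminated_by = "logd_filter"
    return list(hits)


@dataclass(frozen=True)
class ChemotaxonomyFilter:
    """Retain candidates reported from an allowed plant family."""

    allowed_families: frozenset[str] = frozenset({"Lemnaceae"})

    def __post_init__(self) -> None:
        if not self.allowed_families:
            raise ValueError("allowed_families must be non-empty")


def chemotaxonomy_filter(
    hits: Sequence[CandidateHit],
    filt: ChemotaxonomyFilter = ChemotaxonomyFilter(),
) -> list[CandidateHit]:
    """Tag candidates whose families miss the allowed set."""
    for h in hits:
        if h.eliminated_by is not None:
            continue
        if not (h.compound.families & filt.allowed_families):
            h.eliminated_by = "chemotaxonomy"
    return list(hits)


@dataclass
class ScreeningResult:
    """Outcome of the successive elimination for one column regime."""

    column: str
    hits: list[CandidateHit]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def survivors(self) -> list[CandidateHit]:
        return [h for h in self.hits if h.look_at and h.eliminated_by is None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "feature_id": h.feature.feature_id,
            "compound_id": h.compound.compound_id,
            "compound_name": h.compound.name,
            "ppm": h.ppm,
            "mass_subscore": h.mass_subscore,
            "rti_subscore": float("nan") if h.rti_subscore is None else h.rti_subscore,
            "msms_subscore": float("nan") if h.msms_subscore is None else h.msms_subscore,
            "composite": h.composite,
            "look_at": h.look_at,
            "eliminated_by": h.eliminated_by or "",
        } for h in self.hits])


def successive_elimination(
    features: Sequence[ConsensusFeature],
    db: Sequence[CompoundRecord],
    cfg: ScoringConfig = ScoringConfig(),
    calibration: Optional[CalibrationModel] = None,
    spectra: Sequence[MsmsSpectrum] = (),
    taxonomy: ChemotaxonomyFilter = ChemotaxonomyFilter(),
    column: Optional[str] = None,
) -> ScreeningResult:
    """Full prioritization pipeline over one column regime's features.

    Stage order: mass screen -> RTI sub-score (RPLC, if calibrated) ->
    MS/MS sub-score (when a spectrum was acquired for the precursor) ->
    composite + 'look at' flag -> keep 'look at' hits -> LogD sign
    filter -> chemotaxonomy filter.  The stage counts record how many
    candidates remain in play after each stage (monotone non-increasing).
    """
    features = list(features)
    if column is None:
        columns = {f.column for f in features}
        if len(columns) > 1:
            raise ValueError("features span both column regimes; pass them separately")
        column = columns.pop() if columns else "HILIC"

    all_hits: list[CandidateHit] = []
    for f in features:
        hits = mass_screen(f, db, cfg)
        if not hits:
            continue
        if column == "RPLC" and calibration is not None:
            pred = predict_logd(calibration, f.rt)
            for h in hits:
                h.rti_subscore = rti_subscore(pred.logd, h.compound.logd_ph7, cfg.rti_scale)
        sp = spectrum_for(f.mz, f.rt, spectra,
                          ppm_tol=2 * cfg.ppm_window, rt_tol=0.3) if spectra else None
        if sp is not None:
            for h in hits:
                h.msms_subscore = msms_subscore(sp, h.compound, cfg)
        composite_and_flag(hits, cfg, column)
        all_hits.extend(hits)

    counts = {"candidates": len(all_hits)}
    look = [h for h in all_hits if h.look_at]
    for h in all_hits:
        if not h.look_at:
            h.eliminated_by = h.eliminated_by or "not_look_at"
    counts["look_at"] = len(look)
    logd_sign_filter(look, column)
    counts["after_logd_filter"] = sum(1 for h in look if h.eliminated_by is None)
    chemotaxonomy_filter(look, taxonomy)
    counts["after_chemotaxonomy"] = sum(1 for h in look if h.eliminated_by is None)
    return ScreeningResult(column=column, hits=all_hits, stage_counts=counts)
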