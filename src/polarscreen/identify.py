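"""Reference-standard confirmation and the 5-level identification scheme.

Level 1: confirmed against an injected reference standard (RT, accurate
mass and at least one shared fragment).  Level 2: annotated from RT
behavior, accurate mass, fragmentation and chemotaxonomy without a
standard.  Level 3: accurate mass plus fragments compared across
laboratories.  Level 4: molecular formula or fragments only.  Level 5:
mass recognition without further information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .features import ppm_deviation
from .records import COLUMN_SWITCH_RT, MsmsSpectrum
from .scoring import CandidateHit, ScoringConfig, msms_subscore


@dataclass(frozen=True)
class ReferenceStandardResult:
    """Coordinates measured from an injected reference standard."""

    name: str
    rt: float
    mz: float
    fragments: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("standard mz must be > 0")


@dataclass
class IdentificationRecord:
    """A compound with its evidence bundle and confidence level."""

    compound_name: str
    level: int
    column: str
    rt_standard: Optional[float] = None
    rt_measured: Optional[float] = None
    mass_standard: Optional[float] = None
    mass_measured: Optional[float] = None
    fragments_matched: int = 0
    fragments_total: int = 0
    chemotaxonomy_ok: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 5:
            raise ValueError(f"level must be 1-5, got {self.level}")

    @property
    def delta_rt(self) -> Optional[float]:
        """Signed RT deviation, standard minus measured (min)."""
        if self.rt_standard is None or self.rt_measured is None:
            return None
        return self.rt_standard - self.rt_measured

    @property
    def delta_ppm(self) -> Optional[float]:
        """Signed mass deviation, (standard - measured)/standard in ppm."""
        if self.mass_standard is None or self.mass_measured is None:
            return None
        return ppm_deviation(self.mass_standard, self.mass_measured)


def confirm_with_standard(
    hit: CandidateHit,
    std: ReferenceStandardResult,
    rt_tol: float = 0.5,
    ppm_tol: float = 5.0,
    min_frag_overlap: int = 1,
    spectrum: Optional[MsmsSpectrum] = None,
    cfg: ScoringConfig = ScoringConfig(),
) -> IdentificationRecord:
    """Promote a surviving candidate to level 1 when the standard agrees.

    The record stays at level 2 when RT, mass or fragment agreement with
    the injected standard fails the thresholds.  Deviations are recorded
    signed (standard minus measured).  ``rt_tol`` defaults to 0.5 min; a
    permissive 1.0 min threshold admits stragglers with larger RT shifts.
    """
    if std.name != hit.compound.name:
        raise ValueError(f"standard {std.name!r} does not match candidate {hit.compound.name!r}")
    frag_total = len(std.fragments)
    frag_matched = 0
    if spectrum is not None and std.fragments:
        ref = hit.compound
        # count std fragments explained by the measured spectrum, same
        # closest-m/z one-to-one matching as candidate scoring
        from dataclasses import replace
        probe = replace(ref, fragments=std.fragments)
        frac = msms_subscore(spectrum, probe, cfg)
        frag_matched = round((frac or 0.0) * frag_total)
    d_rt = std.rt - hit.feature.rt
    d_ppm = ppm_deviation(std.mz, hit.feature.mz)
    confirmed = (abs(d_rt) <= rt_tol and abs(d_ppm) <= ppm_tol
                 and frag_matched >= min_frag_overlap)
    return IdentificationRecord(
        compound_name=hit.compound.name,
        level=1 if confirmed else 2,
        column=hit.feature.column,
        rt_standard=std.rt,
        rt_measured=hit.feature.rt,
        mass_standard=std.mz,
        mass_measured=hit.feature.mz,
        fragments_matched=frag_matched,
        fragments_total=frag_total,
        chemotaxonomy_ok=hit.eliminated_by is None,
    )


def assign_level(
    evidence: dict,
    has_standard: bool = False,
    has_fragments: bool = False,
    has_formula: bool = False,
) -> int:
    """Map an evidence bundle onto the 5-level confidence scheme.

    ``evidence`` may carry boolean keys ``accurate_mass`` (default True),
    ``rt_behavior`` and ``chemotaxonomy``.  A standard confirmation
    without an accurate mass is contradictory and raises.
    """
    mass = bool(evidence.get("accurate_mass", True))
    rt_ok = bool(evidence.get("rt_behavior", False))
    chemo = bool(evidence.get("chemotaxonomy", False))
    if has_standard:
        if not mass:
            raise ValueError("standard confirmation without accurate mass is contradictory")
        return 1
    if mass and rt_ok and has_fragments and chemo:
        return 2
    if mass and has_fragments:
        return 3
    if has_formula or has_fragments:
        return 4
    if mass:
        return 5
    raise ValueError("no usable evidence supplied")


def deviation_table(records: Sequence[IdentificationRecord]) -> pd.DataFrame:
    """Standard-vs-measured deviation report for confirmed annotations.

    One row per record of level <= 2 with both coordinate sets, sorted by
    standard RT; deltas are signed (standard minus measured) and rounded
    to one decimal place as conventionally reported.
    """
    rows = []
    for r in records:
        if r.level > 2 or r.rt_standard is None:
            continue
        rows.append({
            "name": r.compound_name,
            "rt_standard_min": r.rt_standard,
            "rt_measured_min": r.rt_measured,
            "delta_rt_min": round(r.delta_rt, 1),
            "mass_standard": r.mass_standard,
            "mass_measured": r.mass_measured,
            "delta_ppm": round(r.delta_ppm, 1),
            "fragments_matched": r.fragments_matched,
            "fragments_total": r.fragments_total,
            "column": r.column,
            "level": r.level,
        })
    df = pd.DataFrame(rows, columns=[
        "name", "rt_standard_min", "rt_measured_min", "delta_rt_min",
        "mass_standard", "mass_measured", "delta_ppm",
        "fragments_matched", "fragments_total", "column", "level"])
    return df.sort_values("rt_standard_min", kind="stable").reset_index(drop=True)
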