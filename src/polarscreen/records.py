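"""Core domain records shared across the screening pipeline.

Masses are neutral monoisotopic Da unless a field name says otherwise;
retention times are minutes on the serial RPLC-HILIC gradient; LogD is the
octanol-water distribution coefficient at pH 7 (dimensionless, negative =
hydrophilic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

#: Mass of a proton in Da; [M+H]+ = M + PROTON_MASS.
PROTON_MASS = 1.00728

#: Retention time (min) at which the serial coupling switches from
#: HILIC-dominated to RPLC-dominated elution.  Features before this point
#: are treated as HILIC (expected LogD < 0), at/after it as RPLC.
COLUMN_SWITCH_RT = 15.0


@dataclass(frozen=True)
class CompoundRecord:
    """One entry of the screening compound database.

    ``families`` holds the plant families the compound has been reported
    from; it drives the chemotaxonomy filter.  ``fragments`` are the
    characteristic MS/MS fragment m/z values used for spectral matching.
    """

    compound_id: str
    name: str
    monoisotopic_mass: float
    logd_ph7: float
    families: frozenset[str]
    fragments: tuple[float, ...] = ()
    literature_tag: str = ""

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"monoisotopic_mass must be > 0, got {self.monoisotopic_mass}")
        if not self.families:
            raise ValueError("families must be non-empty")
        if any(f >= self.adduct_mass for f in self.fragments):
            raise ValueError("fragments must all lie below the [M+H]+ mass")

    @property
    def adduct_mass(self) -> float:
        """Protonated-molecule m/z, the only ion species scored by default."""
        return self.monoisotopic_mass + PROTON_MASS


@dataclass(frozen=True)
class InternalStandard:
    """A spiked QC standard with its expected coordinates."""

    name: str
    expected_mz: float
    expected_rt: float
    concentration_um: float = 5.0


@dataclass(frozen=True)
class InstrumentProfile:
    """Detection characteristics of one mass spectrometer.

    ``detection_prob`` is the per-injection probability that a truly
    present compound yields a feature; ``intensity_scale`` multiplies all
    abundances; ``has_msms`` controls whether fragment spectra are
    acquired (QTOF-class instruments) or not (single-TOF-class).
    """

    label: str
    mass_sigma_ppm: float = 1.5
    rt_sigma: float = 0.05
    detection_prob: float = 0.95
    intensity_scale: float = 1.0
    has_msms: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must lie in [0, 1]")


def default_instruments() -> tuple[InstrumentProfile, InstrumentProfile]:
    """The two default spectrometer profiles.

    System A emulates an older single-TOF: lower per-injection detection
    probability, attenuated intensities, no fragment spectra.  System B
    emulates a newer QTOF with MS/MS.
    """
    return (
        InstrumentProfile("A", mass_sigma_ppm=2.0, rt_sigma=0.05,
                          detection_prob=0.85, intensity_scale=0.7, has_msms=False),
        InstrumentProfile("B", mass_sigma_ppm=1.5, rt_sigma=0.05,
                          detection_prob=0.95, intensity_scale=1.0, has_msms=True),
    )


DEFAULT_SOLVENTS = ("100% MeOH", "50% MeOH", "100% H2O")


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated extraction/injection study."""

    solvents: tuple[str, ...] = DEFAULT_SOLVENTS
    instruments: tuple[InstrumentProfile, ...] = field(default_factory=default_instruments)
    n_injections: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")


@dataclass
class GroundTruth:
    """True sample composition behind a simulated study.

    ``abundances`` maps (solvent, compound_id) to the true abundance
    (arbitrary units, log-normal across compounds); ``contaminants`` maps
    solvent to the (mz, rt, intensity) triples spiked into both blank and
    sample tables.
    """

    abundances: dict[tuple[str, str], float]
    contaminants: dict[str, list[tuple[float, float, float]]]

    def compounds_in(self, solvent: str) -> list[str]:
        return [cid for (sol, cid) in self.abundances if sol == solvent]


@dataclass(frozen=True)
class MsmsSpectrum:
    """A fragment spectrum attached to a precursor coordinate."""

    precursor_mz: float
    rt: float
    peaks: tuple[tuple[float, float], ...]
    source_id: Optional[str] = None

    @property
    def mz_values(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)


def spectrum_for(feature_mz: float, feature_rt: float,
                 spectra: Sequence[MsmsSpectrum],
                 ppm_tol: float = 10.0, rt_tol: float = 0.3) -> Optional[MsmsSpectrum]:
    """Locate the acquired spectrum whose precursor matches a feature.

    Nearest precursor m/z within ``ppm_tol`` and ``rt_tol`` wins; ``None``
    when no spectrum was acquired in the window (e.g. single-TOF data).
    """
    best = None
    best_d = None
    for sp in spectra:
        d_ppm = abs(sp.precursor_mz - feature_mz) / feature_mz * 1e6
        if d_ppm <= ppm_tol and abs(sp.rt - feature_rt) <= rt_tol:
            key = (d_ppm, abs(sp.rt - feature_rt))
            if best_d is None or key < best_d:
                best, best_d = sp, key
    return best
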