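"""Feature-table processing: QC, triplicate consensus, blank subtraction,
and the HILIC/RPLC partition.

Per-injection feature tables are pandas DataFrames with columns
``feature_id, mz, rt_min, intensity, sample, injection, instrument``
(the dialect written by :mod:`polarscreen.synthetic`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import COLUMN_SWITCH_RT, InternalStandard


def ppm_deviation(mass_ref: float, mass_obs: float) -> float:
    """Signed relative mass error in ppm: (ref - obs) / ref * 1e6.

    Positive when the observed mass reads low relative to the reference.
    """
    if mass_ref <= 0:
        raise ValueError("mass_ref must be > 0")
    return (mass_ref - mass_obs) / mass_ref * 1e6


@dataclass(frozen=True)
class Tolerances:
    """Matching tolerances and filters for feature processing.

    Defaults follow QTOF-class screening practice: 5 ppm mass tolerance,
    0.3 min RT tolerance, a 5-34 min usable RT window, a 50-count noise
    threshold, and a blank subtraction factor of 1.
    """

    ppm_tol: float = 5.0
    rt_tol: float = 0.3
    rt_window: tuple[float, float] = (5.0, 34.0)
    noise_threshold: float = 50.0
    blank_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ppm_tol, self.rt_tol, self.noise_threshold, self.blank_factor) <= 0:
            raise ValueError("all tolerances must be positive")
        if self.rt_window[0] >= self.rt_window[1]:
            raise ValueError("rt_window must be increasing")


@dataclass
class ConsensusFeature:
    """A feature confirmed in every injection of one sample.

    ``mz``/``rt`` are unweighted means over the supporting per-injection
    features; ``column`` is HILIC for rt < 15 min, RPLC otherwise.
    """

    feature_id: str
    mz: float
    rt: float
    intensities: tuple[float, ...]
    n_injections_found: int
    sample: str
    instrument: str
    member_ids: tuple[str, ...] = ()

    @property
    def intensity(self) -> float:
        return float(np.mean(self.intensities))

    @property
    def column(self) -> str:
        return "HILIC" if self.rt < COLUMN_SWITCH_RT else "RPLC"


@dataclass
class StandardQC:
    """QC summary for one internal standard across all tables."""

    name: str
    n_found: int
    n_tables: int
    mean_mz: float | None
    delta_ppm: float | None
    rt_sd: float | None
    missing: bool


@dataclass
class QCReport:
    """Mass-accuracy and RT-stability report over the spiked standards."""

    standards: list[StandardQC]
    ppm_tol: float
    rt_tol: float

    @property
    def passed(self) -> bool:
        found = [s for s in self.standards if not s.missing]
        if not found:
            return False
        return all(abs(s.delta_ppm) <= self.ppm_tol and s.rt_sd <= self.rt_tol
                   for s in found)

    def to_json(self) -> str:
        return json.dumps({
            "passed": self.passed,
            "ppm_tol": self.ppm_tol,
            "rt_tol": self.rt_tol,
            "standards": [asdict(s) for s in self.standards],
        }, indent=2)

    def to_text(self) -> str:
        lines = [f"QC {'PASS' if self.passed else 'FAIL'} "
                 f"(|dppm| <= {self.ppm_tol}, RT SD <= {self.rt_tol} min)"]
        for s in self.standards:
            if s.missing:
                lines.append(f"  {s.name}: MISSING ({s.n_found}/{s.n_tables} tables)")
            else:
                lines.append(f"  {s.name}: dppm={s.delta_ppm:+.2f} rt_sd={s.rt_sd:.3f} "
                             f"({s.n_found}/{s.n_tables})")
        return "\n".join(lines)


def qc_internal_standards(
    tables: Iterable[pd.DataFrame],
    standards: Sequence[InternalStandard],
    tol: Tolerances = Tolerances(),
) -> QCReport:
    """Mass deviation and RT stability of the spiked standards.

    Per standard and table, the nearest feature within 10x the working
    tolerances is taken as the standard's detection; the mean observed
    m/z gives the ppm deviation versus the expected mass and the RT
    standard deviation across tables measures retention stability.  A
    standard absent from more than half the tables is flagged missing
    rather than failing the run.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables supplied")
    report = []
    for std in standards:
        mzs, rts = [], []
        for t in tables:
            d_ppm = (t["mz"] - std.expected_mz).abs() / std.expected_mz * 1e6
            d_rt = (t["rt_min"] - std.expected_rt).abs()
            cand = t[(d_ppm <= 10 * tol.ppm_tol) & (d_rt <= 10 * tol.rt_tol)]
            if cand.empty:
                continue
            best = cand.loc[(cand["mz"] - std.expected_mz).abs().idxmin()]
            mzs.append(float(best["mz"]))
            rts.append(float(best["rt_min"]))
        missing = len(mzs) <= len(tables) / 2
        if mzs:
            mean_mz = float(np.mean(mzs))
            dppm = ppm_deviation(std.expected_mz, mean_mz)
            rt_sd = float(np.std(rts, ddof=0))
        else:
            mean_mz = dppm = rt_sd = None
        report.append(StandardQC(std.name, len(mzs), len(tables),
                                 mean_mz, dppm, rt_sd, missing))
    return QCReport(standards=report, ppm_tol=tol.ppm_tol, rt_tol=tol.rt_tol)


def consensus_features(
    injection_tables: Sequence[pd.DataFrame],
    tol: Tolerances = Tolerances(),
) -> list[ConsensusFeature]:
    """Align replicate injections and keep features found in all of them.

    After dropping intensities below the noise threshold, features from
    all injections are pooled and grouped greedily: seeds are visited in
    descending intensity (ties: ascending m/z, then table order); for each
    seed, every injection contributes its unused feature closest in m/z
    (ties: closest RT) within ``ppm_tol`` and ``rt_tol`` of the seed.  A
    group is accepted only when every injection contributes; consensus
    m/z and RT are unweighted means over the members.
    """
    if len(injection_tables) < 2:
        raise ValueError("need at least 2 injection tables")
    samples = {str(t["sample"].iloc[0]) for t in injection_tables if len(t)}
    instruments = {str(t["instrument"].iloc[0]) for t in injection_tables if len(t)}
    if len(samples) > 1 or len(instruments) > 1:
        raise ValueError(f"mixed sample/instrument labels: {samples}, {instruments}")
    sample = samples.pop() if samples else ""
    instrument = instruments.pop() if instruments else ""

    n_inj = len(injection_tables)
    pool = []  # (intensity, mz, rt, injection_slot, feature_id)
    for slot, t in enumerate(injection_tables):
        t = t[t["intensity"] >= tol.noise_threshold]
        for row in t.itertuples(index=False):
            pool.append((float(row.intensity), float(row.mz), float(row.rt_min),
                         slot, str(row.feature_id)))
    order = sorted(range(len(pool)), key=lambda i: (-pool[i][0], pool[i][1], i))
    used = [False] * len(pool)
    by_slot: list[list[int]] = [[] for _ in range(n_inj)]
    for i, rec in enumerate(pool):
        by_slot[rec[3]].append(i)

    out = []
    g = 0
    for i in order:
        if used[i]:
            continue
        _, seed_mz, seed_rt, _, _ = pool[i]
        members = []
        ok = True
        for slot in range(n_inj):
            best = None
            best_key = None
            for j in by_slot[slot]:
                if used[j]:
                    continue
                _, mz, rt, _, _ = pool[j]
                if abs(mz - seed_mz) / seed_mz * 1e6 > tol.ppm_tol:
                    continue
                if abs(rt - seed_rt) > tol.rt_tol:
                    continue
                key = (abs(mz - seed_mz), abs(rt - seed_rt), j)
                if best_key is None or key < best_key:
                    best, best_key = j, key
            if best is None:
                ok = False
                break
            members.append(best)
        if ok:
            for j in members:
                used[j] = True
            mzs = [pool[j][1] for j in members]
            rts = [pool[j][2] for j in members]
            out.append(ConsensusFeature(
                feature_id=f"{instrument}:{sample}:g{g:05d}",
                mz=float(np.mean(mzs)),
                rt=float(np.mean(rts)),
                intensities=tuple(pool[j][0] for j in sorted(members, key=lambda j: pool[j][3])),
                n_injections_found=n_inj,
                sample=sample,
                instrument=instrument,
                member_ids=tuple(pool[j][4] for j in sorted(members, key=lambda j: pool[j][3])),
            ))
            g += 1
        else:
            used[i] = True  # unmatched seed is consumed, never revisited
    return out


def blank_subtract(
    features: Sequence[ConsensusFeature],
    blank: pd.DataFrame,
    tol: Tolerances = Tolerances(),
    mode: str = "coordinate",
) -> list[ConsensusFeature]:
    """Remove sample features that also occur in the paired blank.

    In ``coordinate`` mode (default, blank factor 1) any blank feature
    matching within ``ppm_tol`` and ``rt_tol`` removes the sample feature.
    In ``ratio`` mode removal additionally requires the sample intensity
    not to exceed ``blank_factor`` times the blank intensity.
    """
    if mode not in ("coordinate", "ratio"):
        raise ValueError(f"unknown blank subtraction mode: {mode}")
    if blank is None or blank.empty:
        return list(features)
    b_mz = blank["mz"].to_numpy()
    b_rt = blank["rt_min"].to_numpy()
    b_int = blank["intensity"].to_numpy()
    out = []
    for f in features:
        hit = (np.abs(b_mz - f.mz) / f.mz * 1e6 <= tol.ppm_tol) & (np.abs(b_rt - f.rt) <= tol.rt_tol)
        if mode == "ratio":
            hit = hit & (f.intensity <= tol.blank_factor * b_int)
        if not hit.any():
            out.append(f)
    return out


def partition_rt(rts: Sequence[float] | np.ndarray,
                 rt_window: tuple[float, float] = (5.0, 34.0)) -> pd.DataFrame:
    """Classify retention times into column regimes.

    Returns a DataFrame with ``rt_min``, ``in_window`` and ``column``
    (HILIC for rt < 15 min, RPLC for rt >= 15; the 15.0 boundary is
    assigned to RPLC by convention).
    """
    rts = np.asarray(rts, dtype=float)
    in_window = (rts >= rt_window[0]) & (rts <= rt_window[1])
    column = np.where(rts < COLUMN_SWITCH_RT, "HILIC", "RPLC")
    return pd.DataFrame({"rt_min": rts, "in_window": in_window, "column": column})


def partition_by_column(
    features: Sequence[ConsensusFeature],
    tol: Tolerances = Tolerances(),
) -> tuple[list[ConsensusFeature], list[ConsensusFeature]]:
    """Split features into (HILIC, RPLC) lists, RT-sorted.

    The usable RT window is applied first; features outside it are
    dropped from both lists.
    """
    lo, hi = tol.rt_window
    kept = [f for f in features if lo <= f.rt <= hi]
    hilic = sorted((f for f in kept if f.rt < COLUMN_SWITCH_RT), key=lambda f: f.rt)
    rplc = sorted((f for f in kept if f.rt >= COLUMN_SWITCH_RT), key=lambda f: f.rt)
    return hilic, rplc


def consensus_to_frame(features: Sequence[ConsensusFeature]) -> pd.DataFrame:
    """Tabular view of a consensus set (for export and joins)."""
    return pd.DataFrame([{
        "feature_id": f.feature_id, "mz": f.mz, "rt_min": f.rt,
        "intensity": f.intensity, "n_injections_found": f.n_injections_found,
        "column": f.column, "sample": f.sample, "instrument": f.instrument,
    } for f in features])
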