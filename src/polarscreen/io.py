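"""Reading and writing the pipeline's delimited-text formats.

Feature tables use the dialect
``feature_id,mz,rt_min,intensity,sample,injection,instrument``; the
compound database round-trips through CSV (families and fragments as
';'-separated lists) and JSON; spectra are exported as MSP and MGF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import CompoundRecord, InternalStandard, MsmsSpectrum
from .synthetic import FEATURE_COLUMNS


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature-table columns {sorted(missing)}")
    return df


def write_compound_db_csv(db: Sequence[CompoundRecord], path) -> None:
    rows = [{
        "compound_id": c.compound_id,
        "name": c.name,
        "monoisotopic_mass": c.monoisotopic_mass,
        "logd_ph7": c.logd_ph7,
        "families": ";".join(sorted(c.families)),
        "fragments": ";".join(f"{f:.5f}" for f in c.fragments),
    } for c in db]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_compound_db_csv(path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        frags = tuple(float(x) for x in str(r.fragments).split(";") if x) if pd.notna(r.fragments) else ()
        out.append(CompoundRecord(
            compound_id=str(r.compound_id), name=str(getattr(r, "name")),
            monoisotopic_mass=float(r.monoisotopic_mass),
            logd_ph7=float(r.logd_ph7),
            families=frozenset(str(r.families).split(";")),
            fragments=frags,
        ))
    return out


def write_compound_db_json(db: Sequence[CompoundRecord], path) -> None:
    data = [{
        "compound_id": c.compound_id, "name": c.name,
        "monoisotopic_mass": c.monoisotopic_mass, "logd_ph7": c.logd_ph7,
        "families": sorted(c.families), "fragments": list(c.fragments),
        "literature_tag": c.literature_tag,
    } for c in db]
    Path(path).write_text(json.dumps(data, indent=2))


def read_compound_db_json(path) -> list[CompoundRecord]:
    data = json.loads(Path(path).read_text())
    return [CompoundRecord(
        compound_id=d["compound_id"], name=d["name"],
        monoisotopic_mass=d["monoisotopic_mass"], logd_ph7=d["logd_ph7"],
        families=frozenset(d["families"]), fragments=tuple(d["fragments"]),
        literature_tag=d.get("literature_tag", ""),
    ) for d in data]


def write_standards_csv(standards: Sequence[InternalStandard], path) -> None:
    pd.DataFrame([{
        "name": s.name, "expected_mz": s.expected_mz,
        "expected_rt": s.expected_rt, "concentration_um": s.concentration_um,
    } for s in standards]).to_csv(path, index=False)


def read_standards_csv(path) -> list[InternalStandard]:
    df = pd.read_csv(path)
    return [InternalStandard(str(r[0]), float(r[1]), float(r[2]), float(r[3]))
            for r in df.itertuples(index=False)]


def write_msp(spectra: Sequence[MsmsSpectrum], path) -> None:
    """Minimal MSP export (NAME/PRECURSORMZ/RETENTIONTIME/Num Peaks)."""
    with open(path, "w") as fh:
        for i, sp in enumerate(spectra):
            fh.write(f"NAME: {sp.source_id or f'spectrum-{i}'}\n")
            fh.write(f"PRECURSORMZ: {sp.precursor_mz:.5f}\n")
            fh.write(f"RETENTIONTIME: {sp.rt:.3f}\n")
            fh.write(f"Num Peaks: {len(sp.peaks)}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.5f} {inten:.1f}\n")
            fh.write("\n")


def write_mgf(spectra: Sequence[MsmsSpectrum], path) -> None:
    """MGF export via pyteomics."""
    from pyteomics import mgf

    entries = []
    for i, sp in enumerate(spectra):
        entries.append({
            "m/z array": [mz for mz, _ in sp.peaks],
            "intensity array": [inten for _, inten in sp.peaks],
            "params": {
                "title": sp.source_id or f"spectrum-{i}",
                "pepmass": sp.precursor_mz,
                "rtinseconds": sp.rt * 60.0,
            },
        })
    mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[MsmsSpectrum]:
    from pyteomics import mgf

    out = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pep = params.get("pepmass", (0.0,))
            out.append(MsmsSpectrum(
                precursor_mz=float(pep[0] if isinstance(pep, (tuple, list)) else pep),
                rt=float(params.get("rtinseconds", 0.0)) / 60.0,
                peaks=tuple(zip(map(float, entry["m/z array"]),
                                map(float, entry["intensity array"]))),
                source_id=str(params.get("title", "")),
            ))
    return out
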