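import numpy as np
import pandas as pd
import pytest

from polarscreen.records import InstrumentProfile, StudyDesign
from polarscreen.synthetic import (
    generate_compound_db,
    make_ground_truth,
    simulate_feature_tables,
)


def noise_free_instrument(label="B", has_msms=True):
    return InstrumentProfile(label, mass_sigma_ppm=0.0, rt_sigma=0.0,
                             detection_prob=1.0, intensity_scale=1.0,
                             has_msms=has_msms)


@pytest.fixture(scope="session")
def small_db():
    return generate_compound_db(20, family_pool=("Lemnaceae",), seed=11)


@pytest.fixture(scope="session")
def noise_free_study(small_db):
    """Single-instrument noise-free study: every truth compound appears in
    every injection at its exact coordinates."""
    design = StudyDesign(solvents=("100% MeOH",),
                         instruments=(noise_free_instrument(),),
                         n_injections=3, seed=5)
    truth = make_ground_truth(design, small_db)
    study = simulate_feature_tables(design, small_db, truth,
                                    intensity_jitter_sigma=0.0, msms_noise_peaks=0)
    return study


def random_injection_tables(rng: np.random.Generator, n_injections=3,
                            n_base=8, sample="s", instrument="X"):
    """Random per-injection tables for oracle comparisons: a few shared
    features with jitter plus injection-specific extras."""
    base_mz = rng.uniform(100, 600, size=n_base)
    base_rt = rng.uniform(5, 34, size=n_base)
    tables = []
    for inj in range(n_injections):
        rows = []
        k = 0
        for mz, rt in zip(base_mz, base_rt):
            if rng.random() < 0.8:  # sometimes missing from an injection
                rows.append((f"{instrument}:{sample}:i{inj}:{k:04d}",
                             mz * (1 + rng.normal(0, 2) * 1e-6),
                             rt + rng.normal(0, 0.05),
                             float(rng.uniform(60, 5000)), sample, inj, instrument))
                k += 1
        for _ in range(rng.integers(0, 4)):
            rows.append((f"{instrument}:{sample}:i{inj}:{k:04d}",
                         float(rng.uniform(100, 600)), float(rng.uniform(5, 34)),
                         float(rng.uniform(60, 5000)), sample, inj, instrument))
            k += 1
        tables.append(pd.DataFrame(rows, columns=[
            "feature_id", "mz", "rt_min", "intensity", "sample", "injection", "instrument"]))
    return tables
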