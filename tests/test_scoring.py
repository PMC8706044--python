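import numpy as np
import pytest

from polarscreen.features import ConsensusFeature, blank_subtract, consensus_features
from polarscreen.records import CompoundRecord, MsmsSpectrum
from polarscreen.rti import fit_calibration, CalibrationStandard
from polarscreen.scoring import (
    CandidateHit,
    ChemotaxonomyFilter,
    ScoringConfig,
    chemotaxonomy_filter,
    composite_and_flag,
    logd_sign_filter,
    mass_screen,
    msms_subscore,
    successive_elimination,
)
from polarscreen.synthetic import (
    calibration_standards_table,
    generate_compound_db,
    generate_decoys,
    simulate_msms,
)

from oracles import mass_screen_oracle


def _feature(mz, rt=10.0, fid="f0"):
    return ConsensusFeature(fid, mz, rt, (1000.0,) * 3, 3, "s", "B")


def _compound(mass=200.0, logd=-1.0, families=("Lemnaceae",), fragments=(80.0, 120.0),
              cid="C0000"):
    return CompoundRecord(cid, f"name-{cid}", mass, logd, frozenset(families),
                          tuple(fragments))


class TestMassScreen:
    def test_exact_match_scores_one(self):
        c = _compound()
        hits = mass_screen(_feature(c.adduct_mass), [c])
        assert len(hits) == 1
        assert hits[0].mass_subscore == 1.0

    def test_window_edge_still_candidate(self):
        c = _compound()
        mz = c.adduct_mass * (1 - 4.999e-6)  # just inside the +5 ppm edge
        hits = mass_screen(_feature(mz), [c])
        assert len(hits) == 1
        assert hits[0].mass_subscore == pytest.approx(0.0, abs=1e-3)

    def test_outside_window_excluded(self):
        c = _compound()
        assert mass_screen(_feature(c.adduct_mass * (1 + 8e-6)), [c]) == []

    def test_empty_db_raises(self):
        with pytest.raises(ValueError):
            mass_screen(_feature(200.0), [])

    def test_matches_brute_force_oracle(self):
        db = generate_compound_db(200, seed=5)
        rng = np.random.default_rng(7)
        for _ in range(50):
            base = db[rng.integers(len(db))].adduct_mass
            mz = base * (1 + rng.normal(0, 4) * 1e-6)
            got = {h.compound.compound_id for h in mass_screen(_feature(mz), db)}
            assert got == mass_screen_oracle(mz, db)


class TestMsmsSubscore:
    def test_exact_fragment_list(self):
        c = _compound(fragments=(80.0, 120.0, 150.0))
        sp = MsmsSpectrum(c.adduct_mass, 10.0, tuple((f, 500.0) for f in c.fragments))
        assert msms_subscore(sp, c) == 1.0

    def test_disjoint_spectrum(self):
        c = _compound(fragments=(80.0, 120.0))
        sp = MsmsSpectrum(c.adduct_mass, 10.0, ((60.0, 500.0), (99.0, 500.0)))
        assert msms_subscore(sp, c) == 0.0

    def test_niacin_like_with_subthreshold_noise(self):
        """A 4-fragment vitamin spectrum plus 10 noise peaks under the
        intensity threshold still self-matches perfectly."""
        niacin = _compound(mass=123.0320, fragments=(124.0 - 46.0, 96.0, 80.0, 78.0),
                           cid="NIA")
        sp = simulate_msms(niacin, noise_peaks=10, seed=2)
        assert msms_subscore(sp, niacin) == 1.0

    def test_no_fragment_list_is_absent_not_zero(self):
        c = CompoundRecord("X", "x", 200.0, 1.0, frozenset({"Lemnaceae"}), ())
        sp = MsmsSpectrum(201.0, 10.0, ((80.0, 500.0),))
        assert msms_subscore(sp, c) is None

    def test_one_peak_matches_at_most_one_fragment(self):
        c = _compound(fragments=(100.00, 100.04))
        sp = MsmsSpectrum(c.adduct_mass, 10.0, ((100.01, 500.0),))
        assert msms_subscore(sp, c, ScoringConfig(msms_mz_tol=0.05)) == 0.5


class TestCompositeAndFlag:
    def test_hilic_perfect_scores(self):
        c = _compound()
        (h,) = composite_and_flag(
            [CandidateHit(_feature(c.adduct_mass), c, 0.0, 1.0, msms_subscore=1.0)],
            ScoringConfig(), "HILIC")
        assert h.composite == pytest.approx(100.0)
        assert h.look_at

    def test_rplc_absent_msms_counts_zero(self):
        c = _compound(logd=1.0)
        (h,) = composite_and_flag(
            [CandidateHit(_feature(c.adduct_mass, rt=19.0), c, 0.0, 1.0,
                          rti_subscore=0.5, msms_subscore=None)],
            ScoringConfig(), "RPLC")
        assert h.composite == pytest.approx(100 * (1 + 0.5) / 3)

    def test_renormalization_mode(self):
        c = _compound(logd=1.0)
        (h,) = composite_and_flag(
            [CandidateHit(_feature(c.adduct_mass, rt=19.0), c, 0.0, 1.0,
                          rti_subscore=0.5, msms_subscore=None)],
            ScoringConfig(renormalize_missing=True), "RPLC")
        assert h.composite == pytest.approx(100 * (1 + 0.5) / 2)

    def test_flag_matches_argmax_oracle(self):
        rng = np.random.default_rng(3)
        f = _feature(200.0)
        for _ in range(100):
            hits = []
            for i in range(rng.integers(1, 8)):
                c = _compound(cid=f"C{i:03d}")
                hits.append(CandidateHit(f, c, float(rng.uniform(-5, 5)),
                                         float(rng.uniform(0, 1)),
                                         msms_subscore=float(rng.uniform(0, 1))))
            composite_and_flag(hits, ScoringConfig(), "HILIC")
            best = min(hits, key=lambda h: (-h.composite, abs(h.ppm),
                                            h.compound.compound_id))
            assert sum(h.look_at for h in hits) == 1
            assert next(h for h in hits if h.look_at) is best

    def test_mixed_features_raise(self):
        c = _compound()
        hits = [CandidateHit(_feature(200.0, fid="a"), c, 0.0, 1.0),
                CandidateHit(_feature(200.0, fid="b"), c, 0.0, 1.0)]
        with pytest.raises(ValueError):
            composite_and_flag(hits, ScoringConfig(), "HILIC")


class TestFilters:
    @pytest.mark.parametrize("column,logd,eliminated", [
        ("HILIC", -2.1, False),
        ("HILIC", 0.5, True),
        ("HILIC", 0.0, False),   # boundary: only strictly positive eliminated
        ("RPLC", 1.5, False),
        ("RPLC", 0.0, True),     # boundary: non-positive eliminated on RPLC
        ("RPLC", -1.0, True),
    ])
    def test_logd_sign_filter(self, column, logd, eliminated):
        c = _compound(logd=logd)
        (h,) = logd_sign_filter([CandidateHit(_feature(c.adduct_mass), c, 0.0, 1.0)],
                                column)
        assert (h.eliminated_by == "logd_filter") == eliminated

    def test_chemotaxonomy_retains_allowed_family(self):
        keep = _compound(families=("Lemnaceae",), cid="K")
        drop = _compound(families=("Fabaceae",), cid="D")
        hits = [CandidateHit(_feature(200.0), c, 0.0, 1.0) for c in (keep, drop)]
        chemotaxonomy_filter(hits)
        assert hits[0].eliminated_by is None
        assert hits[1].eliminated_by == "chemotaxonomy"

    def test_allow_all_families_is_identity(self):
        c = _compound(families=("Fabaceae",))
        (h,) = chemotaxonomy_filter(
            [CandidateHit(_feature(200.0), c, 0.0, 1.0)],
            ChemotaxonomyFilter(frozenset({"Fabaceae", "Lemnaceae"})))
        assert h.eliminated_by is None

    def test_filters_commute(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            hits_a, hits_b = [], []
            for i in range(10):
                c = _compound(logd=float(rng.uniform(-3, 3)),
                              families=("Lemnaceae",) if rng.random() < 0.5 else ("Fabaceae",),
                              cid=f"C{i}")
                hits_a.append(CandidateHit(_feature(c.adduct_mass), c, 0.0, 1.0))
                hits_b.append(CandidateHit(_feature(c.adduct_mass), c, 0.0, 1.0))
            column = "HILIC" if rng.random() < 0.5 else "RPLC"
            chemotaxonomy_filter(logd_sign_filter(hits_a, column))
            logd_sign_filter(chemotaxonomy_filter(hits_b), column)
            surv_a = {h.compound.compound_id for h in hits_a if h.eliminated_by is None}
            surv_b = {h.compound.compound_id for h in hits_b if h.eliminated_by is None}
            assert surv_a == surv_b


class TestSuccessiveElimination:
    @pytest.fixture()
    def screened_study(self, small_db, noise_free_study):
        study = noise_free_study
        solvent, instr = "100% MeOH", "B"
        feats = consensus_features(study.injection_tables(solvent, instr))
        feats = blank_subtract(feats, study.blank_tables[(solvent, instr)])
        calib = fit_calibration([
            CalibrationStandard(r["name"], r.rt_min, r.logd_ph7)
            for _, r in calibration_standards_table().iterrows()])
        decoys = generate_decoys(small_db, 40, seed=1)
        db = list(small_db) + decoys
        hilic = [f for f in feats if f.column == "HILIC"]
        rplc = [f for f in feats if f.column == "RPLC"]
        spectra = study.spectra[(solvent, instr)]
        res_h = successive_elimination(hilic, db, calibration=None, spectra=spectra,
                                       column="HILIC")
        res_r = successive_elimination(rplc, db, calibration=calib, spectra=spectra,
                                       column="RPLC")
        return res_h, res_r

    def test_all_truth_compounds_survive_noise_free(self, small_db, screened_study):
        res_h, res_r = screened_study
        survivors = {h.compound.compound_id for r in screened_study for h in r.survivors}
        assert survivors == {c.compound_id for c in small_db}

    def test_stage_counts_monotone(self, screened_study):
        for res in screened_study:
            counts = list(res.stage_counts.values())
            assert counts == sorted(counts, reverse=True)

    def test_decoys_never_survive(self, screened_study):
        for res in screened_study:
            assert all(not h.compound.compound_id.startswith("Z")
                       for h in res.survivors)

    def test_decoy_hits_eliminated_by_chemotaxonomy_when_applied(self, screened_study):
        """Any decoy hit, pruned or not, fails the chemotaxonomy filter."""
        for res in screened_study:
            decoy_hits = [CandidateHit(h.feature, h.compound, h.ppm, h.mass_subscore)
                          for h in res.hits if h.compound.compound_id.startswith("Z")]
            assert decoy_hits, "screen produced no decoy candidates"
            chemotaxonomy_filter(decoy_hits)
            assert all(h.eliminated_by == "chemotaxonomy" for h in decoy_hits)

    def test_precision_of_filters_with_family_only_decoys(self, small_db,
                                                          noise_free_study):
        """With decoys differing only in family, applying the two
        elimination filters to all candidates leaves only truth hits."""
        study = noise_free_study
        feats = consensus_features(study.injection_tables("100% MeOH", "B"))
        feats = blank_subtract(feats, study.blank_tables[("100% MeOH", "B")])
        decoys = generate_decoys(small_db, len(small_db), seed=2, same_fragments=True)
        db = list(small_db) + decoys
        all_hits = []
        for f in feats:
            all_hits.extend(mass_screen(f, db))
        column_of = {f.feature_id: f.column for f in feats}
        for h in all_hits:
            logd_sign_filter([h], column_of[h.feature.feature_id])
        chemotaxonomy_filter(all_hits)
        survivors = [h for h in all_hits if h.eliminated_by is None]
        assert survivors
        assert all(not h.compound.compound_id.startswith("Z") for h in survivors)

    def test_audit_counts_match_independent_recount(self, screened_study):
        for res in screened_study:
            recount = {
                "candidates": len(res.hits),
                "look_at": sum(1 for h in res.hits if h.look_at),
                "after_logd_filter": sum(
                    1 for h in res.hits
                    if h.look_at and h.eliminated_by != "logd_filter"),
                "after_chemotaxonomy": sum(
                    1 for h in res.hits if h.look_at and h.eliminated_by is None),
            }
            assert res.stage_counts == recount

    def test_mixed_columns_raise(self):
        db = generate_compound_db(5, seed=0)
        feats = [_feature(200.0, rt=10.0, fid="h"), _feature(300.0, rt=20.0, fid="r")]
        with pytest.raises(ValueError):
            successive_elimination(feats, db)
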