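import numpy as np
import pandas as pd
import pytest

from chemevol.annotate import (
    AnnotationError,
    ConsistencyError,
    annotate_cardenolides,
    detect_genin_fragments,
    find_adduct_pairs,
    infer_glycoside_chain,
    quantify_compounds,
    screen_glucosinolates,
)
from chemevol.masses import (
    NA_H_SPACING,
    monoisotopic_mass,
    mz_mh_neg,
    mz_mh_pos,
    mz_mna_pos,
)

from conftest import positive_features

DIGITOXIGENIN = monoisotopic_mass("C23H34O4")
HEXOSE = monoisotopic_mass("C6H10O5")
DEOXYHEXOSE = monoisotopic_mass("C6H10O4")
ACETYL = monoisotopic_mass("C2H2O")


class TestAdductPairs:
    def test_pair_found_at_na_h_spacing(self):
        features = positive_features(
            [("f1", 537.3059, 6.0, 100.0), ("f2", 559.2878, 6.0, 60.0)]
        )
        pairs = find_adduct_pairs(features, mz_tol=0.005, rt_tol=0.05)
        assert len(pairs) == 1
        h_id, na_id, neutral = pairs[0]
        assert (h_id, na_id) == ("f1", "f2")
        assert neutral == pytest.approx(536.2985, abs=0.005)

    def test_wrong_spacing_not_paired(self):
        features = positive_features(
            [("f1", 537.3059, 6.0, 100.0), ("f2", 537.3059 + 21.95, 6.0, 60.0)]
        )
        assert find_adduct_pairs(features) == []

    def test_rt_separation_blocks_pairing(self):
        features = positive_features(
            [("f1", 537.3059, 6.0, 100.0), ("f2", 537.3059 + NA_H_SPACING, 6.2, 60.0)]
        )
        assert find_adduct_pairs(features, rt_tol=0.05) == []

    def test_greedy_pairing_prefers_higher_intensity_partner(self):
        # one H-adduct, two co-eluting Na candidates: pick the stronger one
        mz_h = 537.3059
        features = positive_features(
            [
                ("h", mz_h, 6.0, 100.0),
                ("na_weak", mz_h + NA_H_SPACING + 0.001, 6.0, 10.0),
                ("na_strong", mz_h + NA_H_SPACING - 0.001, 6.0, 90.0),
            ]
        )
        pairs = find_adduct_pairs(features, mz_tol=0.005)
        assert len(pairs) == 1
        assert pairs[0][1] == "na_strong"
        # brute-force: of all valid pairings, greedy picks the max-intensity one
        assert 100.0 + 90.0 == max(100.0 + 90.0, 100.0 + 10.0)

    def test_each_feature_in_at_most_one_pair(self):
        mz_h = 400.0
        features = positive_features(
            [
                ("a", mz_h, 5.0, 50.0),
                ("b", mz_h + NA_H_SPACING, 5.0, 40.0),
                ("c", mz_h + 2 * NA_H_SPACING, 5.0, 30.0),
            ]
        )
        pairs = find_adduct_pairs(features)
        used = [fid for p in pairs for fid in p[:2]]
        assert len(used) == len(set(used))

    def test_negative_mode_rejected(self):
        features = positive_features([("f1", 300.0, 1.0, 10.0)])
        features["mode"] = "negative"
        with pytest.raises(ValueError, match="positive"):
            find_adduct_pairs(features)


class TestGeninFragments:
    def test_protonated_genin_detected(self, library):
        group = positive_features([("f1", mz_mh_pos(DIGITOXIGENIN), 6.0, 10.0)])
        candidates = detect_genin_fragments(group, library)
        assert candidates and candidates[0][0] == "digitoxigenin"

    def test_water_loss_fragment_detected(self, library):
        group = positive_features([("f1", 357.2424, 6.0, 10.0)])
        candidates = detect_genin_fragments(group, library)
        assert ("digitoxigenin", 1) in candidates

    def test_no_match_gives_empty(self, library):
        group = positive_features([("f1", 111.0, 6.0, 10.0)])
        assert detect_genin_fragments(group, library) == []

    def test_empty_group(self, library):
        assert detect_genin_fragments(positive_features([]), library) == []


class TestGlycosideChain:
    def test_single_hexose(self, library):
        sugars, acetyl, resolved = infer_glycoside_chain(
            DIGITOXIGENIN + HEXOSE, "digitoxigenin", positive_features([]), library
        )
        assert sugars == ("hexose",)
        assert not acetyl
        assert resolved

    def test_diglycoside_order_from_outer_loss_fragment(self, library):
        neutral = DIGITOXIGENIN + HEXOSE + DEOXYHEXOSE
        group = positive_features(
            [("frag", mz_mh_pos(neutral - DEOXYHEXOSE), 6.0, 5.0)]
        )
        sugars, acetyl, resolved = infer_glycoside_chain(
            neutral, "digitoxigenin", group, library
        )
        assert sugars == ("hexose", "deoxyhexose")  # inner, outer
        assert resolved and not acetyl

    def test_diglycoside_without_fragment_flagged_unresolved(self, library):
        neutral = DIGITOXIGENIN + HEXOSE + DEOXYHEXOSE
        sugars, _, resolved = infer_glycoside_chain(
            neutral, "digitoxigenin", positive_features([]), library
        )
        assert set(sugars) == {"hexose", "deoxyhexose"}
        assert not resolved

    def test_acetylated_hexoside(self, library):
        sugars, acetyl, _ = infer_glycoside_chain(
            DIGITOXIGENIN + HEXOSE + ACETYL,
            "digitoxigenin",
            positive_features([]),
            library,
        )
        assert sugars == ("hexose",)
        assert acetyl

    def test_unexplainable_mass_raises(self, library):
        with pytest.raises(AnnotationError):
            infer_glycoside_chain(
                DIGITOXIGENIN + 77.77, "digitoxigenin", positive_features([]), library
            )


class TestAnnotateCardenolides:
    def test_round_trip_on_noise_free_data(self, library, noise_free_dataset):
        features = noise_free_dataset["features"]
        panel = noise_free_dataset["panel"]
        annotations = annotate_cardenolides(
            features[features["mode"] == "positive"], library
        )
        truth = sorted(
            (c.genin, tuple(c.sugars), c.acetyl, round(c.neutral_mass, 3), c.isomer_index)
            for c in panel
            if c.compound_class == "cardenolide"
        )
        found = sorted(
            (a.genin, tuple(a.sugars), a.acetyl, round(a.neutral_mass, 3), a.isomer_index)
            for a in annotations
        )
        assert found == truth

    def test_isomer_indices_ascend_with_rt(self, library):
        neutral = DIGITOXIGENIN + HEXOSE
        genin_mz = mz_mh_pos(DIGITOXIGENIN)
        rows = []
        for tag, rt in (("a", 8.0), ("b", 3.0)):
            rows += [
                (f"h_{tag}", mz_mh_pos(neutral), rt, 10.0),
                (f"na_{tag}", mz_mna_pos(neutral), rt, 5.0),
                (f"g_{tag}", genin_mz, rt, 2.0),
            ]
        annotations = annotate_cardenolides(positive_features(rows), library)
        assert len(annotations) == 2
        by_rt = sorted(annotations, key=lambda a: a.rt)
        assert [a.isomer_index for a in by_rt] == [1, 2]

    def test_empty_table(self, library):
        assert annotate_cardenolides(positive_features([]), library) == []

    def test_monotone_tolerance(self, library, noise_free_dataset):
        """Shrinking mz_tol never adds annotations."""
        features = noise_free_dataset["features"]
        pos = features[features["mode"] == "positive"]
        wide = annotate_cardenolides(pos, library, mz_tol=0.005)
        narrow = annotate_cardenolides(pos, library, mz_tol=0.0005)
        assert len(narrow) <= len(wide)

    def test_mass_additivity_invariant(self, library, noise_free_dataset):
        features = noise_free_dataset["features"]
        annotations = annotate_cardenolides(
            features[features["mode"] == "positive"], library, mz_tol=0.005
        )
        for a in annotations:
            expected = (
                library.genin_by_name(a.genin).mass
                + sum(library.sugar_by_name(s).loss_mass for s in a.sugars)
                + (library.acetyl_mass if a.acetyl else 0.0)
            )
            assert abs(a.neutral_mass - expected) <= 0.005


class TestScreenGlucosinolates:
    def _neg(self, rows):
        df = positive_features(rows)
        df["mode"] = "negative"
        return df

    def test_library_match_by_exact_mass(self, library):
        sinigrin = library.glucosinolate_by_name("sinigrin")
        features = self._neg([("f1", mz_mh_neg(sinigrin.mass), 2.0, 10.0)])
        out = screen_glucosinolates(features, library)
        assert [a.name for a in out] == ["sinigrin"]

    def test_glucoiberin_match(self, library):
        glucoiberin = library.glucosinolate_by_name("glucoiberin")
        features = self._neg([("f1", mz_mh_neg(glucoiberin.mass), 1.5, 10.0)])
        out = screen_glucosinolates(features, library)
        assert [a.name for a in out] == ["glucoiberin"]

    def test_unknown_candidate_needs_diagnostic_fragments(self, library):
        parent_mz = 500.1234
        diag = library.diagnostic_fragments_neg
        with_frags = self._neg(
            [
                ("p", parent_mz, 3.0, 50.0),
                ("d1", diag[0], 3.0, 5.0),
                ("d2", diag[1], 3.0, 5.0),
            ]
        )
        out = screen_glucosinolates(with_frags, library, min_diag=2)
        assert [a.name for a in out] == ["unknown glucosinolate candidate"]
        without = self._neg([("p", parent_mz, 3.0, 50.0)])
        assert screen_glucosinolates(without, library, min_diag=2) == []

    def test_round_trip_names(self, library, noise_free_dataset):
        features = noise_free_dataset["features"]
        panel = noise_free_dataset["panel"]
        out = screen_glucosinolates(features[features["mode"] == "negative"], library)
        assert sorted(a.name for a in out) == sorted(
            c.name for c in panel if c.compound_class == "glucosinolate"
        )


class TestQuantify:
    def test_global_adduct_selection_by_total_intensity(self, library):
        neutral = DIGITOXIGENIN + HEXOSE
        rows = []
        # sample s1: Na much stronger; sample s2: H slightly stronger
        frame = pd.DataFrame(
            [
                ("h", mz_mh_pos(neutral), 6.0, 1e5, "s1", "positive"),
                ("na", mz_mna_pos(neutral), 6.0, 9e5, "s1", "positive"),
                ("g", mz_mh_pos(DIGITOXIGENIN), 6.0, 1e3, "s1", "positive"),
                ("h", mz_mh_pos(neutral), 6.0, 2e5, "s2", "positive"),
                ("na", mz_mna_pos(neutral), 6.0, 1e5, "s2", "positive"),
                ("g", mz_mh_pos(DIGITOXIGENIN), 6.0, 1e3, "s2", "positive"),
            ],
            columns=["feature_id", "mz", "rt", "intensity", "sample_id", "mode"],
        )
        annotations = annotate_cardenolides(frame, library)
        assert len(annotations) == 1
        q = quantify_compounds(frame, annotations)
        # Na total (1e6) beats H total (3e5): Na intensities reported everywhere
        assert q.iloc[:, 0].tolist() == [9e5, 1e5]

    def test_absent_sample_reports_zero(self, library, noise_free_dataset):
        features = noise_free_dataset["features"]
        panel = noise_free_dataset["panel"]
        abundance = noise_free_dataset["abundance"]
        annotations = annotate_cardenolides(
            features[features["mode"] == "positive"], library
        ) + screen_glucosinolates(features[features["mode"] == "negative"], library)
        q = quantify_compounds(features, annotations)
        # zero abundance in the ground truth maps to zero reported intensity
        by_key = {}
        for c in panel:
            by_key[(c.genin, tuple(c.sugars), c.acetyl, c.isomer_index, c.name)] = (
                c.compound_id
            )
        for a in annotations:
            cid = by_key[(a.genin, tuple(a.sugars), a.acetyl, a.isomer_index,
                          a.name if a.compound_class == "glucosinolate" else None)]
            truth = abundance[cid].reindex(q.index)
            got = q[a.compound_id]
            nz = truth > 0
            # absences report exactly zero; present samples are proportional to
            # the true abundance (the adduct response factor is global)
            assert np.allclose(got[~nz].to_numpy(), 0.0)
            if nz.any():
                ratios = got[nz].to_numpy() / truth[nz].to_numpy()
                assert np.allclose(ratios, ratios[0], rtol=1e-9)

    def test_dangling_annotation_raises(self, library):
        frame = positive_features([("h", 537.3059, 6.0, 10.0)])
        from chemevol.annotate import AnnotatedCompound

        bad = AnnotatedCompound(
            compound_id="x", compound_class="cardenolide", genin="digitoxigenin",
            sugars=("hexose",), acetyl=False, neutral_mass=536.3, rt=6.0,
            adducts={"[M+H]+": "missing"},
        )
        with pytest.raises(ConsistencyError):
            quantify_compounds(frame, [bad])
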