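"""Hand-crafted feature extractors: worked examples and invariants."""

import math

import numpy as np
import pytest

from thermoshift.core import Condition, Mutation, MutationRecord, ProteinRecord
from thermoshift.dataio import (
    AAindexEntry,
    PSSM,
    ScaleSet,
    SiftRecord,
    bundled_aaindex,
    default_scales,
    fallback_pssm,
)
from thermoshift.features import FeatureTable
from thermoshift.features.traditional import (
    ExtractionConfig,
    FeatureExtractionError,
    aaindex_features,
    condition_features,
    extract_traditional,
    grouping_features,
    neighborhood_features,
    physicochemical_features,
    pssm_features,
    pssm_section_bounds,
    scale_features,
    sift_features,
    total_atoms,
)

KI = Mutation("K", 79, "I")


class TestAAindexFeatures:
    def test_constant_scale_gives_zero_difference(self):
        entry = AAindexEntry("CONST00001", 1, index={r: 3.14 for r in "ACDEFGHIKLMNPQRSTVWY"})
        cols = aaindex_features(KI, [entry])
        assert cols == {"aaindex1_CONST00001": 0.0}

    def test_hydropathy_difference(self):
        kd = [e for e in bundled_aaindex(1) if e.accession == "KYTJ820101"]
        cols = aaindex_features(KI, kd)
        assert cols["aaindex1_KYTJ820101"] == pytest.approx(8.4)

    def test_antisymmetry_kind1(self):
        entries = bundled_aaindex(1)
        fwd = aaindex_features(Mutation("K", 9, "I"), entries)
        rev = aaindex_features(Mutation("I", 9, "K"), entries)
        for name in fwd:
            assert fwd[name] == pytest.approx(-rev[name])

    def test_symmetric_matrix_invariant_under_swap(self):
        entries = bundled_aaindex(2)[:1]
        fwd = aaindex_features(Mutation("K", 79, "I"), entries)
        rev = aaindex_features(Mutation("I", 79, "K"), entries)
        assert list(fwd.values()) == pytest.approx(list(rev.values()))

    def test_queried_na_cell_raises(self):
        mat = np.full((20, 20), np.nan)
        entry = AAindexEntry("NAMAT00001", 2, matrix=mat)
        with pytest.raises(FeatureExtractionError) as err:
            aaindex_features(KI, [entry])
        assert err.value.reason == "aaindex_na"


class TestNeighborhoodFeatures:
    def test_poly_a(self):
        p = ProteinRecord("p", "A" * 51)
        cols = neighborhood_features(p, Mutation("A", 26, "V"))
        assert cols["neigh_freq_A"] == 1.0
        assert sum(cols.values()) == pytest.approx(1.0)

    def test_frequencies_sum_to_one_everywhere(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        p = ProteinRecord("p", seq)
        for pos in (1, 2, 13, 50, 99, 100):
            wild = seq[pos - 1]
            mutant = "A" if wild != "A" else "V"
            cols = neighborhood_features(p, Mutation(wild, pos, mutant))
            assert sum(cols.values()) == pytest.approx(1.0)
            assert len(cols) == 20

    def test_terminal_window_clipped_to_13(self):
        # site 1 of a 100-mer: window covers positions 1-13 only
        seq = "W" + "A" * 12 + "C" * 87
        p = ProteinRecord("p", seq)
        cols = neighborhood_features(p, Mutation("W", 1, "V"))
        assert cols["neigh_freq_W"] == pytest.approx(1 / 13)
        assert cols["neigh_freq_A"] == pytest.approx(12 / 13)
        assert cols["neigh_freq_C"] == 0.0


class TestGroupingFeatures:
    @pytest.mark.parametrize(
        "mut,cell",
        [
            (Mutation("V", 5, "I"), "group_hydrophobic_to_hydrophobic"),
            (Mutation("D", 5, "K"), "group_negative_to_positive"),
            (Mutation("K", 79, "I"), "group_positive_to_hydrophobic"),
        ],
    )
    def test_one_hot_cell(self, mut, cell):
        cols = grouping_features(mut)
        assert len(cols) == 36
        assert cols[cell] == 1.0
        assert sum(cols.values()) == 1.0


class TestPssmFeatures:
    def test_constant_pssm(self):
        p = ProteinRecord("p", "A" * 40)
        pssm = PSSM("p", p.sequence, np.full((40, 20), 2.5), "fallback:X")
        cols = pssm_features(p, pssm)
        assert len(cols) == 400
        assert set(cols.values()) == {2.5}

    def test_length_20_sections_are_rows(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(-5, 6, size=(20, 20)).astype(float)
        p = ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY")
        cols = pssm_features(p, PSSM("p", p.sequence, scores, "x"))
        flat = np.array(list(cols.values())).reshape(20, 20)
        assert np.array_equal(flat, scores)

    def test_length_23_sections_match_brute_force(self):
        # Independent oracle: balanced partition (3 sections of 2, 17 of 1)
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(23, 20))
        seq = "ACDEFGHIKLMNPQRSTVWYACD"
        p = ProteinRecord("p", seq)
        bounds = pssm_section_bounds(23)
        assert [hi - lo for lo, hi in bounds] == [2, 2, 2] + [1] * 17
        assert bounds[0] == (0, 2) and bounds[-1] == (22, 23)
        cols = pssm_features(p, PSSM("p", seq, scores, "x"))
        flat = np.array(list(cols.values())).reshape(20, 20)
        for s, (lo, hi) in enumerate(bounds):
            expected = scores[lo:hi].mean(axis=0)
            assert flat[s] == pytest.approx(expected)

    def test_too_short_sequence_dropped(self):
        p = ProteinRecord("p", "ACDEFGHIKLMNPQRSTVW")  # 19 residues
        with pytest.raises(FeatureExtractionError) as err:
            pssm_features(p, fallback_pssm(p))
        assert err.value.reason == "sequence_too_short"


class TestPhysicochemicalFeatures:
    def test_poly_ala_worked_values(self):
        p = ProteinRecord("p", "A" * 10)
        cols = physicochemical_features(p)
        # instability index: (10/L) * (L-1) * DIWV(A,A) with DIWV(A,A)=1.0
        assert cols["param_instability"] == pytest.approx(9.0)
        # aliphatic index: 100 mole-% Ala, no V/I/L terms
        assert cols["param_aliphatic"] == pytest.approx(100.0)
        # no W/Y/C: zero absorbance at 280 nm
        assert cols["param_extinction"] == 0.0
        assert cols["param_length"] == 10.0
        # 10 alanines (13 atoms each) minus 9 waters (3 atoms each)
        assert cols["param_atoms"] == 10 * 13 - 9 * 3

    def test_seven_columns_and_molecular_weight(self):
        p = ProteinRecord("p", "MKVLATGEIRSDFWYHQCNP")
        cols = physicochemical_features(p)
        assert len(cols) == 7
        # average mass of a 20-mer lies in a plausible band
        assert 1800 < cols["param_mol_weight"] < 3000
        assert 0 < cols["param_pi"] < 14

    def test_total_atoms_additive(self):
        assert total_atoms("A") == 13
        assert total_atoms("AA") == 23  # two free Ala minus one water


class TestSiftFeatures:
    def test_passthrough(self, toy_record):
        sift = {toy_record.key: SiftRecord(0.03, 3.1, 120)}
        cols = sift_features(toy_record, sift)
        assert cols == {"sift_score": 0.03, "sift_median": 3.1, "sift_num_seq": 120.0}

    def test_absent_imputed_with_neutral(self, toy_record):
        cols = sift_features(toy_record, {}, policy="impute")
        assert cols == {"sift_score": 1.0, "sift_median": 3.0, "sift_num_seq": 0.0}

    def test_absent_dropped_by_default(self, toy_record):
        with pytest.raises(FeatureExtractionError) as err:
            sift_features(toy_record, {})
        assert err.value.reason == "no_sift"


class TestScaleFeatures:
    def test_kyte_doolittle_k_to_i(self):
        cols = scale_features(KI, default_scales())
        assert cols["scale_hydropathy_kyte_doolittle"] == pytest.approx(8.4)
        assert len(cols) == 57

    def test_antisymmetric_under_reverse(self):
        scales = default_scales()
        fwd = scale_features(Mutation("D", 4, "W"), scales)
        rev = scale_features(Mutation("W", 4, "D"), scales)
        for name in fwd:
            assert fwd[name] == pytest.approx(-rev[name])

    def test_identity_difference_is_zero_by_formula(self):
        # wild == mutant cannot occur in valid data; assert on the formula
        scales = ScaleSet({"s": {r: float(i) for i, r in enumerate("ARNDCQEGHILKMFPSTWYV")}})
        assert scales.scales["s"]["K"] - scales.scales["s"]["K"] == 0.0


class TestConditionFeatures:
    def test_ph_tm(self, toy_record):
        assert condition_features(toy_record, "ph_tm") == {"ph": 7.0, "tm": 65.0}

    def test_common_has_no_columns(self):
        rec = MutationRecord("p", Mutation("K", 2, "A"), Condition(), delta_tm=1.0)
        assert condition_features(rec, "common") == {}

    def test_tm_missing_errors(self):
        rec = MutationRecord("p", Mutation("K", 2, "A"), Condition(ph=7.0), delta_tm=1.0)
        with pytest.raises(FeatureExtractionError):
            condition_features(rec, "tm")


class TestOrchestrator:
    def test_extraction_is_pure(self, small_dataset):
        cfg = ExtractionConfig(aaindex=False, pssm=False, sift=False,
                               variant_tag="ph_tm")
        args = (small_dataset.protein_map, small_dataset.records[:40], cfg)
        t1, d1 = extract_traditional(*args, scales=default_scales())
        t2, d2 = extract_traditional(*args, scales=default_scales())
        assert t1.content_hash() == t2.content_hash()
        assert d1 == d2

    def test_pssm_fallback_policy(self, small_dataset):
        cfg = ExtractionConfig(aaindex=False, sift=False, physicochemical=False,
                               pssm_policy="fallback", variant_tag="common")
        records = small_dataset.records[:10]
        variant_records = [r for r in records]
        from thermoshift.curation import make_variant
        common = make_variant(variant_records, "common").records
        table, drops = extract_traditional(
            small_dataset.protein_map, common, cfg, scales=default_scales())
        assert drops.get("no_pssm", 0) == 0
        assert sum(c.startswith("pssm_") for c in table.columns) == 400

    def test_pssm_drop_policy(self, small_dataset):
        cfg = ExtractionConfig(aaindex=False, sift=False, physicochemical=False,
                               scales=False, pssm_policy="drop", variant_tag="ph_tm")
        table, drops = extract_traditional(
            small_dataset.protein_map, small_dataset.records[:10], cfg)
        assert len(table) == 0
        assert drops["no_pssm"] == 10


class TestFeatureTable:
    def test_rejects_nan_and_duplicate_columns(self):
        import pandas as pd

        with pytest.raises(ValueError, match="NaN"):
            FeatureTable(pd.DataFrame({"a": [1.0, np.nan]}))
        df = pd.DataFrame([[1.0, 2.0]], columns=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(df)

    def test_tsv_roundtrip_with_provenance(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"x": [1.0, 2.0], "y": [0.5, -0.5]},
                          index=["r1", "r2"])
        table = FeatureTable(df, {"x": {"extractor": "t"}, "y": {"extractor": "u"}})
        table.to_tsv(tmp_path / "t.tsv")
        back = FeatureTable.from_tsv(tmp_path / "t.tsv")
        assert back.content_hash() == table.content_hash()
        assert back.provenance["x"] == {"extractor": "t"}
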