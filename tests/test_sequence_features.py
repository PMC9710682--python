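import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from molpatch.evaluation import PredictionRecord, r_squared
from molpatch.fixtures import make_regression_table
from molpatch.sequence_features import (
    GFM_FEATURES,
    ModelSpec,
    NBM_FEATURES,
    TFM_FEATURES,
    extract_features,
    features_frame,
    fit_model,
    predict,
    split_and_validate,
)

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

aa_sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=60)


class TestExtractFeatures:
    def test_homopolymer_alanine(self):
        f = extract_features("AAAA")
        assert f.length == 4
        assert f.gravy == pytest.approx(1.8)
        assert f.entropy == 0.0
        assert f.aromaticity == 0.0
        assert f.hydrophobic_count == 4

    def test_all_aromatic(self):
        assert extract_features("FWY").aromaticity == pytest.approx(1.0)

    def test_hydrophobic_set_counted(self):
        f = extract_features("ACFILMVWY")
        assert f.hydrophobic_count == 9
        assert f.hydrophilic_count == 0

    def test_counts_sum_to_length_and_buried_subset(self):
        f = extract_features("ACDEFGHIKLMNPQRSTVWY")
        assert sum(f.aa_counts.values()) == f.length == 20
        assert f.buried_fraction == pytest.approx(7 / 20)
        assert f.entropy == pytest.approx(np.log2(20))

    def test_extinction_coefficient_gill_von_hippel(self):
        # W*5500 + Y*1490 + (C pairs)*125, all cysteines assumed paired
        f = extract_features("WWYCC")
        assert f.extinction_coefficient == pytest.approx(2 * 5500 + 1490 + 125)

    def test_empty_and_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            extract_features("")
        with pytest.raises(ValueError):
            extract_features("AB1")

    def test_unknown_residue_tolerated_in_counts(self):
        f = extract_features("AXA")
        assert f.length == 3
        assert f.aa_counts == {"A": 2}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(aa_sequences)
    def test_gravy_is_mean_kyte_doolittle(self, seq):
        f = extract_features(seq)
        expected = sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)
        assert f.gravy == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(aa_sequences, st.randoms(use_true_random=False))
    def test_features_invariant_under_shuffle(self, seq, rnd):
        # all features are composition statistics except the instability
        # index (dipeptide weights) and the isoelectric point (terminal
        # pKa values), which depend on residue order by definition
        letters = list(seq)
        rnd.shuffle(letters)
        a = extract_features(seq).to_dict()
        b = extract_features("".join(letters)).to_dict()
        for order_dependent in ("instability_index", "isoelectric_point"):
            a.pop(order_dependent), b.pop(order_dependent)
        assert set(a) == set(b)
        for key in a:
            assert a[key] == pytest.approx(b[key]), key

    def test_features_frame_has_31_global_columns(self):
        frame = features_frame({"p1": "ACDEF", "p2": "GHIKL"})
        assert set(GFM_FEATURES) <= set(frame.columns)
        assert len(GFM_FEATURES) == 31
        assert list(frame.index) == ["p1", "p2"]


class TestModelSpec:
    def test_feature_sets_fixed_per_family(self):
        assert ModelSpec("TFM", "THSA").feature_names == TFM_FEATURES
        assert ModelSpec("NBM", "LHP").feature_names == NBM_FEATURES
        assert len(ModelSpec("GFM", "RHSA").feature_names) == 31

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("XYZ", "THSA")


class TestSplit:
    def test_partition_disjoint_exhaustive_and_sized(self):
        data = pd.DataFrame({"x": range(100)})
        sp = split_and_validate(data, seed=1)
        assert len(sp.test_idx) == 20
        assert len(sp.train_idx) == 80
        assert set(sp.train_idx) | set(sp.test_idx) == set(range(100))
        assert not set(sp.train_idx) & set(sp.test_idx)
        assert set(sp.cv_pool_idx) | set(sp.validation_idx) == set(sp.train_idx)
        assert len(sp.validation_idx) == 27  # one third of the training part

    def test_reproducible_for_fixed_seed(self):
        data = pd.DataFrame({"x": range(50)})
        a, b = split_and_validate(data, seed=7), split_and_validate(data, seed=7)
        assert np.array_equal(a.test_idx, b.test_idx)
        assert np.array_equal(a.cv_pool_idx, b.cv_pool_idx)
        c = split_and_validate(data, seed=8)
        assert not np.array_equal(a.test_idx, c.test_idx)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            split_and_validate(pd.DataFrame({"x": range(5)}), seed=0)


class TestFitModel:
    def _heldout_r2(self, name, noise, seed=42):
        table = make_regression_table(name, 500, noise, seed=seed)
        spec = ModelSpec(name, "THSA")
        sp = split_and_validate(table, seed=1)
        model = fit_model(spec, table.iloc[sp.train_idx], seed=1)
        pred = predict(model, spec, table.iloc[sp.test_idx])
        truth = table.iloc[sp.test_idx]["THSA"].to_numpy()
        records = [
            PredictionRecord(str(i), "THSA", float(p), float(t))
            for i, (p, t) in enumerate(zip(pred, truth))
        ]
        return r_squared(records)

    def test_linear_target_recovered_by_tfm(self):
        assert self._heldout_r2("TFM", 0.0) > 0.99

    def test_nbm_recovers_thsa_relation(self):
        assert self._heldout_r2("NBM", 0.0) > 0.95

    def test_constant_target_gives_constant_predictions(self):
        table = make_regression_table("TFM", 100, 0.0, seed=0)
        table["THSA"] = 5.0
        spec = ModelSpec("TFM", "THSA")
        model = fit_model(spec, table, seed=0)
        pred = predict(model, spec, table)
        assert np.allclose(pred, 5.0)

    def test_missing_feature_column_rejected(self):
        table = make_regression_table("TFM", 50, 0.0, seed=0).drop(columns=["length"])
        with pytest.raises(ValueError):
            fit_model(ModelSpec("TFM", "THSA"), table)

    def test_fit_deterministic_given_seed(self):
        table = make_regression_table("NBM", 100, 0.1, seed=3)
        spec = ModelSpec("NBM", "THSA")
        m1 = fit_model(spec, table, seed=5, param_grid={})
        m2 = fit_model(spec, table, seed=5, param_grid={})
        assert np.allclose(m1.predict(table[NBM_FEATURES]), m2.predict(table[NBM_FEATURES]))
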