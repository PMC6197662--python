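"""Feature-extraction behaviour: index standardization, correlation factors
against a brute-force oracle, and the algebraic invariants of the final
pseudo-composition vector."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xylact.errors import (
    AlphabetError,
    DegenerateIndexError,
    IncompleteTableError,
    NormalizationError,
    ParameterError,
    SequenceTooShortError,
)
from xylact.pseaac import (
    CANONICAL_RESIDUES,
    EnzymeSequence,
    IndexTable,
    PseAACEncoder,
    PseAACParams,
    compare_feature_matrices,
    correlation_factors,
    default_hydrophilicity,
    default_hydrophobicity,
    extract_features,
    normalize_index,
    pseaac_vector,
    residue_frequencies,
)

sequences = st.text(alphabet=CANONICAL_RESIDUES, min_size=10, max_size=120)


def naive_correlation_factors(residues, lam, params):
    """Independent double-loop oracle for the tau vector."""
    h1 = normalize_index(params.hydrophobicity).values
    h2 = normalize_index(params.hydrophilicity).values
    L = len(residues)
    tau = []
    for k in range(1, lam + 1):
        t1 = sum(h1[residues[i]] * h1[residues[i + k]] for i in range(L - k))
        t2 = sum(h2[residues[i]] * h2[residues[i + k]] for i in range(L - k))
        tau.extend([t1 / (L - k), t2 / (L - k)])
    return np.array(tau)


class TestIndexTables:
    @pytest.mark.parametrize("table", [default_hydrophobicity(), default_hydrophilicity()])
    def test_standardization_gives_zero_mean_unit_population_sd(self, table):
        arr = normalize_index(table).as_array()
        assert abs(arr.mean()) < 1e-9
        assert abs(np.sqrt((arr**2).mean()) - 1.0) < 1e-9

    def test_constant_table_is_degenerate(self):
        flat = IndexTable("flat", {aa: 3.0 for aa in CANONICAL_RESIDUES})
        with pytest.raises(DegenerateIndexError):
            normalize_index(flat)

    def test_missing_residue_rejected(self):
        values = {aa: 1.0 for aa in CANONICAL_RESIDUES[:-1]}
        with pytest.raises(IncompleteTableError):
            IndexTable("partial", values)


class TestSequencesAndFrequencies:
    def test_nonstandard_residue_policy(self):
        with pytest.raises(AlphabetError):
            EnzymeSequence("x", "ACDX")
        dropped = EnzymeSequence("x", "ACDX", on_nonstandard="drop")
        assert dropped.residues == "ACD"

    def test_lowercase_input_is_uppercased(self):
        assert EnzymeSequence("x", "acd").residues == "ACD"

    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("AAA", {"A": 1.0}),
            ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
        ],
    )
    def test_known_compositions(self, residues, expected):
        f = residue_frequencies(EnzymeSequence("x", residues))
        for j, aa in enumerate(CANONICAL_RESIDUES):
            assert f[j] == pytest.approx(expected.get(aa, 0.0))

    @settings(max_examples=50, derandomize=True)
    @given(sequences)
    def test_frequencies_sum_to_one(self, residues):
        assert residue_frequencies(EnzymeSequence("x", residues)).sum() == pytest.approx(1.0)


class TestCorrelationFactors:
    def test_homopolymer_tiers_equal_squared_index(self):
        params = PseAACParams(lambda_=2)
        tau = correlation_factors(EnzymeSequence("x", "A" * 10), params).tau
        h1a = normalize_index(params.hydrophobicity).values["A"]
        h2a = normalize_index(params.hydrophilicity).values["A"]
        assert tau[0] == pytest.approx(h1a**2) and tau[2] == pytest.approx(h1a**2)
        assert tau[1] == pytest.approx(h2a**2) and tau[3] == pytest.approx(h2a**2)

    def test_sequence_shorter_than_lambda_rejected(self):
        with pytest.raises(SequenceTooShortError):
            correlation_factors(EnzymeSequence("x", "ACDEF"), PseAACParams(lambda_=7))

    @settings(max_examples=40, derandomize=True)
    @given(sequences, st.integers(min_value=1, max_value=7))
    def test_vectorized_matches_double_loop_oracle(self, residues, lam):
        params = PseAACParams(lambda_=lam)
        tau = correlation_factors(EnzymeSequence("x", residues), params).tau
        expected = naive_correlation_factors(residues, lam, params)
        np.testing.assert_allclose(tau, expected, atol=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(sequences)
    def test_reversal_leaves_tau_unchanged(self, residues):
        params = PseAACParams(lambda_=7)
        fwd = correlation_factors(EnzymeSequence("f", residues), params).tau
        rev = correlation_factors(EnzymeSequence("r", residues[::-1]), params).tau
        np.testing.assert_allclose(fwd, rev, atol=1e-12)


class TestPseAACVector:
    def test_default_vector_has_34_elements(self):
        v = pseaac_vector(EnzymeSequence("x", CANONICAL_RESIDUES * 3))
        assert v.shape == (34,)

    @settings(max_examples=50, derandomize=True)
    @given(sequences)
    def test_elements_sum_to_one_and_composition_nonnegative(self, residues):
        v = pseaac_vector(EnzymeSequence("x", residues))
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert (v[:20] >= 0).all()

    @settings(max_examples=30, derandomize=True)
    @given(sequences)
    def test_reversal_leaves_full_vector_unchanged(self, residues):
        fwd = pseaac_vector(EnzymeSequence("f", residues))
        rev = pseaac_vector(EnzymeSequence("r", residues[::-1]))
        np.testing.assert_allclose(fwd, rev, atol=1e-12)

    def test_lambda_zero_is_plain_composition(self):
        seq = EnzymeSequence("x", "ACDEACD")
        v = pseaac_vector(seq, PseAACParams(lambda_=0))
        np.testing.assert_allclose(v, residue_frequencies(seq))

    def test_zero_weight_turns_off_order_terms(self):
        seq = EnzymeSequence("x", "ACDEFGHIKL" * 3)
        v = pseaac_vector(seq, PseAACParams(lambda_=7, weight=0.0))
        np.testing.assert_allclose(v[:20], residue_frequencies(seq))
        np.testing.assert_allclose(v[20:], 0.0)

    def test_permutation_changes_only_order_terms(self):
        rng = np.random.default_rng(0)
        residues = "".join(rng.choice(list(CANONICAL_RESIDUES), 60))
        shuffled = "".join(rng.permutation(list(residues)))
        a = pseaac_vector(EnzymeSequence("a", residues))
        b = pseaac_vector(EnzymeSequence("b", shuffled))
        # composition terms agree up to the (shared) denominator rescaling
        np.testing.assert_allclose(a[:20] / a[:20].sum(), b[:20] / b[:20].sum(),
                                   atol=1e-12)

    def test_negative_denominator_raises(self):
        # anticorrelated index + alternating sequence + large weight pushes
        # the denominator below zero
        spiky = {aa: 0.0 for aa in CANONICAL_RESIDUES}
        spiky.update({"A": 5.0, "R": -5.0})
        table = IndexTable("spiky", spiky)
        params = PseAACParams(lambda_=1, weight=5.0,
                              hydrophobicity=table, hydrophilicity=table)
        with pytest.raises(NormalizationError):
            pseaac_vector(EnzymeSequence("x", "AR" * 20), params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            PseAACParams(lambda_=-1)
        with pytest.raises(ParameterError):
            PseAACParams(weight=-0.1)


class TestBatchExtraction:
    def test_row_order_and_duplicates(self):
        seqs = [EnzymeSequence("a", "ACDEFGHIKL"), EnzymeSequence("b", "ACDEFGHIKL")]
        m = extract_features(seqs, PseAACParams(lambda_=3))
        assert list(m.index) == ["a", "b"]
        np.testing.assert_allclose(m.iloc[0], m.iloc[1])

    def test_empty_input_gives_empty_matrix(self):
        m = extract_features([], PseAACParams(lambda_=7))
        assert m.shape == (0, 34)

    def test_matrix_comparison_flags_perturbed_column(self):
        seqs = [EnzymeSequence(f"s{i}", CANONICAL_RESIDUES * 2) for i in range(3)]
        m = extract_features(seqs)
        assert compare_feature_matrices(m, m.copy(), tol=1e-6).passed
        bad = m.copy()
        bad.iloc[1, 4] += 2e-6
        report = compare_feature_matrices(m, bad, tol=1e-6)
        assert not report.passed and report.failing_columns == ["e5"]
        with pytest.raises(ParameterError):
            compare_feature_matrices(m, m.iloc[:, :10], tol=1e-6)


class TestEncoder:
    def test_transform_accepts_plain_strings(self):
        enc = PseAACEncoder(lambda_=4)
        X = enc.fit_transform(["ACDEFGHIKLMN", "ACDEFGHIKLMN"])
        assert X.shape == (2, 28)
        assert list(enc.get_feature_names_out()) == [f"e{i}" for i in range(1, 29)]

    def test_sklearn_param_interface(self):
        enc = PseAACEncoder()
        assert enc.get_params()["lambda_"] == 7
        enc.set_params(lambda_=2, weight=0.1)
        assert enc.fit([]).n_features_out_ == 24

    def test_pipeline_composition(self):
        from sklearn.pipeline import make_pipeline
        from xylact.models import KNNRegressor

        pipe = make_pipeline(PseAACEncoder(lambda_=2), KNNRegressor(n_neighbors=1))
        seqs = ["ACDEFGHIKL" * 2, "MNPQRSTVWY" * 2, "AAAAACCCCC" * 2]
        pipe.fit(seqs, np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(pipe.predict(seqs), [1.0, 2.0, 3.0])
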