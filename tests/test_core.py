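import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmfe.core import (FmfeConfig, FuzzyFeatureMatrix, MatchSettings,
                       OptimizedFilterBank, TemplateFeatureMatrix,
                       extract_fmfe, fuzzy_features, match_time_domain_self,
                       matching_degree, optimize_filters, template_features)
from fmfe.errors import ValidationError
from fmfe.signal_io import PcgSignal
from fmfe.synthetic import generate_signal
from fmfe.templating import Template
from fmfe.wavelets import build_wavelet_bank
from oracles import conv_full, match_pipeline


def make_template(values):
    return Template(np.asarray(values, float), "time")


# ---------------------------------------------------------------- template features

def test_template_features_impulse_reproduces_filters():
    bank = build_wavelet_bank(8, 6)
    impulse = np.zeros(20)
    impulse[0] = 1.0
    X = template_features(make_template(impulse), bank)
    assert X.rows.shape == (8, 25)
    np.testing.assert_allclose(X.rows[:, :6], bank.filters, atol=1e-15)
    assert np.allclose(X.rows[:, 6:], 0.0)


def test_template_features_zero_and_oracle(rng):
    bank = build_wavelet_bank(8, 6)
    assert np.all(template_features(make_template(np.zeros(30)), bank).rows == 0)
    m = rng.standard_normal(50)
    X = template_features(make_template(m), bank)
    for row, w in zip(X.rows, bank.filters):
        np.testing.assert_allclose(row, conv_full(m.tolist(), w.tolist()),
                                   atol=1e-12)
    with pytest.raises(ValidationError):
        template_features(make_template(np.ones(4)), bank)


# ---------------------------------------------------------------- eigen optimization

def test_full_component_count_preserves_trace(rng):
    bank = build_wavelet_bank(6, 8)
    X = template_features(make_template(rng.standard_normal(40)), bank)
    mask, optimized = optimize_filters(X, bank, n_components=6)
    np.testing.assert_allclose(mask.columns.T @ mask.columns, np.eye(6),
                               atol=1e-10)
    assert np.isclose(mask.eigenvalues.sum(), np.trace(X.rows @ X.rows.T),
                      rtol=1e-9)
    # change of basis preserves the Frobenius norm of the row space map
    np.testing.assert_allclose(
        np.linalg.norm(mask.columns.T @ bank.filters),
        np.linalg.norm(optimized.filters), rtol=1e-12)


def test_rank_one_feature_matrix_selects_that_row(rng):
    bank = build_wavelet_bank(5, 6)
    rows = np.zeros((5, 30))
    rows[3] = rng.standard_normal(30)
    mask, _ = optimize_filters(TemplateFeatureMatrix(rows), bank, 1)
    expected = np.zeros(5)
    expected[3] = 1.0
    np.testing.assert_allclose(np.abs(mask.columns[:, 0]), expected, atol=1e-10)
    assert mask.columns[3, 0] > 0                      # sign fixed positive
    assert np.isclose(mask.eigenvalues[0], np.dot(rows[3], rows[3]))


def test_eigenvalues_sorted_and_sign_convention(rng):
    bank = build_wavelet_bank(8, 6)
    X = template_features(make_template(rng.standard_normal(100)), bank)
    mask, _ = optimize_filters(X, bank, 5)
    assert np.all(np.diff(mask.eigenvalues) <= 1e-12)
    for col in mask.columns.T:
        assert col[np.argmax(np.abs(col))] > 0
    with pytest.raises(ValidationError):
        optimize_filters(X, bank, 9)
    with pytest.raises(ValidationError):
        optimize_filters(X, bank, 0)


# ---------------------------------------------------------------- fuzzy features

def test_fuzzy_features_trim_arithmetic(rng):
    filters = OptimizedFilterBank(rng.standard_normal((3, 6)))
    x = rng.standard_normal(40)
    full = fuzzy_features(x, filters, trim_amount=0)
    assert full.rows.shape == (3, 45)
    default = fuzzy_features(x, filters)                 # trim = L-1
    assert default.rows.shape == (3, 40 - 6 + 1)
    np.testing.assert_array_equal(default.rows, full.rows[:, 5:-5])
    impulse = np.zeros(10)
    impulse[0] = 1.0
    rows = fuzzy_features(impulse, filters, trim_amount=0).rows
    np.testing.assert_allclose(rows[:, :6], filters.filters, atol=1e-15)


def test_fuzzy_features_matches_loop_oracle(rng):
    filters = OptimizedFilterBank(rng.standard_normal((2, 4)))
    x = rng.standard_normal(25)
    got = fuzzy_features(x, filters, trim_amount=2)
    for row, w in zip(got.rows, filters.filters):
        conv = conv_full(x.tolist(), w.tolist())
        np.testing.assert_allclose(row, conv[2:-2], atol=1e-12)
    with pytest.raises(ValidationError):
        fuzzy_features(np.ones(3), filters)              # shorter than filter


# ---------------------------------------------------------------- matching degree

def _fuzzy(values, filters, trim):
    return fuzzy_features(np.asarray(values, float),
                          OptimizedFilterBank(filters), trim)


def test_identical_rows_give_unit_degree(rng):
    w = rng.standard_normal((2, 3))
    x = rng.standard_normal(12)
    Xs = _fuzzy(x, w, 2)
    result = matching_degree(Xs, Xs, "ncc")
    assert result.degree.size == 1
    assert np.isclose(result.mmd, 1.0, atol=1e-12)
    negated = FuzzyFeatureMatrix(-Xs.rows[:1], -Xs.raw[:1], Xs.trim_amount)
    anti = matching_degree(FuzzyFeatureMatrix(Xs.rows[:1], Xs.raw[:1], 2),
                           negated, "ncc")
    assert np.isclose(anti.mmd, -1.0, atol=1e-12)


def test_three_lag_worked_example():
    # template row [1,2] against signal row [0,1,2,0]: the middle window
    # matches exactly, the flanks follow the dot-product/norm arithmetic
    Xs = FuzzyFeatureMatrix(np.array([[0.0, 1.0, 2.0, 0.0]]),
                            np.array([[0.0, 1.0, 2.0, 0.0]]), 0)
    Xm = FuzzyFeatureMatrix(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]), 0)
    result = matching_degree(Xs, Xm, "ncc")
    expected = [2 / np.sqrt(5), 1.0, 2 / (2 * np.sqrt(5))]
    np.testing.assert_allclose(result.degree, expected, atol=1e-12)
    assert result.mmd_index == 1
    _, degree, mmd, idx, energies = match_pipeline(
        [0.0, 1.0, 2.0, 0.0], [1.0, 2.0], [[1.0]], 0)
    np.testing.assert_allclose(result.degree, degree, atol=1e-12)
    np.testing.assert_allclose(result.energies, energies, atol=1e-12)


def test_literal_mode_is_proportional_to_ncc(rng):
    w = rng.standard_normal((3, 4))
    s, m = rng.standard_normal(60), rng.standard_normal(20)
    Xs, Xm = _fuzzy(s, w, 3), _fuzzy(m, w, 3)
    ncc = matching_degree(Xs, Xm, "ncc")
    literal = matching_degree(Xs, Xm, "literal")
    for i in range(3):
        scale = np.linalg.norm(Xm.rows[i])
        np.testing.assert_allclose(literal.traces[i] * scale, ncc.traces[i],
                                   atol=1e-9)
    assert literal.mmd_index == ncc.mmd_index


def test_silent_windows_flagged_not_raised():
    Xs = FuzzyFeatureMatrix(np.array([[0.0, 0.0, 1.0, 1.0]]),
                            np.array([[0.0, 0.0, 1.0, 1.0]]), 0)
    Xm = FuzzyFeatureMatrix(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]), 0)
    result = matching_degree(Xs, Xm, "ncc")
    assert result.traces[0, 0] == 0.0
    assert result.zero_norm_lags[0] and not result.zero_norm_lags[2]
    zero_template = FuzzyFeatureMatrix(np.zeros((1, 2)), np.zeros((1, 2)), 0)
    with pytest.raises(ValidationError):
        matching_degree(Xs, zero_template, "ncc")


def test_slide_mode_covers_every_start_position(rng):
    w = rng.standard_normal((2, 3))
    s, m = rng.standard_normal(30), rng.standard_normal(12)
    Xs, Xm = _fuzzy(s, w, 2), _fuzzy(m, w, 2)
    result = matching_degree(Xs, Xm, "ncc", mode="slide")
    assert result.degree.size == Xs.row_length
    traces, degree, mmd, idx, energies = match_pipeline(
        s.tolist(), m.tolist(), w.tolist(), 2, mode="slide")
    np.testing.assert_allclose(result.traces, traces, atol=1e-9)
    np.testing.assert_allclose(result.energies, energies, atol=1e-9)
    assert result.mmd_index == idx


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from(["valid", "slide"]))
def test_ncc_traces_bounded_by_one(seed, mode):
    """Cauchy-Schwarz: every normalized trace lies in [-1, 1]."""
    r = np.random.default_rng(seed)
    w = r.standard_normal((2, 4))
    Xs, Xm = _fuzzy(r.standard_normal(40), w, 3), _fuzzy(r.standard_normal(15), w, 3)
    result = matching_degree(Xs, Xm, "ncc", mode=mode)
    assert np.all(np.abs(result.traces) <= 1 + 1e-9)


# ---------------------------------------------------------------- end-to-end blocks

def test_time_domain_tiling_identity(rng):
    cycle = rng.standard_normal(400)
    signal = PcgSignal(np.tile(cycle, 3), 8000, id="tiled")
    md, me = match_time_domain_self(signal, MatchSettings())
    np.testing.assert_allclose(md, 1.0, atol=1e-9)
    assert me.shape == (3, 3)
    assert np.all(me > 0)


def test_feature_vector_shape_names_and_determinism(fast_config, rng):
    signal = generate_signal("MR", fast_config, np.random.default_rng(7), "mr0")
    config = FmfeConfig()
    v1 = extract_fmfe(signal, config)
    v2 = extract_fmfe(signal, config)
    assert len(v1) == 36
    assert len(v1.names) == 36 and len(set(v1.names)) == 36
    np.testing.assert_array_equal(v1.values, v2.values)   # bitwise determinism
    assert v1.names[:3] == ["TD.S.MD.1", "TD.S.MD.2", "TD.S.MD.3"]
    assert v1.names[-1] == "FD.M.ME.3.3"


def test_component_count_sets_vector_length(fast_config):
    signal = generate_signal("NHS", fast_config, np.random.default_rng(3), "n0")
    config = FmfeConfig(time=MatchSettings(n_components=1),
                        freq=MatchSettings(length=2, n_components=1, mode="slide"))
    assert len(extract_fmfe(signal, config)) == 18      # 9 * (O + 1), O = 1
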