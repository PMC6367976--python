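"""Encoding, similarity sorting, padding/shaping and target transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coalcnn import imageprep as ip


# --- encodings ---------------------------------------------------------------


@pytest.mark.parametrize("encoding,expected", [
    (ip.Encoding.ZERO_ONE, [[0.0, 1.0]]),
    (ip.Encoding.ZERO_255, [[0.0, 255.0]]),
    (ip.Encoding.NEG_POS, [[-1.0, 1.0]]),
])
def test_encode_symbol_maps(encoding, expected):
    assert ip.encode_alleles(np.array([[0, 1]]), encoding).tolist() == expected


def test_encoding_is_bijective_on_symbols():
    rng = np.random.default_rng(0)
    m = rng.integers(0, 2, size=(12, 30))
    for enc in ip.Encoding.SYMBOLS:
        assert (ip.decode_alleles(ip.encode_alleles(m, enc), enc) == m).all()


def test_unknown_encoding_rejected():
    with pytest.raises(ValueError):
        ip.encode_alleles(np.zeros((1, 1)), "hex")


# --- similarity sorting -------------------------------------------------------


def test_sort_worked_four_row_example():
    """Greedy chain from row A=000: nearest is C (d=1), then from C the
    nearest unplaced is B (d=2), leaving D — order A, C, B, D."""
    m = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 1], [1, 1, 0]])
    perm, out = ip.sort_by_similarity(m)
    assert perm.tolist() == [0, 2, 1, 3]
    assert (out == m[perm]).all()


def test_identical_rows_keep_input_order():
    m = np.ones((5, 4), dtype=int)
    perm, _ = ip.sort_by_similarity(m)
    assert perm.tolist() == [0, 1, 2, 3, 4]


def test_single_row_identity():
    perm, out = ip.sort_by_similarity(np.array([[1, 0]]))
    assert perm.tolist() == [0]


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_sort_is_permutation_and_idempotent(seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(0, 2, size=(rng.integers(2, 15), rng.integers(1, 20)))
    perm, out = ip.sort_by_similarity(m)
    assert sorted(perm.tolist()) == list(range(m.shape[0]))
    # row multisets match
    assert sorted(map(tuple, out.tolist())) == sorted(map(tuple, m.tolist()))
    perm2, _ = ip.sort_by_similarity(out)
    assert perm2.tolist() == list(range(m.shape[0]))


def test_sorting_reduces_adjacent_hamming_distance_on_average():
    """Over random 20 x 40 binary matrices the mean sum of adjacent-row
    Hamming distances after sorting must be below the unsorted mean
    (one-sided paired comparison, far beyond the alpha=0.01 bar)."""
    rng = np.random.default_rng(42)
    diffs = []
    for _ in range(200):
        m = rng.integers(0, 2, size=(20, 40))
        _, s = ip.sort_by_similarity(m)
        before = np.abs(np.diff(m, axis=0)).sum()
        after = np.abs(np.diff(s, axis=0)).sum()
        diffs.append(before - after)
    diffs = np.array(diffs, dtype=float)
    t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
    assert diffs.mean() > 0 and t > 2.33  # one-sided z at alpha = 0.01


def test_sort_handles_real_valued_matrices():
    m = np.array([[0.0, 0.0], [1.0, 1.0], [0.1, 0.0]])
    perm, _ = ip.sort_by_similarity(m)
    assert perm.tolist() == [0, 2, 1]


# --- padding and shaping -------------------------------------------------------


def test_pad_and_shape_dimensions_and_padding_value():
    rng = np.random.default_rng(1)
    enc = ip.encode_alleles(rng.integers(0, 2, size=(34, 1000)), ip.Encoding.ZERO_ONE)
    img, pos = ip.pad_and_shape(enc, np.sort(rng.random(1000)), width_W=1201,
                                sort=False, transpose=True)
    assert img.pixels.shape == (1201, 34)
    assert (img.pixels[1000:] == 0).all()  # 201 padded site rows, ancestral symbol
    assert img.n_real_sites == 1000 and img.width_W == 1201
    assert (pos.values[1000:] == -1).all()


def test_pad_never_alters_real_sites_and_exact_width_unpadded():
    rng = np.random.default_rng(2)
    m = rng.integers(0, 2, size=(6, 10))
    enc = ip.encode_alleles(m, ip.Encoding.NEG_POS)
    img, _ = ip.pad_and_shape(enc, np.sort(rng.random(10)), width_W=10,
                              sort=False, transpose=False,
                              encoding=ip.Encoding.NEG_POS)
    assert (img.pixels == enc).all()  # no padding applied
    img2, _ = ip.pad_and_shape(enc, np.sort(rng.random(10)), width_W=14,
                               sort=False, transpose=False,
                               encoding=ip.Encoding.NEG_POS)
    assert (img2.pixels[:, :10] == enc).all()
    assert (img2.pixels[:, 10:] == -1).all()  # ancestral symbol of NEG_POS


def test_positions_padded_with_minus_one():
    enc = np.zeros((2, 1), dtype=np.float32)
    _, pos = ip.pad_and_shape(enc, np.array([0.5]), width_W=3, sort=False,
                              transpose=True)
    assert pos.values.tolist() == [0.5, -1.0, -1.0]


def test_overflow_raises_naming_alignment():
    enc = np.zeros((2, 5), dtype=np.float32)
    with pytest.raises(ValueError, match="rep7"):
        ip.pad_and_shape(enc, np.linspace(0, 1, 5), width_W=3, name="rep7")


def test_sort_applies_before_transposition():
    m = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 1]], dtype=np.float32)
    img, _ = ip.pad_and_shape(m, np.array([0.1, 0.2, 0.3]), width_W=3,
                              sort=True, transpose=True)
    perm, _ = ip.sort_by_similarity(m)
    assert (img.pixels == m[perm].T).all()


# --- distances -----------------------------------------------------------------


def test_distances_arithmetic_and_padding():
    d = ip.positions_to_distances(np.array([0.1, 0.4, 0.9]), out_length=2)
    assert np.allclose(d.values, [0.3, 0.5])
    d2 = ip.positions_to_distances(np.array([0.7]), out_length=3)
    assert d2.values.tolist() == [0.0, 0.0, 0.0]


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_distances_telescope_to_span(seed):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.random(rng.integers(2, 40)))
    d = ip.positions_to_distances(pos, out_length=50)
    assert np.isclose(d.values.sum(), pos[-1] - pos[0], atol=1e-6)


def test_distances_reject_unsorted_and_short_output():
    with pytest.raises(ValueError):
        ip.positions_to_distances(np.array([0.5, 0.1]), 4)
    with pytest.raises(ValueError):
        ip.positions_to_distances(np.linspace(0, 1, 5), 2)


# --- target transforms -----------------------------------------------------------


def test_log_center_example():
    tf = ip.fit_target_transform(np.exp([1.0, 3.0]), log_flag=True)
    assert np.allclose(tf.apply(np.exp([1.0, 3.0])).ravel(), [-1.0, 1.0])


def test_zscore_example():
    tf = ip.fit_target_transform(np.array([0.0, 2.0]), zscore_flag=True)
    assert np.allclose(tf.apply(np.array([0.0, 2.0])).ravel(), [-1.0, 1.0])


def test_transform_statistics_come_from_training_split_only():
    train = np.array([1.0, 3.0])
    tf = ip.fit_target_transform(train, log_flag=False, zscore_flag=False)
    # applying to other data must reuse the train mean (2.0), not recentre
    assert np.allclose(tf.apply(np.array([10.0, 20.0])).ravel(), [8.0, 18.0])


@given(st.integers(0, 2**31 - 1), st.booleans(), st.booleans())
@settings(max_examples=25, deadline=None)
def test_transform_roundtrip(seed, log_flag, zscore_flag):
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.1, 50, size=(30, 3))
    tf = ip.fit_target_transform(v, log_flag=log_flag, zscore_flag=zscore_flag)
    assert np.allclose(tf.invert(tf.apply(v)), v, rtol=1e-10)


def test_log_transform_rejects_nonpositive():
    with pytest.raises(ValueError):
        ip.fit_target_transform(np.array([1.0, 0.0]), log_flag=True)
    tf = ip.fit_target_transform(np.array([1.0, 2.0]), log_flag=True)
    with pytest.raises(ValueError):
        tf.apply(np.array([-1.0]))
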