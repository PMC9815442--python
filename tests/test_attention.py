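"""Mask families, masked attention, truncation and combination schemes."""

import json

import numpy as np
import pytest

from tracheidnet.attention import (
    AttentionWeights,
    attend,
    build_pattern,
    combine_interleaved,
    combine_multihead,
    top_k_truncate,
)

# ---------------------------------------------------------------------------
# index-set construction


def rule_set(family, n, k, i):
    """Literal enumeration of the connectivity rules."""
    out = []
    for j in range(1, n + 1):
        d = abs(i - j)
        if family == "dense":
            ok = True
        elif family == "local":
            ok = d <= k
        elif family == "atrous":
            ok = d % k == 0
        else:
            ok = d <= k or (d % k == 0 and d >= 2 * k)
        if ok:
            out.append(j)
    return tuple(out)


@pytest.mark.parametrize(
    ("family", "n", "k", "i", "expected"),
    [
        ("local", 9, 2, 5, (3, 4, 5, 6, 7)),
        ("atrous", 9, 2, 1, (1, 3, 5, 7, 9)),
        ("sparse", 13, 2, 7, (1, 3, 5, 6, 7, 8, 9, 11, 13)),
        ("dense", 4, None, 2, (1, 2, 3, 4)),
    ],
)
def test_pattern_worked_examples(family, n, k, i, expected):
    assert build_pattern(family, n, k).S[i - 1] == expected


def test_patterns_match_rule_enumeration_exhaustively():
    """Every index set for n <= 20, k <= 5 equals the literal rule."""
    for n in range(1, 21):
        for family in ("dense", "local", "atrous", "sparse"):
            for k in range(1, 6):
                if family == "atrous" and k < 2:
                    continue
                p = build_pattern(family, n, k)
                for i in range(1, n + 1):
                    assert p.S[i - 1] == rule_set(family, n, k, i), (family, n, k, i)


def test_pattern_invariants():
    for family, k in (("local", 3), ("atrous", 2), ("sparse", 2), ("dense", None)):
        p = build_pattern(family, 15, k)
        for i, s in enumerate(p.S, start=1):
            assert s and i in s and all(1 <= j <= 15 for j in s)
        if family == "local":
            assert all(len(s) <= 2 * k + 1 for s in p.S)


def test_sparsity_accounting():
    n, k = 18, 3
    local = build_pattern("local", n, k)
    atrous = build_pattern("atrous", n, k)
    sparse = build_pattern("sparse", n, k)
    assert sum(len(s) for s in local.S) <= n * (2 * k + 1)
    assert sum(len(s) for s in atrous.S) <= n * (int(np.ceil(n / k)) + 1)
    for i in range(n):
        strided = {j for j in sparse.S[i] if abs(j - (i + 1)) >= 2 * k}
        assert set(local.S[i]) | strided == set(sparse.S[i])


def test_pattern_config_errors():
    with pytest.raises(ValueError):
        build_pattern("atrous", 5, 1)
    with pytest.raises(ValueError):
        build_pattern("banded", 5, 1)
    with pytest.raises(ValueError):
        build_pattern("local", 0, 1)


def test_pattern_json_roundtrip():
    p = build_pattern("sparse", 6, 2)
    payload = json.loads(p.to_json())
    assert payload["n"] == 6 and payload["family"] == "sparse"
    assert payload["S"][0] == list(p.S[0])


# ---------------------------------------------------------------------------
# attention numerics


def _weights(rng, c, d, out=None):
    return AttentionWeights(
        wq=rng.normal(size=(d, c)),
        wk=rng.normal(size=(d, c)),
        wv=rng.normal(size=(d, c)),
        wp=rng.normal(size=(out or d, d)),
    )


def test_singleton_sequence_returns_value_projection():
    rng = np.random.default_rng(0)
    w = _weights(rng, 3, 2)
    x = rng.normal(size=(1, 3))
    out = attend(x, build_pattern("dense", 1), w)
    assert np.allclose(out, x @ w.wv.T)


def test_identical_inputs_give_uniform_weights():
    rng = np.random.default_rng(1)
    w = _weights(rng, 3, 2)
    x = np.tile(rng.normal(size=(1, 3)), (5, 1))
    out = attend(x, build_pattern("dense", 5), w)
    assert np.allclose(out, x @ w.wv.T)      # mean of identical values


def test_three_token_scalar_oracle():
    """Step-by-step hand computation with 2x2 matrices."""
    wq = np.array([[1.0, 0.0], [0.0, 1.0]])
    wk = np.array([[0.5, 0.0], [0.0, 0.5]])
    wv = np.array([[1.0, 1.0], [0.0, 1.0]])
    w = AttentionWeights(wq=wq, wk=wk, wv=wv, wp=np.eye(2))
    x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    d = 2
    expected = np.zeros((3, 2))
    keys = x @ wk.T
    vals = x @ wv.T
    for i in range(3):
        q = wq @ x[i]
        scores = np.array([q @ keys[j] / np.sqrt(d) for j in range(3)])
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        expected[i] = sum(a[j] * vals[j] for j in range(3))
    out = attend(x, build_pattern("dense", 3), w)
    assert np.allclose(out, expected, atol=1e-12)


def test_dense_pattern_equals_textbook_attention():
    rng = np.random.default_rng(2)
    w = _weights(rng, 4, 4)
    x = rng.normal(size=(7, 4))
    q, k, v = x @ w.wq.T, x @ w.wk.T, x @ w.wv.T
    s = q @ k.T / np.sqrt(4)
    a = np.exp(s - s.max(axis=1, keepdims=True))
    a /= a.sum(axis=1, keepdims=True)
    assert np.allclose(attend(x, build_pattern("dense", 7), w), a @ v, atol=1e-6)


@pytest.mark.parametrize("family,k", [("local", 2), ("atrous", 3), ("sparse", 2)])
def test_positions_outside_the_index_set_have_no_influence(family, k):
    rng = np.random.default_rng(3)
    w = _weights(rng, 3, 3)
    x = rng.normal(size=(9, 3))
    p = build_pattern(family, 9, k)
    base = attend(x, p, w)
    for i in range(9):
        outside = [j for j in range(1, 10) if j not in p.S[i]]
        if not outside:
            continue
        x2 = x.copy()
        x2[outside[0] - 1] += 10.0
        assert np.allclose(attend(x2, p, w)[i], base[i])


def test_saturated_mask_equals_dense():
    rng = np.random.default_rng(4)
    w = _weights(rng, 3, 3)
    x = rng.normal(size=(6, 3))
    dense = attend(x, build_pattern("dense", 6), w)
    for family in ("local", "sparse"):
        sat = attend(x, build_pattern(family, 6, 6), w)
        assert np.allclose(sat, dense, atol=1e-6)


# ---------------------------------------------------------------------------
# top-k truncation


@pytest.mark.parametrize(
    ("scores", "k", "expected"),
    [
        ((3.0, 1.0, 2.0), 2, [True, False, True]),
        ((3.0, 1.0, 2.0), 5, [True, True, True]),    # no-op bound
        ((3.0, 1.0, 2.0), 1, [True, False, False]),
        ((1.0, 1.0, 1.0), 2, [True, True, False]),   # ties -> smaller index
    ],
)
def test_top_k_truncate(scores, k, expected):
    assert list(top_k_truncate(np.array(scores), k)) == expected


def test_truncated_attend_excludes_dropped_scores():
    rng = np.random.default_rng(5)
    w = _weights(rng, 2, 2)
    x = np.array([[5.0, 0.0], [0.1, 0.1], [4.0, 0.2], [0.0, 3.0]])
    full = attend(x, build_pattern("dense", 4), w)
    trunc = attend(x, build_pattern("dense", 4), w, kattn=2)
    assert not np.allclose(full, trunc)
    one = attend(x, build_pattern("dense", 4), w, kattn=4)
    assert np.allclose(full, one)


# ---------------------------------------------------------------------------
# combination schemes


def test_interleaved_modular_selection():
    rng = np.random.default_rng(6)
    w = _weights(rng, 3, 3, out=2)
    x = rng.normal(size=(5, 3))
    pats = [build_pattern("local", 5, 1), build_pattern("atrous", 5, 2)]
    for r in (0, 1, 2, 3, 4):
        got = combine_interleaved(x, pats, r, w)
        manual = attend(x, pats[r % 2], w) @ w.wp.T
        assert np.allclose(got, manual)


def test_multihead_reduces_to_interleaved_for_one_head():
    rng = np.random.default_rng(7)
    w = _weights(rng, 3, 3, out=2)
    x = rng.normal(size=(4, 3))
    pats = [build_pattern("dense", 4)]
    a = combine_interleaved(x, pats, 0, w)
    b = combine_multihead(x, pats, [w], w.wp)
    assert np.allclose(a, b)


def test_multihead_concatenates_heads():
    rng = np.random.default_rng(8)
    w1 = _weights(rng, 3, 2)
    w2 = _weights(rng, 3, 2)
    x = rng.normal(size=(4, 3))
    pats = [build_pattern("local", 4, 1), build_pattern("dense", 4)]
    wp = rng.normal(size=(3, 4))
    got = combine_multihead(x, pats, [w1, w2], wp)
    manual = np.concatenate(
        [attend(x, pats[0], w1), attend(x, pats[1], w2)], axis=1) @ wp.T
    assert np.allclose(got, manual)
    # identical heads duplicate columns before the post matrix
    dup = combine_multihead(x, [pats[1], pats[1]], [w1, w1], wp)
    half = attend(x, pats[1], w1)
    assert np.allclose(dup, np.concatenate([half, half], axis=1) @ wp.T)


def test_multihead_shape_errors():
    rng = np.random.default_rng(9)
    w = _weights(rng, 3, 2)
    x = rng.normal(size=(4, 3))
    with pytest.raises(ValueError):
        combine_multihead(x, [build_pattern("dense", 4)], [w, w], w.wp)
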