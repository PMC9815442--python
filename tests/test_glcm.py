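"""Co-occurrence matrices and the nine texture features vs brute force."""

import numpy as np
import pytest

from tracheidnet.glcm import (
    FEATURE_NAMES,
    GLCMParams,
    cooccurrence,
    extract_features,
    image_texture,
    quantize,
    texture_features,
)

# ---------------------------------------------------------------------------
# independent oracle: naive pair enumeration and literal feature formulas


def oracle_glcm(window, levels, offset):
    m = np.zeros((levels, levels))
    h, w = window.shape
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[window[r, c] - 1, window[r2, c2] - 1] += 1
    return m / m.sum()


def oracle_features(m):
    g = m.shape[0]
    asm = con = ent = var = idm = 0.0
    u_i = u_j = 0.0
    sij = 0.0
    for i in range(1, g + 1):
        for j in range(1, g + 1):
            p = m[i - 1, j - 1]
            asm += p * p
            con += (i - j) ** 2 * p
            if p > 0:
                ent -= p * np.log(p)
            idm += p / (1 + (i - j) ** 2)
            u_i += i * p
            u_j += j * p
            sij += i * j * p
    d_i = d_j = 0.0
    for i in range(1, g + 1):
        for j in range(1, g + 1):
            p = m[i - 1, j - 1]
            d_i += (i - u_i) ** 2 * p
            d_j += (j - u_j) ** 2 * p
            var += (i - u_i) ** 2 * p
    d_i, d_j = np.sqrt(d_i), np.sqrt(d_j)
    corr = 0.0 if d_i * d_j == 0 else (sij - u_i * u_j) / (d_i * d_j)
    pxy = {k: 0.0 for k in range(2, 2 * g + 1)}
    for i in range(1, g + 1):
        for j in range(1, g + 1):
            pxy[i + j] += m[i - 1, j - 1]
    sa = sum(k * p for k, p in pxy.items())
    sv = sum((k - sa) ** 2 * p for k, p in pxy.items())
    se = -sum(p * np.log(p) for p in pxy.values() if p > 0)
    return np.array([asm, con, corr, ent, var, sa, sv, idm, se])


# ---------------------------------------------------------------------------
# quantization


@pytest.mark.parametrize(
    ("value", "levels", "expected"),
    [(0, 16, 1), (255, 16, 16), (15, 16, 1), (16, 16, 2), (255, 4, 4)],
)
def test_quantize_bin_edges(value, levels, expected):
    assert quantize(np.array([[value]]), levels)[0, 0] == expected


def test_quantize_matches_floor_oracle():
    ramp = np.arange(256).reshape(16, 16)
    assert np.array_equal(quantize(ramp, 4), ramp // 64 + 1)


def test_quantize_rejects_bad_input():
    with pytest.raises(ValueError):
        quantize(np.array([[300]]), 16)
    with pytest.raises(ValueError):
        quantize(np.empty((0, 0)), 16)


# ---------------------------------------------------------------------------
# co-occurrence


def test_constant_window_single_cell():
    m = cooccurrence(np.full((8, 8), 5), GLCMParams())
    assert m[4, 4] == 1.0 and m.sum() == 1.0


def test_two_by_two_window_by_hand():
    m = cooccurrence(np.array([[1, 2], [1, 2]]), GLCMParams(window=2, levels=16))
    assert m[0, 1] == 1.0          # both horizontal pairs are (1, 2)


def test_window_too_small_for_offset():
    with pytest.raises(ValueError):
        cooccurrence(np.array([[1], [2]]), GLCMParams(window=2))


@pytest.mark.parametrize("seed", range(5))
def test_cooccurrence_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    win = rng.integers(1, 17, size=(8, 8))
    p = GLCMParams()
    assert np.allclose(
        cooccurrence(win, p), oracle_glcm(win, 16, p.offset), atol=1e-15
    )


# ---------------------------------------------------------------------------
# features


def test_degenerate_distribution_features():
    m = np.zeros((16, 16))
    m[4, 4] = 1.0
    with pytest.warns(RuntimeWarning):
        f = dict(zip(FEATURE_NAMES, texture_features(m)))
    assert f["ASM"] == 1.0 and f["CON"] == 0.0 and f["ENT"] == 0.0
    assert f["IDM"] == 1.0 and f["VAR"] == 0.0


def test_uniform_distribution_is_maximum_entropy():
    m = np.full((16, 16), 1 / 256)
    f = dict(zip(FEATURE_NAMES, texture_features(m)))
    assert np.isclose(f["ASM"], 1 / 256)
    assert np.isclose(f["ENT"], np.log(256))


def test_hand_worked_two_level_case():
    """All mass on (1,2): contrast 1, IDM 1/2, and the level-sum
    distribution concentrates at k=3 so SA=3, SV=0, SE=0."""
    m = np.zeros((16, 16))
    m[0, 1] = 1.0
    with pytest.warns(RuntimeWarning):
        f = dict(zip(FEATURE_NAMES, texture_features(m)))
    assert f["CON"] == 1.0 and f["IDM"] == 0.5
    assert f["SA"] == 3.0 and f["SV"] == 0.0 and f["SE"] == 0.0


def test_features_match_oracle_on_random_windows():
    """All nine features agree with literal-formula enumeration to 1e-10
    on 50 random 8x8 windows."""
    rng = np.random.default_rng(42)
    p = GLCMParams()
    for _ in range(50):
        win = rng.integers(1, 17, size=(8, 8))
        m = cooccurrence(win, p)
        assert np.allclose(texture_features(m), oracle_features(m), atol=1e-10)


def test_contrast_zero_iff_diagonal():
    rng = np.random.default_rng(0)
    diag = np.diag(rng.dirichlet(np.ones(16)))
    f = dict(zip(FEATURE_NAMES, texture_features(diag)))
    assert f["CON"] == 0.0
    off = np.zeros((16, 16))
    off[0, 1] = off[2, 2] = 0.5
    f2 = dict(zip(FEATURE_NAMES, texture_features(off)))
    assert f2["CON"] > 0


# ---------------------------------------------------------------------------
# per-image aggregation


def test_single_window_identity():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 256, size=(8, 8))
    per_window = texture_features(cooccurrence(quantize(img, 16), GLCMParams()))
    assert np.allclose(image_texture(img).to_numpy(), per_window)


@pytest.mark.parametrize(("h", "w"), [(8, 8), (20, 24), (16, 33)])
def test_image_mean_equals_window_loop(h, w):
    rng = np.random.default_rng(h * 100 + w)
    img = rng.integers(0, 256, size=(h, w))
    p = GLCMParams()
    feats = []
    for r in range(0, h - 8 + 1, 4):
        for c in range(0, w - 8 + 1, 4):
            m = cooccurrence(quantize(img[r:r + 8, c:c + 8], 16), p)
            feats.append(texture_features(m))
    assert np.allclose(image_texture(img, p).to_numpy(),
                       np.mean(feats, axis=0), atol=1e-12)


def test_window_count_formula():
    """(floor((H-w)/s)+1)*(floor((W-w)/s)+1) windows tile the image."""
    img = np.arange(40 * 28).reshape(40, 28) % 256
    p = GLCMParams()
    count = 0
    for _r in range(0, 40 - 8 + 1, 4):
        for _c in range(0, 28 - 8 + 1, 4):
            count += 1
    assert count == ((40 - 8) // 4 + 1) * ((28 - 8) // 4 + 1)
    # the vectorized path must be consistent with this tiling
    assert image_texture(img, p).notna().all()


def test_constant_image_propagates_degeneracy():
    with pytest.warns(RuntimeWarning):
        f = image_texture(np.full((16, 16), 77))
    assert f["CON"] == 0.0 and f["ASM"] == 1.0


def test_shift_invariance_within_bins():
    """A gray offset that crosses no bin boundary changes nothing."""
    rng = np.random.default_rng(7)
    img = (rng.integers(0, 16, size=(16, 16)) * 16 + 3).astype(int)  # mid-bin
    shifted = img + 5                                 # still inside each bin
    a = image_texture(img).to_numpy()
    b = image_texture(shifted).to_numpy()
    assert np.allclose(a, b)


def test_image_smaller_than_window_rejected():
    with pytest.raises(ValueError):
        image_texture(np.zeros((4, 4)))


def test_extract_features_table_shape():
    rng = np.random.default_rng(2)
    imgs = {f"im{i}": rng.integers(0, 256, size=(12, 12)) for i in range(3)}
    table = extract_features(imgs)
    assert table.shape == (3, 9) and list(table.columns) == list(FEATURE_NAMES)
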