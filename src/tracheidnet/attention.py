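"""Factorized sparse self-attention over 1-D token sequences.

Standard self-attention lets every output position attend to every input
position.  Factorized variants restrict position ``i`` to an index set
``S_i``:

* ``dense``  : S_i = {1..n} (full attention),
* ``local``  : S_i = {j : |i-j| <= k}, a window of 2k+1 positions,
* ``atrous`` : S_i = {j : |i-j| mod k == 0}, strided "hopping" links
  (self included, distance 0); requires k > 1,
* ``sparse`` : the local window plus long-range links at relative
  distances 2k, 3k, ... — tight local correlation with sparse remote
  correlation.

Attention itself is the scaled dot product: for each position
``a(x_i, S_i) = softmax(q_i K_{S_i}^T / sqrt(d)) V_{S_i}`` with
``q_i = Wq x_i``, keys/values ``Wk x_j`` / ``Wv x_j`` for j in S_i.
Index sets are 1-based at the interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

FAMILIES = ("dense", "local", "atrous", "sparse")


@dataclass(frozen=True)
class AttentionPattern:
    """Connection mode S = {S_1..S_n} for one mask family.

    ``S`` holds 1-based, sorted index tuples; ``S[i-1]`` is the index set
    of output position ``i``.
    """

    n: int
    family: str
    k: int | None
    S: tuple[tuple[int, ...], ...] = field(repr=False)

    def mask(self) -> np.ndarray:
        """Boolean (n, n) connectivity matrix, mask[i-1, j-1] = j in S_i."""
        m = np.zeros((self.n, self.n), dtype=bool)
        for i, s in enumerate(self.S):
            m[i, np.asarray(s) - 1] = True
        return m

    def to_json(self) -> str:
        return json.dumps(
            {"n": self.n, "family": self.family, "k": self.k,
             "S": [list(s) for s in self.S]}
        )


@dataclass(frozen=True)
class AttentionWeights:
    """Projection matrices of one attention module.

    ``wq``, ``wk``, ``wv`` are (d, input_dim); ``wp`` is the post-attention
    matrix (output_dim, d_attend) applied after attending.
    """

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wp: np.ndarray

    def __post_init__(self) -> None:
        d, c = self.wq.shape
        if self.wk.shape != (d, c) or self.wv.shape[1] != c:
            raise ValueError("inconsistent projection shapes")
        if d <= 0:
            raise ValueError("inner dimension must be positive")

    @property
    def d(self) -> int:
        """Inner (query/key) dimension used in the sqrt(d) scaling."""
        return self.wq.shape[0]


def build_pattern(family: str, n: int, k: int | None = None) -> AttentionPattern:
    """Construct the index sets of a mask family on ``n`` positions.

    ``k`` is the window half-width (local), stride (atrous) or both
    (sparse); dense ignores it.  Atrous requires k > 1, others k >= 1.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown attention family {family!r}; choose from {FAMILIES}")
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    if family != "dense":
        if k is None or k < 1:
            raise ValueError(f"{family} attention requires k >= 1")
        if family == "atrous" and k < 2:
            raise ValueError("atrous attention requires k > 1")
    j = np.arange(1, n + 1)
    sets = []
    for i in range(1, n + 1):
        dist = np.abs(i - j)
        if family == "dense":
            keep = np.ones(n, dtype=bool)
        elif family == "local":
            keep = dist <= k
        elif family == "atrous":
            keep = dist % k == 0
        else:  # sparse: local window plus strides at 2k, 3k, ...
            keep = (dist <= k) | ((dist % k == 0) & (dist >= 2 * k))
        sets.append(tuple(int(x) for x in j[keep]))
    return AttentionPattern(n=n, family=family, k=None if family == "dense" else k, S=tuple(sets))


def top_k_truncate(scores: np.ndarray, kattn: int) -> np.ndarray:
    """Boolean keep-mask retaining the ``kattn`` largest scores.

    Ties are broken toward the smaller index.  With ``kattn >= len(scores)``
    everything is kept.
    """
    if kattn < 1:
        raise ValueError("kattn must be >= 1")
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[-1]
    keep = np.zeros(n, dtype=bool)
    if kattn >= n:
        keep[:] = True
        return keep
    # stable sort on (-score, index): equal scores keep the earlier index
    order = np.lexsort((np.arange(n), -scores))
    keep[order[:kattn]] = True
    return keep


def attend(
    X: np.ndarray,
    pattern: AttentionPattern,
    weights: AttentionWeights,
    kattn: int | None = None,
) -> np.ndarray:
    """Masked scaled-dot-product attention; returns the (n, d_v) outputs.

    ``kattn`` optionally truncates each position's scores to the top-k
    before the softmax (off by default; the mask family is the primary
    sparsification).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != pattern.n:
        raise ValueError(f"expected {pattern.n} input vectors, got {X.shape[0]}")
    q = X @ weights.wq.T                       # (n, d)
    k = X @ weights.wk.T
    v = X @ weights.wv.T
    scores = q @ k.T / np.sqrt(weights.d)      # (n, n)
    mask = pattern.mask()
    if kattn is not None:
        for i in range(pattern.n):
            idx = np.flatnonzero(mask[i])
            keep = top_k_truncate(scores[i, idx], kattn)
            drop = idx[~keep]
            mask = mask.copy()
            mask[i, drop] = False
    neg = np.where(mask, scores, -np.inf)
    neg = neg - neg.max(axis=1, keepdims=True)
    e = np.exp(neg) * mask
    w = e / e.sum(axis=1, keepdims=True)
    return w @ v


def combine_interleaved(
    X: np.ndarray,
    patterns: list[AttentionPattern],
    r: int,
    weights: AttentionWeights,
    kattn: int | None = None,
) -> np.ndarray:
    """Interleaved combination: residual block ``r`` uses pattern ``r mod p``.

    Returns ``attend(X, A(r mod p)) @ Wp^T``.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    out = attend(X, patterns[r % len(patterns)], weights, kattn=kattn)
    return out @ weights.wp.T


def combine_multihead(
    X: np.ndarray,
    patterns: list[AttentionPattern],
    head_weights: list[AttentionWeights],
    wp: np.ndarray,
    kattn: int | None = None,
) -> np.ndarray:
    """Multi-head combination: one attention product per pattern, computed
    in parallel, concatenated along the feature axis, then Wp."""
    if len(patterns) != len(head_weights):
        raise ValueError("one weight set per pattern/head is required")
    outs = [attend(X, p, w, kattn=kattn) for p, w in zip(patterns, head_weights)]
    widths = {o.shape[0] for o in outs}
    if len(widths) != 1:
        raise ValueError("head outputs disagree in length")
    cat = np.concatenate(outs, axis=1)
    if wp.shape[1] != cat.shape[1]:
        raise ValueError(
            f"post-attention matrix expects width {wp.shape[1]}, got {cat.shape[1]}"
        )
    return cat @ wp.T
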