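"""Agent-attention mathematics: stacked softmax attention and rollout.

Full softmax attention over n tiles costs O(n^2 d).  Agent attention routes
information through k << n agent tokens in two stacked softmax stages:

    V_agent = SAttn(A, K, V)            (first-aggregation,  k x d)
    out     = SAttn(Q, A, V_agent)      (second-broadcast,   n x d)

so the cost drops to O(n k d).  The effective tile-to-tile attention matrix
(used for interpretability) is the rollout product of the two stage
matrices,

    M = softmax(Q A^T / sqrt(d)) @ softmax(A K^T / sqrt(d))

which is row-stochastic as a product of row-stochastic factors.  Both
stages use the 1/sqrt(d) temperature of scaled dot-product attention; the
rollout applies the same scale for consistency with the forward pass.

These are stateless NumPy reference functions; the trainable model in
:mod:`cpmp.model` re-expresses the same math on autodiff tensors and is
tested against these (and against scalar double-loop oracles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "softmax",
    "softmax_attention",
    "make_agent_tokens",
    "agent_pooling_matrix",
    "agent_attention",
    "rollout_matrix",
    "AttentionMaps",
    "attention_maps",
    "count_macs_full_attention",
    "count_macs_agent_attention",
    "macs_full_attention_closed_form",
    "macs_agent_attention_closed_form",
]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction per row)."""
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_2d(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {x.shape}")
    return x


def softmax_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d)) V."""
    Q, K, V = _check_2d("Q", Q), _check_2d("K", K), _check_2d("V", V)
    if K.shape[0] != V.shape[0]:
        raise ValueError(
            f"K and V must have equal row counts: {K.shape[0]} vs {V.shape[0]}"
        )
    if Q.shape[1] != K.shape[1]:
        raise ValueError(
            f"Q and K must share column count: {Q.shape[1]} vs {K.shape[1]}"
        )
    d = Q.shape[1]
    return softmax(Q @ K.T / np.sqrt(d)) @ V


def agent_pooling_matrix(n: int, k: int) -> np.ndarray:
    """k x n matrix averaging k contiguous near-equal segments of n rows.

    Segment sizes differ by at most one (the first ``n % k`` segments get the
    extra row); ``k == n`` yields the identity.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    P = np.zeros((k, n))
    start = 0
    for j, size in enumerate(sizes):
        P[j, start : start + size] = 1.0 / size
        start += size
    return P


def make_agent_tokens(Q: np.ndarray, k: int) -> np.ndarray:
    """Pool k agent tokens as segment means of the query rows."""
    Q = _check_2d("Q", Q)
    return agent_pooling_matrix(Q.shape[0], k) @ Q


def agent_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, A: np.ndarray
) -> np.ndarray:
    """Two-stage agent attention: SAttn(Q, A, SAttn(A, K, V))."""
    A = _check_2d("A", A)
    if A.shape[1] != np.asarray(Q).shape[1]:
        raise ValueError(
            f"A and Q must share column count: {A.shape[1]} vs {np.asarray(Q).shape[1]}"
        )
    v_agent = softmax_attention(A, K, V)
    return softmax_attention(Q, A, v_agent)


def rollout_matrix(Q: np.ndarray, K: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Effective n x n attention: softmax(QA^T/sqrt(d)) @ softmax(AK^T/sqrt(d))."""
    Q, K, A = _check_2d("Q", Q), _check_2d("K", K), _check_2d("A", A)
    if not (Q.shape[1] == K.shape[1] == A.shape[1]):
        raise ValueError("Q, K, A must share column count")
    d = Q.shape[1]
    query_agent = softmax(Q @ A.T / np.sqrt(d))
    agent_key = softmax(A @ K.T / np.sqrt(d))
    return query_agent @ agent_key


@dataclass
class AttentionMaps:
    """The two stage matrices, the agent values, and their rollout product."""

    agent_key: np.ndarray  # k x n_k, row-stochastic
    query_agent: np.ndarray  # n_q x k, row-stochastic
    v_agent: np.ndarray  # k x d
    rollout: np.ndarray  # n_q x n_k, row-stochastic


def attention_maps(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, A: np.ndarray
) -> AttentionMaps:
    """Compute all intermediate agent-attention matrices in one pass."""
    Q, K, V, A = (_check_2d(n, x) for n, x in zip("QKVA", (Q, K, V, A)))
    d = Q.shape[1]
    agent_key = softmax(A @ K.T / np.sqrt(d))
    query_agent = softmax(Q @ A.T / np.sqrt(d))
    return AttentionMaps(
        agent_key=agent_key,
        query_agent=query_agent,
        v_agent=agent_key @ V,
        rollout=query_agent @ agent_key,
    )


# ---------------------------------------------------------------------------
# Analytic cost accounting
# ---------------------------------------------------------------------------
# A matmul of (p x q) @ (q x r) performs p*q*r multiply-accumulates.  The
# counters walk the exact sequence of matmuls each mechanism performs
# (similarity products plus weighted value sums; projections excluded, since
# both mechanisms share them).


def _matmul_macs(shapes: list[tuple[int, int, int]]) -> int:
    return sum(p * q * r for p, q, r in shapes)


def count_macs_full_attention(n: int, d: int) -> int:
    """MACs for softmax(Q K^T) V with n tokens, width d."""
    return _matmul_macs(
        [
            (n, d, n),  # Q @ K^T
            (n, n, d),  # weights @ V
        ]
    )


def count_macs_agent_attention(n: int, k: int, d: int) -> int:
    """MACs for the two agent-attention stages with n tokens, k agents."""
    return _matmul_macs(
        [
            (k, d, n),  # A @ K^T
            (k, n, d),  # stage-1 weights @ V
            (n, d, k),  # Q @ A^T
            (n, k, d),  # stage-2 weights @ V_agent
        ]
    )


def macs_full_attention_closed_form(n: int, d: int) -> int:
    return 2 * n * n * d


def macs_agent_attention_closed_form(n: int, k: int, d: int) -> int:
    return 4 * n * k * d
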