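"""Mailman multiplication for {0,1,2}-valued matrix blocks.

A block A (m x n over the base-3 alphabet) is factored as A = U P where U is
the (implicit) matrix whose columns enumerate all base-3 vectors of a segment
height h, and P is a 0/1 column-selection encoded as one integer code per
column. With h = ceil(log3 n) a segment's product with a vector costs
O(n + 3^h) = O(n) instead of O(h n), so a full m x n product costs
O(mn / log3 n). Blocks taller than h rows are cut into contiguous segments
that share one decomposition.

Both multiplication directions reuse the *same* decomposition:

- right (A b): scatter b into d[code] += b_j, then collapse d over digits,
  least-significant first, harvesting each row's contribution;
- left (f^T A): expand u[code] = sum_i digit_i(code) f_i over the code tree,
  most-significant digit first, then gather u[code_j] per column.

U is never materialized; the per-segment work buffer is at most 3^h <= 3n
entries. Accumulation is always in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .exceptions import AlphabetError, DimensionError

__all__ = [
    "MailmanSegment",
    "MailmanPlan",
    "decompose",
    "decode",
    "multiply_right",
    "multiply_left",
    "multiply_right_multi",
    "multiply_left_multi",
    "operation_counts",
]


@dataclass(frozen=True)
class MailmanSegment:
    """One contiguous row chunk of a plan: its height and per-column codes."""

    start_row: int
    seg_rows: int
    n: int
    p_index: np.ndarray  # length-n ints in [0, 3^seg_rows)


@dataclass(frozen=True)
class MailmanPlan:
    """Segmented base-3 decomposition of an m x n block.

    ``p_index[s, j]`` is the base-3 integer encoded by column j of segment s,
    first row of the segment being the most significant digit. All segments
    have height ``seg_height`` except possibly the last.
    """

    p_index: np.ndarray  # (n_segments, n) int32 codes
    seg_heights: np.ndarray  # (n_segments,) int64
    m: int
    n: int

    @property
    def n_segments(self) -> int:
        return self.p_index.shape[0]

    @property
    def segments(self) -> list[MailmanSegment]:
        out, row = [], 0
        for s in range(self.n_segments):
            h = int(self.seg_heights[s])
            out.append(MailmanSegment(row, h, self.n, self.p_index[s]))
            row += h
        return out


def segment_height(n: int) -> int:
    """Tallest segment height whose code table stays O(n).

    The smallest h with 3^h > n; this is ceil(log3 n) except when n is an
    exact power of 3, where one extra row still keeps the table below 3n.
    """
    h = 1
    while 3**h <= n:
        h += 1
    return h


def decompose(block: np.ndarray) -> MailmanPlan:
    """Build the segmented decomposition of a {0,1,2} block in one pass."""
    block = np.asarray(block)
    if block.ndim != 2:
        raise DimensionError("block must be 2-D")
    m, n = block.shape
    bad = (block < 0) | (block > 2)
    if bad.any():
        j, i = np.argwhere(bad)[0]
        raise AlphabetError(
            f"entry outside {{0,1,2}} at row {j}, column {i}: {block[j, i]}"
        )
    h = min(segment_height(n), m)
    n_segments = -(-m // h)
    p_index = np.zeros((n_segments, n), dtype=np.int32)
    heights = np.empty(n_segments, dtype=np.int64)
    for s in range(n_segments):
        heights[s] = min((s + 1) * h, m) - s * h
    _decompose_kernel(np.ascontiguousarray(block, dtype=np.int8), heights, p_index)
    return MailmanPlan(p_index=p_index, seg_heights=heights, m=m, n=n)


@njit(cache=True)
def _decompose_kernel(block, seg_heights, p_index):  # pragma: no cover - numba
    n = block.shape[1]
    row0 = 0
    for s in range(seg_heights.shape[0]):
        h = seg_heights[s]
        for r in range(h):  # first row = most significant digit
            for j in range(n):
                p_index[s, j] = p_index[s, j] * 3 + block[row0 + r, j]
        row0 += h


def decode(plan: MailmanPlan) -> np.ndarray:
    """Reconstruct the original block from the plan (test oracle)."""
    out = np.empty((plan.m, plan.n), dtype=np.int8)
    row = 0
    for s in range(plan.n_segments):
        h = int(plan.seg_heights[s])
        code = plan.p_index[s].astype(np.int64).copy()
        for r in range(h - 1, -1, -1):
            out[row + r] = code % 3
            code //= 3
        row += h
    return out


@njit(cache=True)
def _right_kernel(p_index, seg_heights, B, out):  # pragma: no cover - numba
    n_segments, n = p_index.shape
    k = B.shape[1]
    max_r = 3 ** np.max(seg_heights)
    d = np.zeros((max_r, k), dtype=np.float64)
    row0 = 0
    for s in range(n_segments):
        h = seg_heights[s]
        r = 3**h
        for q in range(r):
            for t in range(k):
                d[q, t] = 0.0
        for j in range(n):
            c = p_index[s, j]
            for t in range(k):
                d[c, t] += B[j, t]
        size = r
        for i in range(h - 1, -1, -1):
            size //= 3
            for q in range(size):
                for t in range(k):
                    a0 = d[3 * q, t]
                    a1 = d[3 * q + 1, t]
                    a2 = d[3 * q + 2, t]
                    out[row0 + i, t] += a1 + 2.0 * a2
                    d[q, t] = a0 + a1 + a2
        row0 += h


@njit(cache=True)
def _left_kernel(p_index, seg_heights, F, out):  # pragma: no cover - numba
    n_segments, n = p_index.shape
    k = F.shape[1]
    max_r = 3 ** np.max(seg_heights)
    u = np.empty((max_r, k), dtype=np.float64)
    row0 = 0
    for s in range(n_segments):
        h = seg_heights[s]
        for t in range(k):
            u[0, t] = 0.0
        size = 1
        for i in range(h):  # most significant digit first
            for q in range(size - 1, -1, -1):
                for t in range(k):
                    base = u[q, t]
                    f = F[row0 + i, t]
                    u[3 * q, t] = base
                    u[3 * q + 1, t] = base + f
                    u[3 * q + 2, t] = base + 2.0 * f
            size *= 3
        for j in range(n):
            c = p_index[s, j]
            for t in range(k):
                out[j, t] += u[c, t]
        row0 += h


def multiply_right_multi(plan: MailmanPlan, B: np.ndarray) -> np.ndarray:
    """Compute block @ B for an n x k matrix B, reusing the plan."""
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if B.shape[0] != plan.n:
        raise DimensionError(f"B has {B.shape[0]} rows, plan expects {plan.n}")
    out = np.zeros((plan.m, B.shape[1]), dtype=np.float64)
    _right_kernel(plan.p_index, plan.seg_heights, np.ascontiguousarray(B), out)
    return out


def multiply_left_multi(plan: MailmanPlan, F: np.ndarray) -> np.ndarray:
    """Compute block^T @ F for an m x k matrix F, reusing the same plan."""
    F = np.atleast_2d(np.asarray(F, dtype=np.float64))
    if F.shape[0] != plan.m:
        raise DimensionError(f"F has {F.shape[0]} rows, plan expects {plan.m}")
    out = np.zeros((plan.n, F.shape[1]), dtype=np.float64)
    _left_kernel(plan.p_index, plan.seg_heights, np.ascontiguousarray(F), out)
    return out


def multiply_right(plan: MailmanPlan, b: np.ndarray) -> np.ndarray:
    """block @ b for a length-n vector b."""
    b = np.asarray(b, dtype=np.float64)
    if b.ndim != 1:
        raise DimensionError("b must be a vector")
    return multiply_right_multi(plan, b[:, None])[:, 0]


def multiply_left(plan: MailmanPlan, f: np.ndarray) -> np.ndarray:
    """f^T @ block for a length-m vector f."""
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 1:
        raise DimensionError("f must be a vector")
    return multiply_left_multi(plan, f[:, None])[:, 0]


def operation_counts(plan: MailmanPlan) -> list[dict]:
    """Per-segment add/multiply counts of one vector product.

    Mirrors the kernels exactly: the scatter/gather touches n entries and the
    code-tree pass touches sum_{l<=h} 3^l < 1.5 * 3^h entries, so each
    segment costs O(n + 3^seg_rows).
    """
    out = []
    for s in range(plan.n_segments):
        h = int(plan.seg_heights[s])
        tree = sum(3**level for level in range(1, h + 1))
        out.append(
            {
                "seg_rows": h,
                "scatter_ops": plan.n,
                "tree_ops": tree,
                "total_ops": plan.n + tree,
                "bound": plan.n + 3**h + 3**h // 2,
            }
        )
    return out
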