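"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (literal double sums, exhaustive
subset enumeration) kept separate from the library code paths they
check.
"""

from __future__ import annotations

import numpy as np


def gyration_tensor_double_sum(coords: np.ndarray) -> np.ndarray:
    """Literal pairwise form T_ab = 1/(2N²) Σ_i Σ_j (r_ia−r_ja)(r_ib−r_jb)."""
    x = np.asarray(coords, dtype=float)
    n = x.shape[0]
    t = np.zeros((3, 3))
    for i in range(n):
        d = x[i] - x          # (N, 3) differences against every j
        t += d.T @ d
    return t / (2.0 * n * n)


def radius_of_gyration_direct(coords: np.ndarray) -> float:
    """Term-by-term evaluation of Rg² = (1/N) Σ (r_i − r₀)²."""
    x = np.asarray(coords, dtype=float)
    r0 = x.sum(axis=0) / len(x)
    total = 0.0
    for r in x:
        total += float((r - r0) @ (r - r0))
    return float(np.sqrt(total / len(x)))


def max_noncrossing_bruteforce(pairs: list[tuple[int, int]]) -> int:
    """Size of the largest crossing-free subset, by exhaustive enumeration.

    Vectorised over all 2^m subsets; intended for m ≤ ~14.
    """
    m = len(pairs)
    if m == 0:
        return 0
    conflict = np.zeros((m, m), dtype=np.int64)
    for a in range(m):
        i, j = pairs[a]
        for b in range(m):
            k, l = pairs[b]
            if a != b and (i < k < j < l or k < i < l < j):
                conflict[a, b] = 1
    masks = np.arange(1 << m, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(m)) & 1).astype(np.int64)
    violations = np.einsum("ka,ab,kb->k", bits, conflict, bits)
    sizes = bits.sum(axis=1)
    return int(sizes[violations == 0].max())
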