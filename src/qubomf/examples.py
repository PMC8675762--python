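"""A tiny worked example with a known exact factorization."""

from __future__ import annotations

import numpy as np

__all__ = ["toy_exact_bmf"]


def toy_exact_bmf():
    """A 3x3 binary matrix with an exact rank-2 factorization.

    Returns ``(A, U, V)`` with ``A == U @ V.T`` exactly, so the BMF
    objective at (U, V) is 0.  Handy for walkthroughs and smoke tests.
    """
    A = np.array([[1, 1, 0], [1, 1, 1], [0, 0, 1]], dtype=np.int64)
    U = np.array([[0, 1], [1, 1], [1, 0]], dtype=np.int64)
    V = np.array([[0, 1], [0, 1], [1, 0]], dtype=np.int64)
    return A, U, V
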