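"""Finite-difference helpers: Richardson-extrapolated central differences.

Terse by design; constraints are noted inline.
"""

from __future__ import annotations

from typing import Callable

__all__ = ["richardson_d1", "d1_5pt", "d2_5pt"]


def richardson_d1(
    f: Callable[[float], float],
    x: float = 0.0,
    h0: float = 1e-4,
    levels: int = 4,
) -> float:
    """First derivative of ``f`` at ``x`` by central differences with a
    Richardson table (step halving; effective order 2*levels)."""
    # rows: step h0/2^i; columns: extrapolation order
    row_prev: list[float] = []
    h = h0
    for i in range(levels):
        d = (f(x + h) - f(x - h)) / (2.0 * h)
        row = [d]
        p4 = 1.0
        for j in range(i):
            p4 *= 4.0
            row.append((p4 * row[j] - row_prev[j]) / (p4 - 1.0))
        row_prev = row
        h *= 0.5
    return row_prev[-1]


def d1_5pt(f: Callable[[float], float], x: float, h: float) -> float:
    """Five-point (4th-order) central first derivative."""
    return (
        -f(x + 2 * h) + 8 * f(x + h) - 8 * f(x - h) + f(x - 2 * h)
    ) / (12.0 * h)


def d2_5pt(f: Callable[[float], float], x: float, h: float) -> float:
    """Five-point (4th-order) central second derivative."""
    return (
        -f(x + 2 * h)
        + 16 * f(x + h)
        - 30 * f(x)
        + 16 * f(x - h)
        - f(x - 2 * h)
    ) / (12.0 * h * h)
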