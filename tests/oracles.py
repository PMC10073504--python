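"""Independent brute-force oracles used only by the test suite.

These deliberately use plain loops and naive counting so they share no code
path with the package implementation.
"""

from __future__ import annotations

import math


def sample_entropy_bruteforce(x, m: int = 2, r: float | None = None,
                              r_factor: float = 0.2) -> float:
    """O(n^2) literal template counting (Chebyshev, self-matches excluded).

    Both the m and m+1 counts use the same n-m template starts.
    """
    x = list(map(float, x))
    n = len(x)
    if n < m + 2:
        return math.nan
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    if sd == 0:
        return 0.0
    if r is None:
        r = r_factor * sd

    def count(length: int) -> int:
        total = 0
        n_templates = n - m  # same template count for both lengths
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if i + length > n or j + length > n:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if d <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def coarse_grain_bruteforce(x, tau: int) -> list[float]:
    """Non-overlapping block means, literal loop."""
    x = list(map(float, x))
    out = []
    i = 0
    while i + tau <= len(x):
        out.append(sum(x[i:i + tau]) / tau)
        i += tau
    return out


def window_count_bruteforce(length: float, window: float, step: float) -> int:
    """Enumerate window start offsets until one no longer fits."""
    count = 0
    start = 0.0
    while start + window <= length + 1e-9:
        count += 1
        start += step
    return count
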