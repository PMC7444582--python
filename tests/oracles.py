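"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the peak oracle scans
every candidate's prominence exhaustively in O(n^2), and the Fisher oracle
is scipy's exact test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def brute_force_peaks(x, min_prominence, min_width):
    """Exhaustive prominence/width peak detection.

    Returns a list of (index, value, prominence, width) tuples, sorted by
    index.  Candidate maxima are equal-value runs strictly above both
    neighbouring runs (reported at the left-middle sample); prominence and
    width bounds are located by whole-array scans rather than walking.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    # group the trace into runs of equal values
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        runs.append((i, j, x[i]))
        i = j + 1
    out = []
    for k in range(1, len(runs) - 1):
        s, e, v = runs[k]
        if runs[k - 1][2] >= v or runs[k + 1][2] >= v:
            continue
        p = (s + e) // 2
        # left boundary: the sample after the last strictly-higher sample
        higher_left = [l for l in range(0, s) if x[l] > v]
        lstart = (max(higher_left) + 1) if higher_left else 0
        left_base_val = x[lstart:p + 1].min()
        higher_right = [r for r in range(e + 1, n) if x[r] > v]
        rend = min(higher_right) if higher_right else n
        right_base_val = x[p:rend].min()
        prom = v - max(left_base_val, right_base_val)
        if prom < min_prominence:
            continue
        # width at half prominence, crossings by exhaustive scan from the peak
        h = v - prom / 2.0
        li = p
        while x[li] > h:
            li -= 1  # guaranteed to terminate: base value < h
        left = li + (h - x[li]) / (x[li + 1] - x[li])
        ri = p
        while x[ri] > h:
            ri += 1
        right = ri - (h - x[ri]) / (x[ri - 1] - x[ri])
        width = right - left
        if width < min_width:
            continue
        out.append((p, float(v), float(prom), float(width)))
    return out


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p via scipy's independent implementation."""
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
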