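"""Independent reference implementations used only to check the package.

Each oracle takes the most literal route available — exact integer
arithmetic, all-pairs scans, textbook step-up — and shares no code with the
implementation it verifies.
"""

from fractions import Fraction
from math import comb

import numpy as np


def exact_hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """Term-by-term exact-rational summation of the upper-tail probability."""
    num = sum(comb(M, i) * comb(N - M, n - i) for i in range(m, min(n, M) + 1))
    return float(Fraction(num, comb(N, n)))


def stepup_bh(p_values):
    """Textbook Benjamini-Hochberg step-up, returned in the input order."""
    p = list(p_values)
    k = len(p)
    order = sorted(range(k), key=lambda i: p[i])
    adjusted = [0.0] * k
    running_min = 1.0
    for rank in range(k, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * k / rank)
        adjusted[i] = running_min
    return adjusted


def naive_targets(peaks, regions):
    """All-pairs >=1 bp half-open overlap scan; returns targeted feature IDs."""
    hit = set()
    for r in regions:
        for p in peaks:
            if p.chrom == r.chrom and max(p.start, r.start) < min(p.end, r.end):
                hit.add(r.feature_id)
                break
    return hit


def naive_targets_broadcast(peaks, regions):
    """Same all-pairs scan as a numpy broadcast, for larger random inputs."""
    hit = set()
    chroms = {r.chrom for r in regions}
    for chrom in chroms:
        rs = [r for r in regions if r.chrom == chrom]
        ps = [p for p in peaks if p.chrom == chrom]
        if not ps:
            continue
        r_start = np.array([r.start for r in rs])
        r_end = np.array([r.end for r in rs])
        p_start = np.array([p.start for p in ps])
        p_end = np.array([p.end for p in ps])
        overlap = (p_start[:, None] < r_end[None, :]) & (p_end[:, None] > r_start[None, :])
        for j in np.nonzero(overlap.any(axis=0))[0]:
            hit.add(rs[j].feature_id)
    return hit
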