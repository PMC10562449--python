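"""Brute-force trade allocator used as an independent oracle.

Implements the surplus-deficit trade semantics directly from their
definition — per-pair Chebyshev distances, exhaustive ring enumeration,
proportional within-ring draws — with no shared code or vectorisation, so
it can cross-check the production implementation on small grids.
"""

import numpy as np


def chebyshev(i1, j1, i2, j2, nlon=None, wrap=False):
    di = abs(i1 - i2)
    dj = abs(j1 - j2)
    if wrap:
        dj = min(dj, nlon - dj)
    return max(di, dj)


def brute_force_trade(production, burnt, demand, removal_cap=0.90,
                      max_radius=20, wrap=False):
    """Return (animal_usage, unmet) after exhaustive ring-by-ring trade."""
    p = np.asarray(production, dtype=float)
    b = np.asarray(burnt, dtype=float)
    d = np.asarray(demand, dtype=float)
    nlat, nlon = p.shape

    avail = np.maximum(0.0, removal_cap * p - b)
    usage = np.minimum(d, avail)
    deficit = d - usage
    capacity = avail - usage

    for r in range(1, max_radius + 1):
        for i in range(nlat):
            for j in range(nlon):
                need = deficit[i, j]
                if need <= 1e-9:
                    continue
                ring = [
                    (ii, jj)
                    for ii in range(nlat)
                    for jj in range(nlon)
                    if chebyshev(i, j, ii, jj, nlon, wrap) == r
                    and capacity[ii, jj] > 1e-9
                ]
                total = sum(capacity[ii, jj] for ii, jj in ring)
                if total <= 0:
                    continue
                take = min(need, total)
                for ii, jj in ring:
                    amount = take * capacity[ii, jj] / total
                    capacity[ii, jj] -= amount
                    usage[ii, jj] += amount
                deficit[i, j] -= take
    unmet = np.where(deficit > 1e-9, deficit, 0.0)
    return usage, unmet
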