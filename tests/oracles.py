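"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately use naive enumeration (python loops, flood fill, direct
ANOVA sums) and never call the package's own vectorized implementations.
"""

from itertools import product

import numpy as np

from radrep.features._base import bin_minmax


def brute_glcm(volume, mask, n_bins):
    """O(n * 26) double-loop co-occurrence enumeration."""
    levels = np.full(mask.shape, -1, dtype=int)
    levels[mask] = bin_minmax(volume[mask], n_bins)
    mat = np.zeros((n_bins, n_bins))
    offsets = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for v in np.argwhere(mask):
        for off in offsets:
            w = v + off
            if (w >= 0).all() and (w < mask.shape).all() and mask[tuple(w)]:
                mat[levels[tuple(v)], levels[tuple(w)]] += 1
    return mat / mat.sum() if mat.sum() else None


def brute_ngtdm(volume, mask, n_bins):
    """Per-voxel 26-neighbourhood enumeration of Amadasun-King n_i, s_i."""
    levels = np.zeros(mask.shape)
    levels[mask] = bin_minmax(volume[mask], n_bins) + 1
    n_i, s_i = np.zeros(n_bins), np.zeros(n_bins)
    for v in np.argwhere(mask):
        nbrs = []
        complete = True
        for off in product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            w = v + off
            if not ((w >= 0).all() and (w < mask.shape).all() and mask[tuple(w)]):
                complete = False
                break
            nbrs.append(levels[tuple(w)])
        if complete:
            lev = int(levels[tuple(v)]) - 1
            n_i[lev] += 1
            s_i[lev] += abs(levels[tuple(v)] - np.mean(nbrs))
    if n_i.sum() == 0:
        return None
    return n_i, s_i


def brute_zones(volume, mask, n_bins):
    """Flood-fill enumeration of 26-connected equal-bin zones."""
    levels = np.full(mask.shape, -1, dtype=int)
    levels[mask] = bin_minmax(volume[mask], n_bins)
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, size, lev = [start], 0, levels[start]
        seen[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for off in product((-1, 0, 1), repeat=3):
                w = tuple(np.array(v) + off)
                if (all(0 <= w[d] < mask.shape[d] for d in range(3))
                        and not seen[w] and levels[w] == lev):
                    seen[w] = True
                    stack.append(w)
        zones.append((lev, size))
    return zones


def anova_icc_oracle(x, y):
    """Direct two-way ANOVA mean-squares ICC(A,1), written independently."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = ((data - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
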