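"""Independent brute-force oracles used only by the tests.

These transliterate the defining formulas over explicit voxel index sets
and per-voxel loops, deliberately sharing no code with the library paths
they check.
"""

import math

import numpy as np


def preprocess_oracle(volume, lower, upper):
    """Literal clip-and-subtract rule, voxel by voxel."""
    out = np.zeros(volume.shape, dtype=np.float64)
    flat_in = volume.ravel()
    flat_out = out.ravel()
    for i in range(flat_in.size):
        v = float(flat_in[i])
        if v > upper:
            flat_out[i] = 0.0
        else:
            d = v - lower
            flat_out[i] = d if d > 0 else 0.0
    return out


def pcc_oracle(vol_a, vol_b, t_a, t_b):
    """Normalized-covariance quotient over all voxels of the grid."""
    a = preprocess_oracle(vol_a, t_a[0], t_a[1]).ravel()
    b = preprocess_oracle(vol_b, t_b[0], t_b[1]).ravel()
    ma, mb = a.mean(), b.mean()
    num = float(((a - ma) * (b - mb)).sum())
    den = math.sqrt(float(((a - ma) ** 2).sum())) * \
        math.sqrt(float(((b - mb) ** 2).sum()))
    if den == 0:
        return None
    return num / den


def mask_set(volume, lower, upper):
    """Explicit index set of voxels with lower < v <= upper."""
    s = set()
    flat = volume.ravel()
    for i in range(flat.size):
        if lower < flat[i] <= upper:
            s.add(i)
    return s


def intersection_oracle(sets):
    """(I, [i_k]) by literal set arithmetic; None marks undefined."""
    inter = set.intersection(*sets) if sets else set()
    union = set.union(*sets) if sets else set()
    I = len(inter) / len(union) if union else None
    per = [len(inter) / len(s) if s else None for s in sets]
    return I, per


def venn_counts_oracle(sets):
    """Exact-region voxel counts keyed by frozenset of 1-based indices."""
    out = {}
    n = len(sets)
    for code in range(1, 2 ** n):
        members = [k for k in range(n) if code >> k & 1]
        region = set.intersection(*[sets[k] for k in members])
        for k in range(n):
            if k not in members:
                region = region - sets[k]
        out[frozenset(k + 1 for k in members)] = len(region)
    return out


def nearest_rank(values, q):
    """Sorted-index percentile: value at 1-based rank ceil(q * n)."""
    s = sorted(values)
    n = len(s)
    return s[max(math.ceil(q * n) - 1, 0)]
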