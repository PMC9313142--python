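"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the library paths used by the package
(scipy.ndimage correlation/labeling, sklearn ROC): plain loops, BFS flood
fill and direct likelihood evaluation only.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_force_suv_peak(values, spacing, mask, diameter_mm: float = 12.0) -> float:
    """Exhaustive sphere search: max over centers in mask of the sphere mean.

    Same conventions as the implementation: voxel included in a sphere iff
    its center is within the radius of the candidate center; the sphere must
    lie fully inside the grid; if no masked center allows that, clipped
    spheres are used; ties go to the first center in scan order.
    """
    values = np.asarray(values, dtype=float)
    shape = values.shape
    r = diameter_mm / 2.0
    ext = [int(math.floor(r / s + 1e-9)) for s in spacing]
    offsets = []
    for dz in range(-ext[0], ext[0] + 1):
        for dy in range(-ext[1], ext[1] + 1):
            for dx in range(-ext[2], ext[2] + 1):
                d2 = (dz * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dx * spacing[2]) ** 2
                if d2 <= r * r + 1e-9:
                    offsets.append((dz, dy, dx))

    centers = [tuple(c) for c in np.argwhere(np.asarray(mask, bool))]
    full = [
        c
        for c in centers
        if all(ext[a] <= c[a] < shape[a] - ext[a] for a in range(3))
    ]
    use_clipped = not full
    candidates = centers if use_clipped else full
    best = -math.inf
    for c in candidates:
        total = 0.0
        n = 0
        for o in offsets:
            p = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
            if use_clipped and not all(0 <= p[a] < shape[a] for a in range(3)):
                continue
            total += values[p]
            n += 1
        m = total / n
        if m > best:
            best = m
    return best


def flood_fill_components(above: np.ndarray, connectivity: int = 26) -> list[frozenset]:
    """Connected components of a boolean volume via BFS."""
    above = np.asarray(above, bool)
    shape = above.shape
    if connectivity == 26:
        neigh = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    elif connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        raise ValueError("connectivity must be 6 or 26")
    seen = np.zeros(shape, bool)
    comps = []
    for start in map(tuple, np.argwhere(above)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for o in neigh:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[a] < shape[a] for a in range(3)) and above[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return comps


def brute_force_segment(
    values, spacing, threshold, min_volume_ml=0.3, exclusion=None, connectivity=26,
    diameter_mm=12.0,
) -> list[frozenset]:
    """Flood-fill segmentation with the volume and SUVpeak filters applied."""
    values = np.asarray(values, float)
    above = values > threshold
    if exclusion is not None:
        above &= ~np.asarray(exclusion, bool)
    voxel_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    comps = []
    for comp in flood_fill_components(above, connectivity):
        if len(comp) * voxel_ml < min_volume_ml:
            continue
        mask = np.zeros(values.shape, bool)
        for v in comp:
            mask[v] = True
        if brute_force_suv_peak(values, spacing, mask, diameter_mm) <= threshold:
            continue
        comps.append(comp)
    return comps


def brute_force_roc(scores, labels, min_spec=0.80):
    """All-thresholds ROC scan, O(n^2), plus pair-counting AUC.

    Returns (auc, youden_cutoff, sens_y, spec_y, minspec_cutoff, sens_m).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    # concordance AUC: ties count half
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    auc = wins / (len(pos) * len(neg))

    cutoffs = sorted(set(scores)) + [math.inf]
    best = None
    for c in cutoffs:
        sens = sum(p >= c for p in pos) / len(pos)
        spec = sum(n < c for n in neg) / len(neg)
        key = (sens + spec - 1.0, spec, c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    minspec = None
    for c in cutoffs:
        spec = sum(n < c for n in neg) / len(neg)
        if spec >= min_spec:
            sens = sum(p >= c for p in pos) / len(pos)
            minspec = (c, sens)
            break
    return auc, best[1], best[2], best[3], minspec[0], minspec[1]


def logistic_loglik(beta, X, y):
    """Direct Bernoulli log-likelihood of a logistic model (for the oracle)."""
    eta = X @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def cox_partial_loglik(beta, times, events, x):
    """Breslow/Efron-free partial log-likelihood for untied event times."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = x[times >= times[i]]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * risk)))
    return ll
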