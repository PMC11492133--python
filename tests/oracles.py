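"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's fast paths: densities are evaluated
directly at 1-bp resolution with full (untruncated) kernels, nearest
neighbours by exhaustive O(N*M) scans, and interval intersections on
per-bp boolean masks.
"""

from __future__ import annotations

import numpy as np


def brute_density(midpoints, positions, sigma=300.0):
    """Untruncated Gaussian kernel sum evaluated at arbitrary positions."""
    m = np.asarray(midpoints, dtype=float)[None, :]
    x = np.asarray(positions, dtype=float)[:, None]
    return np.exp(-((x - m) ** 2) / (2.0 * sigma**2)).sum(axis=1)


def brute_peaks_1bp(midpoints, sigma=300.0, pad_sigmas=4.0):
    """Plateau-collapsed local maxima of the density on a 1-bp grid."""
    midpoints = sorted(midpoints)
    pad = int(pad_sigmas * sigma)
    xs = np.arange(midpoints[0] - pad, midpoints[-1] + pad + 1)
    dens = brute_density(midpoints, xs, sigma)
    peaks = []
    n = len(dens)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and dens[j + 1] == dens[i]:
            j += 1
        left_ok = i == 0 or dens[i - 1] < dens[i]
        right_ok = j == n - 1 or dens[j + 1] < dens[j]
        if left_ok and right_ok:
            peaks.append(int(xs[(i + j) // 2]))
        i = j + 1
    return peaks


def brute_contributions(midpoints, peak, sigma=300.0, threshold=0.1):
    """Indices of sites whose kernel weight at the peak >= threshold."""
    out = []
    for k, m in enumerate(midpoints):
        if np.exp(-((peak - m) ** 2) / (2.0 * sigma**2)) >= threshold:
            out.append(k)
    return out


def brute_nearest(query_positions, target_positions):
    """For each query, indices of all exact-minimum-distance targets."""
    out = []
    for q in query_positions:
        d = [abs(q - t) for t in target_positions]
        best = min(d)
        out.append((best, [i for i, x in enumerate(d) if x == best]))
    return out


def brute_interval_intersection(stage_interval_lists, lo, hi):
    """Fragments covered in every stage, via per-bp boolean masks."""
    mask = np.ones(hi - lo, dtype=bool)
    for intervals in stage_interval_lists:
        stage_mask = np.zeros(hi - lo, dtype=bool)
        for s, e in intervals:
            stage_mask[max(0, s - lo) : max(0, e - lo)] = True
        mask &= stage_mask
    frags = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            frags.append((lo + i, lo + j + 1))
            i = j + 1
        else:
            i += 1
    return frags


def brute_overlap_pairs(intervals_a, intervals_b, min_overlap=1):
    """All index pairs with interval overlap >= min_overlap (same chrom)."""
    out = set()
    for i, (sa, ea) in enumerate(intervals_a):
        for j, (sb, eb) in enumerate(intervals_b):
            if min(ea, eb) - max(sa, sb) >= min_overlap:
                out.add((i, j))
    return out


def clustered_tfbs_fixture(rng, n_clusters=5, span=60_000, min_gap=2_500,
                           sites_per_cluster=(3, 8), site_sd=100.0):
    """Cluster-center layout with Gaussian-scattered site midpoints,
    mimicking motif hits piling up in accessible regions."""
    centers = []
    while len(centers) < n_clusters:
        c = int(rng.integers(2_000, span - 2_000))
        if all(abs(c - o) >= min_gap for o in centers):
            centers.append(c)
    midpoints = []
    for c in sorted(centers):
        k = int(rng.integers(sites_per_cluster[0], sites_per_cluster[1] + 1))
        for _ in range(k):
            midpoints.append(int(round(rng.normal(c, site_sd))))
    return sorted(centers), sorted(midpoints)
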