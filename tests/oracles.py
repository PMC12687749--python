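"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's own code paths: plain-Python
loops and definitions, so they can serve as oracles for the vectorized
implementations.
"""

from __future__ import annotations

import math


def brute_force_bins(latencies, bin_size, min_points, anchor=0.0):
    """Max pooling by definition: dict bin_index -> list of point indices,
    plus the set of significant bins."""
    assignments = {}
    for i, lat in enumerate(latencies):
        b = math.floor((lat - anchor) / bin_size)
        assignments.setdefault(b, []).append(i)
    significant = {b for b, idxs in assignments.items() if len(idxs) >= min_points}
    return assignments, significant


def brute_force_mp_labels(latencies, bin_size, min_points, anchor=0.0):
    """Labels per point: cluster index (bins ordered ascending) or -1."""
    assignments, significant = brute_force_bins(latencies, bin_size, min_points, anchor)
    order = {b: k for k, b in enumerate(sorted(significant))}
    labels = [-1] * len(latencies)
    for b, idxs in assignments.items():
        if b in significant:
            for i in idxs:
                labels[i] = order[b]
    return labels


def brute_force_amp_labels(latencies, bin_size, min_points, anchor=0.0):
    """MP labels with runs of consecutive significant bins merged."""
    assignments, significant = brute_force_bins(latencies, bin_size, min_points, anchor)
    merged = {}
    cluster = -1
    prev = None
    for b in sorted(significant):
        if prev is None or b != prev + 1:
            cluster += 1
        merged[b] = cluster
        prev = b
    labels = [-1] * len(latencies)
    for b, idxs in assignments.items():
        if b in merged:
            for i in idxs:
                labels[i] = merged[b]
    return labels


def brute_force_dbscan_labels(latencies, eps, min_samples):
    """Density-reachability from core points, by definition.

    Returns labels (arbitrary but consistent numbering) with -1 noise.
    """
    n = len(latencies)
    neighbors = [
        [j for j in range(n) if abs(latencies[j] - latencies[i]) <= eps]
        for i in range(n)
    ]
    core = [i for i in range(n) if len(neighbors[i]) >= min_samples]
    labels = [-1] * n
    cluster = -1
    for seed in core:
        if labels[seed] != -1:
            continue
        cluster += 1
        stack = [seed]
        labels[seed] = cluster
        while stack:
            i = stack.pop()
            if i not in core:
                continue  # border points do not expand
            for j in neighbors[i]:
                if labels[j] == -1:
                    labels[j] = cluster
                    if j in core:
                        stack.append(j)
    return labels


def same_partition(labels_a, labels_b):
    """True when two labelings induce the same partition + noise set."""
    if len(labels_a) != len(labels_b):
        return False
    mapping = {}
    reverse = {}
    for a, b in zip(labels_a, labels_b):
        if (a == -1) != (b == -1):
            return False
        if a == -1:
            continue
        if a in mapping and mapping[a] != b:
            return False
        if b in reverse and reverse[b] != a:
            return False
        mapping[a] = b
        reverse[b] = a
    return True


def brute_force_cv(edges, latency):
    """CV by definition: edges as (u, v) pairs, latency as a dict."""
    if not edges:
        return 0.0, 0, 0
    n_viol = sum(1 for u, v in edges if latency[v] < latency[u])
    return n_viol / len(edges), n_viol, len(edges)
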